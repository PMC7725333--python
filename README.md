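# glycoscan

Which sugars can a bacterium or archaeon actually make? Unlike DNA and
proteins, glycans are not built from one universal alphabet: the set of
monosaccharides an organism can biosynthesize — its **glycan alphabet** —
varies between phyla, species, and even strains of one species. `glycoscan`
infers that alphabet for a genome from homology-search evidence: it
post-processes profile-HMM (HMMER3) and blastp hit tables for the enzyme
families of nucleotide-sugar biosynthesis pathways and applies a strict
pathway-completeness rule.

It is written for comparative genomicists who already run `hmmsearch` /
`blastp` over proteomes and want a tested, deterministic way to turn hit
tables into per-genome monosaccharide calls and corpus-level prevalence
analytics.

## The model

The package ships a curated registry of 55 monosaccharides reachable through
57 nucleotide sugars (UDP-, GDP-, CMP-, TDP/dTDP-, ADP-, CDP-activated) from
six precursors (Glc-1-P, Fru*f*-6-P, GDP-Man, UDP-Glc2NAc, Glc2NAc-1-P,
Sed-7-P). Each nucleotide sugar has one or more biosynthesis routes; each
route step is satisfiable by one or more enzyme families (57 profile-HMM
families `GPExxxxx` with bit-score thresholds, plus blastp-query families
with coverage/similarity cutoffs).

Inference proceeds in four stages:

1. **Filter** — an HMM hit passes iff its *best-one-domain* bit score
   `b ≥ T_f` for family *f* (database-size independent); a blastp hit passes
   iff query coverage ≥ 90 % and similarity ≥ 30 % (per-family overrides,
   e.g. 70 % similarity for the PdeG query). All comparisons are inclusive.
2. **Resolve** — a protein passing several profiles gets exactly one
   annotation: a single passing profile wins outright; a narrow-specificity
   profile beats the broad profile built from a superset of its seeds;
   otherwise the profile with the largest margin `b − T_f` wins (ties to the
   smallest family id). Substrate-ambiguous families (e.g. the
   non-hydrolysing NDP-Hex2NAc C2-epimerase) are attributed by gene
   neighbourhood: default pathway unless another enzyme of an override
   pathway lies within ±10 CDS.
3. **Call** — completeness rule: monosaccharide *m* is present iff some
   route of some nucleotide sugar of *m* has **every** step supported by a
   passing, attributed homologue. A single missing step means absence (the
   pathway is reported as partial, with its missing-step count).
4. **Close** — paired products sharing one pathway up to homologous terminal
   reductases (rhamnose/6-deoxytalose, cillose/cereose, abequose/paratose)
   are co-called, and presence of a product implies its registered precursor
   (11 pairs, e.g. paratose → tyvelose), iterated to a fixed point.

Corpus analytics classify monosaccharides as **common** (fraction of genomes
≥ 0.50), **rare** (≤ 0.10) or **less common** (between), aggregate per-species
maxima and strain ranges, and build phylum × monosaccharide prevalence
tables. Threshold calibration utilities implement ROC sweeps against an
annotated reference (operating point: max Matthews correlation, stringent
tie-break), bit-score scatter partitioning for sibling profiles, seed
self-score thresholds T_exp / T_extend, and a largest-score-gap mode.

A first-class synthetic-data generator plants registry-consistent pathway
gene clusters into simulated genomes (with decoys, ambiguous hits, step
dropout) and writes the exact formats the pipeline reads, so the whole
system is testable offline with known ground truth.

## Worked example

```bash
glycoscan simulate --out universe --seed 11 --phyla 3 --species-per-phylum 4 \
    --strains 1:3 --decoy-rate 4
# INFO glycoscan: wrote 20 genomes under universe
glycoscan call --universe universe --out calls
# INFO glycoscan: called 20 genomes
glycoscan summarize --matrix calls/presence_matrix.tsv \
    --taxonomy universe/taxonomy.tsv --out summary
# INFO glycoscan: summarized 20 genomes x 55 monosaccharides
```

`calls/presence_matrix.tsv` is a genomes × 55 monosaccharides 0/1 matrix.
For the first simulated genome:

```
GCF_000000001.1 alphabet size 5
['gal2nac', 'gal2naca', 'glc2naca', 'mana', 'yer']
matches planted truth: True
```

i.e. this genome carries complete pathways for N-acetyl-galactosamine, two
uronic acid derivatives, mannuronic acid and yersiniose A, and nothing else —
exactly the content the generator planted. `summary/prevalence_groups.tsv`
assigns each monosaccharide its prevalence fraction and group:

```
mono_id	n_genomes_present	fraction	group
6d-l-tal	3	0.15	less_common
6d-tal	1	0.05	rare
...
```

and `summary/strain_ranges.tsv` lists per-species (min, max) alphabet sizes
over strains, e.g. `Phylum_01_species_04  2  9  10`: two sequenced strains
using 9 and 10 monosaccharides.

The registry's printed-table aggregates are reproduced by
`glycoscan registry-summary --out table.tsv` (27 Glc-1-P nucleotide sugars,
column sum 58, 57 distinct, 55 monosaccharides, …).

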