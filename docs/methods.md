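# Methods

## The inference problem

A genome is scanned for the ability to biosynthesize each of 55
nucleotide-activated monosaccharides. Evidence is homology: per-proteome hit
tables from profile-HMM searches (HMMER3) and from blastp with characterized
query enzymes. The unit of decision is the *pathway*: a monosaccharide is
called present only when every enzymatic step of at least one of its
biosynthesis routes has a homologue passing its family threshold. The
absence of even one step is interpreted as absence of the monosaccharide —
a deliberately conservative rule: partial pathways are reported (with their
missing-step counts) but never contribute to presence.

## The pathway registry

The registry (`src/glycoscan/data/registry.yaml`, one human-editable YAML
file, bit-exact round-trip through load→dump) encodes:

- **55 monosaccharides**, each with enantiomer (d/l), ring form
  (pyranose/furanose) and backbone class (pentose, hexose, heptulose,
  nonulose);
- **57 nucleotide sugars** grouped under six precursors. Column counts per
  precursor (sugars 27/2/8/16/1/4; monosaccharides 25/2/8/16/1/4; plus the
  backbone/enantiomer/ring/nucleotide breakdowns) reproduce the published
  summary table exactly, including its two footnote identities: the column
  sum of sugars is 58 while the distinct count is 57, because CMP-Leg5Ac7Ac
  has two routes with distinct precursors (UDP-Glc2NAc and Glc2NAc-1-P,
  the latter via an uncommon guanylyltransferase first step); and the
  distinct sugar count exceeds the monosaccharide count by exactly 2,
  because l-rhamnose and Qui4NAc are made as both UDP- and TDP/dTDP-
  derivatives;
- **57 profile-HMM enzyme families** (`GPExxxxx`) with bit-score thresholds
  and the calibration method that set each (roc / scatter / t_exp /
  t_extend / manual), and **10 blastp-query families** (`GPE8xxxx`, carrying
  a human query name such as PdeG) with coverage/similarity cutoffs.
  Seed-sequence counts across all families total 789;
- **11 precursor→product pairs** (l-Rha2NAc→l-Qui2NAc, l-Rha→6-deoxy-l-Tal,
  Fuc→Fucf, Par→Tyv, Gal→Galf, GlcA→GalA, l-Ara4N→l-Ara4NFo, Per→Per4Ac,
  Man2NAc→Man2NAcA, Glc2NAcA→Gal2NAcA, Bac2Ac4Ac→Leg5Ac7Ac) and **3 product
  pairs** whose members share one pathway up to homologous terminal
  C4-reductases (d-rhamnose/6-deoxy-d-talose, cillose/cereose,
  abequose/paratose);
- **2 context rules** for substrate-promiscuous families (below).

Where published sources state only aggregate structure, the concrete route
memberships follow standard nucleotide-sugar biochemistry (RmlABCD for
TDP-sugars, Gmd/Fcl and ColD/ColC for GDP-sugars, the Wbp oxidase/
aminotransferase/acetyltransferase ladder for diacetamido-uronates, the
Pgl/Pse/Leg/Neu routes to nonulosonates, ArnAB for l-Ara4N, GmhA/Hdd/Hld
for heptoses) and are this package's own curation. Shared families are
deliberate: broad SDR-superfamily reductase, aminotransferase,
N-acetyltransferase, epimerase and synthase profiles each serve steps in
several pathways, exactly the promiscuity structure that makes resolution
and context rules necessary. Glycolytic precursor-forming steps
(Glc-6-P→Glc-1-P etc.) are not route steps, and the UDP-Glc2NAc and GDP-Man
hub routes are stored once, never duplicated into their derivatives'
routes — so derivative pathways can be detected in organisms that have lost
the hub pathway (host-dependent intracellular bacteria show precisely this
pattern). l-iduronic acid is excluded: it has no standalone pathway
(it arises by C5-epimerization within polymer chains). UDP-glucose carries a
second single-step route (the family-2 uridylyltransferase) as a genuine
alternative activation.

Validation is exhaustive, not first-error: loading reports every schema
violation, dangling identifier, duplicate id, malformed pair and
precursor-pair cycle at once.

## Scores, thresholds and calibration

HMM hits are judged on the best-one-domain bit score, which does not depend
on database size; E-values are carried but never thresholded on. All cutoff
comparisons are inclusive (≥), matching the blastp convention (≥ 90 %
coverage, ≥ 30 % similarity), and boundary behaviour is tested.

Calibration implements the three ways family thresholds are set in practice:

- **ROC sweep** (`roc_curve`) against a reference whose annotations are
  assumed correct: one confusion-matrix point per distinct score, predicted
  positive iff score ≥ threshold. The operating point (`choose_threshold`)
  defaults to maximum Matthews correlation with ties resolved to the
  *highest* threshold — the stringency bias appropriate when false pathway
  calls are costlier than misses. Max-F1 and Youden J are available by flag
  and recorded in output metadata.
- **Scatter partitioning** (`scatter_partition`) for homologous sibling
  profiles whose reference annotations are too incomplete for a ROC curve:
  per-axis thresholds maximize the inter-cloud margin; overlapping clouds
  are flagged non-separable and the full scatter table is emitted for
  curator review (the decision is manual practice, the tool prepares it).
  A divergent sibling sequence is excluded by construction: the threshold
  lands above its score.
- **Seed self-scores**: T_exp is the minimum self-score of the
  experimentally characterized seeds, T_extend the minimum over the extended
  homologue set (absent for some families; requesting it then is an error).
  These are defined here as minima — the natural "keep every seed" rule —
  since only the names are fixed by convention. T_extend ≤ T_exp whenever
  the extended set contains the experimental set.
- **Largest-gap mode** (`largest_gap_threshold`) for families whose
  matching-annotation scores fall in discontinuous blocks (e.g. 705–303
  bits, then 57–41): the threshold is the bottom edge of the upper block.

A two-Normal synthetic sweep (N(55,5) positives vs N(30,5) negatives)
recovers the analytic equal-likelihood boundary of 42.5 bits within ±1 bit
at 10 000 scores per class; this is asserted in the acceptance suite.

## Annotation resolution and genomic context

A protein passing several profiles receives exactly one annotation, in rule
order: (1) single passing profile; (2) narrow-over-broad — when a narrow
profile and the broad profile generated from a superset of its seeds both
pass, the narrow one wins regardless of margin (lowering thresholds on
narrow families would cost specificity, so their verdicts take precedence);
(3) maximum margin (score − threshold), ties to the lexicographically
smallest family id. The procedure is deterministic, permutation-invariant,
and satisfies independence of irrelevant alternatives (removing a loser
never changes the winner); each decision is logged to an audit table.

Two families carry **context rules**:

- the non-hydrolysing NDP-Hex2NAc C2-epimerase defaults to the Man2NAc
  pathway (and its registered downstream products, e.g. Man2NAcA, which pass
  through the same step); it is additionally attributed to l-Fuc2NAc,
  l-Qui2NAc or Man2NAc3NAcA only when another enzyme serving that pathway
  lies within ±10 CDS on the same replicon. Without a feature table the
  check degrades to whole-genome context and says so in the audit record.
  The window default of ±10 genes is a design choice (O-antigen and capsule
  clusters are compact); it is configurable per rule.
- the NDP-sugar C4-epimerase family is attributed to *all* pathways
  containing it (`mode: all`). The known consequence is a systematic
  over-call of l-arabinose in xylose-positive genomes — the two pathways
  differ only by this promiscuous epimerization, and sequence similarity
  alone cannot assign substrate specificity. This over-call is intentional
  and documented rather than hidden.

## Calling and closure

Per genome: a step is satisfied iff ≥ 1 attributed passing hit matches any
family in its alternative set (non-orthologous enzymes catalysing the same
reaction are one step with several families); a route is complete iff all
steps are satisfied; a sugar is made iff ≥ 1 route is complete; the alphabet
is the deduplicated monosaccharide set (l-rhamnose via UDP and TDP routes
counts once). One protein may support steps in many pathways — shared
enzymes impose no exclusivity. Closures then run to a fixed point: product
pairs are co-called, and product presence implies precursor presence.
Implied presences are distinguished from detected ones
(`detected` / `implied_pair` / `implied_precursor`) in the evidence bundle,
one JSON file per genome, alongside the 0/1 presence matrix.

Calling is monotone (adding hits never removes a monosaccharide) and the
closure is idempotent; both are property-tested, and calls are checked
against an exhaustive route × step × hit brute-force evaluator.

## Prevalence analytics

The prevalence denominator is all genomes in the run; a species-level
denominator is available by aggregating first (per-species maxima). Groups:
common ≥ 0.50, rare ≤ 0.10, less common between, both printed boundaries
inclusive toward their own group. Species aggregation reports the max
alphabet over strains (with arg-max genome); strain ranges cover only
species with > 1 sequenced strain and ≥ 1 monosaccharide in some strain;
phylum tables drop phyla with < 5 genomes from the rendered output while
keeping them in the raw table. Genomes without taxonomy land in an explicit
`unassigned` bucket, never silently dropped. Alphabet size vs proteome size
is summarized by Spearman rank correlation with a seeded permutation
p-value (10 000 permutations by default, vectorized over ranks).

## The synthetic universe

The generator emulates a RefSeq-scale scan at desk scale. Default study
conditions: 5 phyla × 8 species × 1–4 strains, planted alphabet sizes
spanning 0–23 (the largest observed alphabet in a real corpus being 23,
none of the organisms using all 55), pass scores Normal(threshold + 25, 5)
truncated to ≥ 5 bits above threshold so float formatting can never flip a
boundary, a mean of 5 sub-threshold decoy hits per genome, and optional
ambiguity (planted hits also passing a sibling profile at half margin) and
dropout (routes losing one step, creating partial pathways). Planted
pathway genes are laid out as contiguous clusters — emulating O-antigen /
capsule operon structure — separated by more filler CDS than any context
window, so neighbourhood evidence cannot leak between unrelated clusters.
Protein identifiers follow the RefSeq `WP_…` pattern. All randomness flows
from one seed through four independent child streams (planting, score
noise, ambiguity, decoys), making each noise knob independently togglable
and every output byte-identical under a fixed seed.

Ground truth is computed by a set-logic evaluator internal to the generator
and independent of the inference modules: route completeness over the
emitted family set, the cluster-co-location form of the context-rule
override, and the pair/precursor closures. With zero noise the pipeline
must recover these expected alphabets for 100 % of genomes; with decoys
strictly below thresholds, recovery must be unchanged; with ambiguity and
correct cluster context, every ambiguous protein must resolve to its
planted family. All three are asserted in the test suite.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: sequence-level score distributions (scores are
drawn from the stated model, not from alignments), annotation errors in the
reference database, fragmented assemblies and split genes, paralogs with
intermediate scores near thresholds, and horizontal transfer patterns. The
closed loop validates the *logic* of filtering, resolution, context,
completeness and closure, not the biological error rate of any particular
threshold.

## Numerical and design choices

- Threshold comparisons inclusive everywhere; tie-breaks always toward
  stringency (highest threshold) or determinism (smallest id).
- Coverage is computed on the query (characterized enzyme) side,
  `100 × alignment length / query length`, clamped to 100 with a warning;
  an explicit coverage column, when declared, is used verbatim. With
  several HSPs per protein–query pair the max-bitscore HSP is kept.
- blastp word size 2 is recorded as a search-invocation constant
  (`BLASTP_WORD_SIZE`); running searches is out of scope — hit tables are
  the input boundary.
- HMMER tables are parsed by hand (stable whitespace format) because
  duplicate (protein, profile) rows must merge by max best-one-domain
  score; the parser is cross-checked against Bio.SearchIO on clean input.
- Degenerate inputs are errors, not guesses: single-class ROC input,
  identical scatter clouds, missing extended seed sets, empty registries,
  cyclic precursor pairs, hi ≤ lo group cutoffs.
- Problem sizes in the acceptance script (200 genomes for the closed loop,
  10 000 scores per class for threshold recovery, exhaustive enumeration
  over all 59 routes for step deletion) were chosen as the smallest sizes
  at which the measured quantities are stable across seeds.

## Known limitations

- Route membership for pathways whose published record is aggregate-only is
  reconstructed curation; swapping in a revised registry file changes calls
  without code changes, which is the point of the registry being data.
- The l-arabinose over-call (C4-epimerase promiscuity) is by design; treat
  l-arabinose prevalence as an upper bound.
- Precursor propagation marks precursors present even when their standalone
  route was not independently detected (the product's presence is the
  evidence); the provenance field preserves the distinction for downstream
  filtering.
- Context attribution assumes clustered pathway genes; organisms with
  scattered pathway loci degrade to whole-genome context, which can only
  widen (never narrow) attribution.
- CD-Hit-style deduplication of near-identical proteins is not performed;
  identical proteins appear as independent supporting hits.
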