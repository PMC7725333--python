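"""Synthetic universes: genomes with planted glycan alphabets.

Stands in for a RefSeq-scale corpus: generates hit tables (HMMER tblout,
BLAST tabular), gene-order feature tables, a taxonomy table and a ground
truth bundle, all deterministically from one seed, so the whole pipeline is
testable offline.

The expected alphabet of each genome is computed by an evaluator internal to
the generator that works directly on planted family sets (plain set logic,
independent of the inference code), including the context-rule semantics and
the pair/precursor closures. With zero noise the pipeline must recover these
expected alphabets exactly; decoy hits are planted strictly below thresholds
and must change nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from glycoscan.calibrate import AnnotatedScore
from glycoscan.registry import Registry

__all__ = [
    "UniverseSpec",
    "GenomeTruth",
    "SyntheticUniverse",
    "generate_universe",
    "generate_score_db",
    "plant_prevalence_profile",
    "expected_alphabet",
    "blast_query_map",
]


@dataclass(frozen=True)
class UniverseSpec:
    """Study conditions for one synthetic universe."""

    n_phyla: int = 5
    n_species_per_phylum: int = 8
    strains_per_species: tuple[int, int] = (1, 4)  # inclusive range
    alphabet_size_range: tuple[int, int] = (0, 23)  # planted sizes span this range
    decoy_rate: float = 5.0  # mean sub-threshold decoy hits per genome
    ambiguity_rate: float = 0.0  # fraction of planted hits also passing a sibling profile
    dropout_rate: float = 0.0  # fraction of planted routes losing one step
    pass_margin: float = 25.0  # mean bits above threshold for planted hits
    score_sd: float = 5.0
    min_margin: float = 5.0  # planted scores never closer than this to the threshold
    #: per-mono planting probabilities; overrides size-targeted planting
    prevalence_targets: tuple[tuple[str, float], ...] | None = None
    seed: int = 0

    def validate(self, reg: Registry) -> None:
        problems = []
        if self.n_phyla < 1 or self.n_species_per_phylum < 1:
            problems.append("n_phyla and n_species_per_phylum must be >= 1")
        if self.strains_per_species[0] < 1 or (
            self.strains_per_species[0] > self.strains_per_species[1]
        ):
            problems.append(f"bad strains_per_species range {self.strains_per_species}")
        lo, hi = self.alphabet_size_range
        if lo < 0 or lo > hi:
            problems.append(f"bad alphabet_size_range {self.alphabet_size_range}")
        if hi > len(reg.monosaccharides):
            problems.append(
                f"alphabet_size_range asks for {hi} monosaccharides but the "
                f"registry holds only {len(reg.monosaccharides)}"
            )
        for r in ("decoy_rate", "ambiguity_rate", "dropout_rate"):
            if getattr(self, r) < 0:
                problems.append(f"{r} must be >= 0")
        if not 0 <= self.ambiguity_rate <= 1:
            problems.append("ambiguity_rate must lie in [0, 1]")
        if not 0 <= self.dropout_rate <= 1:
            problems.append("dropout_rate must lie in [0, 1]")
        if self.prevalence_targets is not None:
            for m, p in self.prevalence_targets:
                if m not in reg.monosaccharides:
                    problems.append(f"prevalence target for unknown monosaccharide {m!r}")
                if not 0 <= p <= 1:
                    problems.append(f"prevalence target for {m} outside [0, 1]: {p}")
        if problems:
            raise ValueError(
                "invalid universe spec:\n" + "\n".join("  - " + p for p in problems)
            )


@dataclass
class GenomeTruth:
    genome_id: str
    planted_monos: list[str]  # monosaccharides whose routes were planted
    planted_routes: list[str]
    dropped_steps: list[tuple[str, int]]  # (route_id, step_index) deletions
    ambiguous_proteins: list[str]
    expected_present: list[str]  # evaluator output incl. closures

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "planted_monos": self.planted_monos,
            "planted_routes": self.planted_routes,
            "dropped_steps": [list(t) for t in self.dropped_steps],
            "ambiguous_proteins": self.ambiguous_proteins,
            "expected_present": self.expected_present,
        }


@dataclass
class SyntheticUniverse:
    spec: UniverseSpec
    #: genome_id -> list of tblout text lines (HMM hits)
    tblout: dict[str, list[str]] = field(default_factory=dict)
    #: genome_id -> list of blast tabular lines
    blast: dict[str, list[str]] = field(default_factory=dict)
    #: genome_id -> list of feature-table data rows (without header)
    features: dict[str, list[str]] = field(default_factory=dict)
    taxonomy_rows: list[str] = field(default_factory=list)
    truth: dict[str, GenomeTruth] = field(default_factory=dict)

    BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "ppos", "length", "qlen",
                     "evalue", "bitscore")

    def genome_ids(self) -> list[str]:
        return list(self.truth)

    def write(self, outdir: str | Path) -> Path:
        """Materialize the universe on disk (per-genome files + taxonomy + truth)."""
        outdir = Path(outdir)
        gdir = outdir / "genomes"
        gdir.mkdir(parents=True, exist_ok=True)
        for gid in self.truth:
            d = gdir / gid
            d.mkdir(exist_ok=True)
            (d / "hits.tblout").write_text(
                "#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----\n"
                "# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target\n"
                "#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ ----- ----- --- --- --- --- --- --- --- ---------------------\n"
                + "".join(self.tblout[gid])
            )
            (d / "hits.blast.tsv").write_text("".join(self.blast[gid]))
            (d / "features.txt").write_text(_FEATURE_HEADER + "".join(self.features[gid]))
        (outdir / "taxonomy.tsv").write_text(
            "genome_id\tspecies\tgenus\tphylum\tdomain\tproteome_size\n"
            + "".join(self.taxonomy_rows)
        )
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {g: t.to_json_dict() for g, t in self.truth.items()},
                indent=1,
            )
            + "\n"
        )
        return outdir


_FEATURE_HEADER = (
    "# feature\tclass\tassembly\tassembly_unit\tseq_type\tchromosome\t"
    "genomic_accession\tstart\tend\tstrand\tproduct_accession\t"
    "non-redundant_refseq\trelated_accession\tname\tsymbol\tGeneID\t"
    "locus_tag\tfeature_interval_length\tproduct_length\tattributes\n"
)


def blast_query_map(reg: Registry) -> dict[str, str]:
    """query sequence name -> blast family gpe_id (for read_blast_table)."""
    return {
        f.query_name: f.gpe_id
        for f in reg.blast_families().values()
        if f.query_name is not None
    }


# ---------------------------------------------------------------------------
# independent expected-alphabet evaluator (plain set logic on family sets)
# ---------------------------------------------------------------------------


def _family_supports(fam: str, mono: str, families: set[str], reg: Registry) -> bool:
    rule = reg.context_rule_for(fam)
    if rule is None or rule.mode == "all":
        return True
    allowed = _closure_down(rule.default_pathway, reg)
    if mono in allowed:
        return True
    for ov in rule.override_pathways:
        if mono in _closure_down(ov, reg):
            # other enzymes of the override pathway anywhere in the genome
            other: set[str] = set()
            for ns in reg.nucleotide_sugars.values():
                if ns.monosaccharide_id == ov:
                    for r in ns.routes:
                        other |= set(r.family_ids)
            if (other - {fam}) & families:
                return True
    return False


def _closure_down(mono: str, reg: Registry) -> set[str]:
    out, frontier = {mono}, [mono]
    while frontier:
        cur = frontier.pop()
        for pre, prod in reg.precursor_pairs:
            if pre == cur and prod not in out:
                out.add(prod)
                frontier.append(prod)
    return out


def expected_alphabet(families: set[str], reg: Registry) -> set[str]:
    """Monosaccharides a genome with exactly these passing families must show.

    Applies the completeness rule, the whole-genome context-rule semantics and
    the product-pair / precursor closures. Used by the generator to freeze
    ground truth; kept independent of the inference modules.
    """
    present: set[str] = set()
    for ns in reg.nucleotide_sugars.values():
        mono = ns.monosaccharide_id
        for route in ns.routes:
            ok = all(
                any(f in families and _family_supports(f, mono, families, reg)
                    for f in step.families)
                for step in route.steps
            )
            if ok:
                present.add(mono)
                break
    changed = True
    while changed:
        changed = False
        for a, b in reg.product_pairs:
            if (a in present) != (b in present):
                present |= {a, b}
                changed = True
        for pre, prod in reg.precursor_pairs:
            if prod in present and pre not in present:
                present.add(pre)
                changed = True
    return present


# ---------------------------------------------------------------------------
# universe generation
# ---------------------------------------------------------------------------


Plant = list[tuple[str, dict[int, str]]]  # (route_id, step_index -> chosen family)


def _choose_route(mono: str, reg: Registry, rng: np.random.Generator):
    sugars = reg.sugars_of_mono(mono)
    ns = sugars[int(rng.integers(len(sugars)))]
    return ns.routes[int(rng.integers(len(ns.routes)))]


def _route_choice(route, rng: np.random.Generator) -> dict[int, str]:
    return {
        s.step_index: sorted(s.families)[int(rng.integers(len(s.families)))]
        for s in route.steps
    }


def _plant_for_target(
    k: int, cap: int, reg: Registry, rng: np.random.Generator
) -> Plant:
    """Pick routes until the expected alphabet reaches >= k monosaccharides.

    Closure effects (shared steps, implied precursors, co-called pairs) can
    pull in more than one monosaccharide per planted route; candidate routes
    that would push the alphabet beyond ``cap`` (the declared size-range
    maximum) are skipped, so planted sizes always stay inside the range.
    """
    monos = list(reg.monosaccharides)
    rng.shuffle(monos)
    plant: Plant = []
    families: set[str] = set()
    present: set[str] = set()
    for mono in monos:
        if len(present) >= k:
            break
        if mono in present:
            continue
        route = _choose_route(mono, reg, rng)
        choice = _route_choice(route, rng)
        trial = families | set(choice.values())
        trial_present = expected_alphabet(trial, reg)
        if len(trial_present) > cap:
            continue
        plant.append((route.route_id, choice))
        families = trial
        present = trial_present
    return plant


def _plant_for_prevalence(
    targets: Sequence[tuple[str, float]], reg: Registry, rng: np.random.Generator
) -> Plant:
    plant: Plant = []
    for mono, p in targets:
        if rng.random() >= p:
            continue
        route = _choose_route(mono, reg, rng)
        plant.append((route.route_id, _route_choice(route, rng)))
    return plant


def _expected_from_clusters(
    emitted: set[tuple[str, str]], reg: Registry
) -> set[str]:
    """Expected alphabet when pathway genes sit in per-route clusters.

    ``emitted`` holds (route_id, family) pairs actually written to the hit and
    feature tables; each route's genes form one contiguous cluster separated
    from other clusters by more than the context window. A context-ruled
    family therefore supports an override pathway exactly when some cluster
    co-locates a ruled gene with another gene whose family serves that
    pathway — the neighbourhood condition the pipeline checks with its gene
    window.
    """
    families = {f for _, f in emitted}
    by_route: dict[str, set[str]] = {}
    for rid, f in emitted:
        by_route.setdefault(rid, set()).add(f)

    def supports(fam: str, mono: str) -> bool:
        rule = reg.context_rule_for(fam)
        if rule is None or rule.mode == "all":
            return True
        if mono in _closure_down(rule.default_pathway, reg):
            return True
        for ov in rule.override_pathways:
            if mono not in _closure_down(ov, reg):
                continue
            ov_families = {
                g for g in reg.enzyme_families
                if ov in reg.monos_with_family(g)
            }
            for cluster in by_route.values():
                if fam in cluster and (cluster - {fam}) & ov_families:
                    return True
        return False

    present: set[str] = set()
    for ns in reg.nucleotide_sugars.values():
        mono = ns.monosaccharide_id
        for route in ns.routes:
            if all(
                any(f in families and supports(f, mono) for f in step.families)
                for step in route.steps
            ):
                present.add(mono)
                break
    changed = True
    while changed:
        changed = False
        for a, b in reg.product_pairs:
            if (a in present) != (b in present):
                present |= {a, b}
                changed = True
        for pre, prod in reg.precursor_pairs:
            if prod in present and pre not in present:
                present.add(pre)
                changed = True
    return present


def generate_universe(spec: UniverseSpec, reg: Registry) -> SyntheticUniverse:
    """Generate a full synthetic universe (in memory; ``.write()`` to disk).

    Per genome and planted route, every step receives one protein with an
    above-threshold hit for one family of the step's alternative set; pathway
    genes are laid out as contiguous clusters in the feature table (O-antigen
    cluster style) separated by filler CDS. Dropout removes single steps,
    decoys score strictly below thresholds, and ambiguous proteins addition-
    ally pass a sibling profile at a smaller margin.
    """
    spec.validate(reg)
    # independent child streams: planting/layout, pass-score noise, ambiguity,
    # decoys — so turning one knob never perturbs the others
    rng_plant = np.random.default_rng([spec.seed, 0])
    rng_score = np.random.default_rng([spec.seed, 1])
    rng_ambig = np.random.default_rng([spec.seed, 2])
    rng_decoy = np.random.default_rng([spec.seed, 3])
    uni = SyntheticUniverse(spec=spec)

    lo_k, hi_k = spec.alphabet_size_range
    hmm_ids = sorted(reg.hmm_families())
    narrow_children: dict[str, set[str]] = {}
    for gid_, fam in reg.enzyme_families.items():
        if fam.broad_parent:
            narrow_children.setdefault(fam.broad_parent, set()).add(gid_)
    route_map = reg.route_map()
    # cluster spacing must exceed every context-rule window, so neighbourhood
    # evidence never leaks between unrelated pathway clusters
    min_gap = max([cr.window for cr in reg.context_rules], default=10) + 2

    genome_counter = 0
    protein_counter = 0
    decoy_counter = 0
    for ph in range(spec.n_phyla):
        phylum = f"Phylum_{ph + 1:02d}"
        domain = "Archaea" if ph == 0 else "Bacteria"
        for sp in range(spec.n_species_per_phylum):
            species = f"{phylum}_species_{sp + 1:02d}"
            genus = f"{phylum}_genus_{sp % 4 + 1:02d}"
            n_strains = int(rng_plant.integers(spec.strains_per_species[0],
                                               spec.strains_per_species[1] + 1))
            base_k = int(rng_plant.integers(lo_k, hi_k + 1))
            for st in range(n_strains):
                genome_counter += 1
                gid = f"GCF_{genome_counter:09d}.1"
                if spec.prevalence_targets is not None:
                    plant = _plant_for_prevalence(spec.prevalence_targets, reg, rng_plant)
                else:
                    k = int(np.clip(base_k + rng_plant.integers(-2, 3), lo_k, hi_k))
                    plant = _plant_for_target(k, hi_k, reg, rng_plant)

                tbl, bla, feat = [], [], []
                replicon = f"NZ_SYN{genome_counter:07d}"
                pos = 1
                emitted: set[tuple[str, str]] = set()
                dropped: list[tuple[str, int]] = []
                ambiguous: list[str] = []

                def filler(n: int) -> None:
                    nonlocal pos, protein_counter
                    for _ in range(n):
                        protein_counter += 1
                        pid = f"WP_{protein_counter:09d}.1"
                        start, end = pos * 1500, pos * 1500 + 1200
                        feat.append(_feature_row("gene", replicon, start, end, "+", ""))
                        feat.append(_feature_row("CDS", replicon, start, end, "+", pid))
                        pos += 1

                filler(int(rng_plant.integers(2, 6)))
                for rid, choice in plant:
                    route = route_map[rid]
                    drop_idx = None
                    if spec.dropout_rate > 0 and rng_plant.random() < spec.dropout_rate:
                        drop_idx = int(rng_plant.integers(1, len(route.steps) + 1))
                        dropped.append((rid, drop_idx))
                    # each cluster carries its own gene for every surviving
                    # step, so the pathway is complete within one neighbourhood
                    for step in route.steps:
                        if step.step_index == drop_idx:
                            continue
                        fam_id = choice[step.step_index]
                        emitted.add((rid, fam_id))
                        protein_counter += 1
                        pid = f"WP_{protein_counter:09d}.1"
                        fam = reg.enzyme_families[fam_id]
                        if fam.is_hmm:
                            score = _pass_score(fam.threshold_bits, spec, rng_score)
                            tbl.append(_tblout_row(pid, fam_id, score, rng_score))
                            if (
                                spec.ambiguity_rate > 0
                                and rng_ambig.random() < spec.ambiguity_rate
                            ):
                                sib = _sibling(fam_id, hmm_ids, narrow_children, rng_ambig)
                                if sib is not None:
                                    sib_thr = reg.enzyme_families[sib].threshold_bits
                                    margin = score - fam.threshold_bits
                                    sib_score = sib_thr + max(margin / 2.0, 1.0)
                                    tbl.append(_tblout_row(pid, sib, sib_score, rng_score))
                                    ambiguous.append(pid)
                        else:
                            bla.append(_blast_row(pid, fam, spec, rng_score, passing=True))
                        start, end = pos * 1500, pos * 1500 + 1200
                        feat.append(_feature_row("gene", replicon, start, end, "+", ""))
                        feat.append(_feature_row("CDS", replicon, start, end, "+", pid))
                        pos += 1
                    filler(int(rng_plant.integers(min_gap, min_gap + 8)))

                # decoys: strictly below threshold, must change nothing
                for _ in range(int(rng_decoy.poisson(spec.decoy_rate))):
                    decoy_counter += 1
                    pid = f"WP_9{decoy_counter:08d}.1"
                    fam_id = sorted(reg.enzyme_families)[
                        int(rng_decoy.integers(len(reg.enzyme_families)))
                    ]
                    fam = reg.enzyme_families[fam_id]
                    if fam.is_hmm:
                        score = max(
                            fam.threshold_bits - spec.min_margin
                            - abs(rng_decoy.normal(0, 10)),
                            2.0,
                        )
                        tbl.append(_tblout_row(pid, fam_id, score, rng_decoy))
                    else:
                        bla.append(_blast_row(pid, fam, spec, rng_decoy, passing=False))
                    start, end = pos * 1500, pos * 1500 + 1200
                    feat.append(_feature_row("CDS", replicon, start, end, "-", pid))
                    pos += 1

                expected = _expected_from_clusters(emitted, reg)
                uni.tblout[gid] = tbl
                uni.blast[gid] = bla
                uni.features[gid] = feat
                uni.truth[gid] = GenomeTruth(
                    genome_id=gid,
                    planted_monos=sorted(
                        {route_map[rid].nucleotide_sugar_id for rid, _ in plant}
                    ),
                    planted_routes=sorted(rid for rid, _ in plant),
                    dropped_steps=sorted(dropped),
                    ambiguous_proteins=sorted(ambiguous),
                    expected_present=sorted(expected),
                )
                proteome = int(rng_plant.integers(800, 4500))
                uni.taxonomy_rows.append(
                    f"{gid}\t{species}\t{genus}\t{phylum}\t{domain}\t{proteome}\n"
                )
    return uni


def _sibling(
    fam_id: str,
    hmm_ids: Sequence[str],
    narrow_children: Mapping[str, set[str]],
    rng: np.random.Generator,
) -> str | None:
    """A sibling profile for ambiguity planting.

    Any other profile except a narrow child of this one (a narrow child would
    legitimately win the resolution over its broad parent). The sibling hit is
    planted at a smaller margin, so margin resolution recovers the true family;
    when the sibling happens to be the broad parent, narrow-over-broad does.
    """
    forbidden = narrow_children.get(fam_id, set()) | {fam_id}
    choices = [g for g in hmm_ids if g not in forbidden]
    if not choices:
        return None
    return choices[int(rng.integers(len(choices)))]


def _pass_score(threshold: float, spec: UniverseSpec, rng: np.random.Generator) -> float:
    s = threshold + spec.pass_margin + rng.normal(0, spec.score_sd)
    return float(max(s, threshold + spec.min_margin))


def _tblout_row(pid: str, fam_id: str, b1_score: float, rng: np.random.Generator) -> str:
    full = b1_score + abs(rng.normal(0, 1.5))
    ev = 10.0 ** (-max(b1_score / 10.0, 1.0))
    return (
        f"{pid:<20} -          {fam_id:<20} -          "
        f"{ev:9.1e} {full:6.1f}   0.1 {ev:9.1e} {b1_score:6.1f}   0.1 "
        f"  1.0   1   0   0   1   1   1   1 synthetic pathway protein\n"
    )


def _blast_row(
    pid: str, fam, spec: UniverseSpec, rng: np.random.Generator, passing: bool
) -> str:
    qlen = 300
    if passing:
        cov = min(fam.blast_min_coverage + 4.0 + abs(rng.normal(0, 3)), 100.0)
        ppos = min(fam.blast_min_similarity + 10.0 + abs(rng.normal(0, 5)), 99.0)
    else:
        cov = max(fam.blast_min_coverage - 10.0 - abs(rng.normal(0, 5)), 5.0)
        ppos = max(fam.blast_min_similarity - 8.0 - abs(rng.normal(0, 4)), 5.0)
    length = int(round(cov * qlen / 100.0))
    pident = max(ppos - 12.0, 2.0)
    bits = 2.0 * length * ppos / 100.0
    qname = fam.query_name or fam.gpe_id
    return (
        f"{qname}\t{pid}\t{pident:.1f}\t{ppos:.1f}\t{length}\t{qlen}\t"
        f"{10.0 ** -30:.1e}\t{bits:.1f}\n"
    )


def _feature_row(
    feature: str, replicon: str, start: int, end: int, strand: str, pid: str
) -> str:
    klass = "with_protein" if feature == "gene" else ""
    name = "synthetic protein" if pid else ""
    plen = (end - start) // 3 if pid else ""
    return (
        f"{feature}\t{klass}\tGCF_synthetic\tPrimary Assembly\tchromosome\t1\t"
        f"{replicon}\t{start}\t{end}\t{strand}\t{pid}\t\t\t{name}\t\t\t"
        f"SYN_{start}\t{end - start}\t{plen}\t\n"
    )


# ---------------------------------------------------------------------------
# annotated score sets (ROC calibration stand-in)
# ---------------------------------------------------------------------------


def generate_score_db(
    n_pos: int,
    n_neg: int,
    pos_mean: float,
    neg_mean: float,
    sd: float,
    seed: int = 0,
) -> list[AnnotatedScore]:
    """Two-component Normal score set with match labels, truncated at 0."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need >= 1 score in each class")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    pos = np.maximum(rng.normal(pos_mean, sd, n_pos), 0.0)
    neg = np.maximum(rng.normal(neg_mean, sd, n_neg), 0.0)
    out = [
        AnnotatedScore(f"POS_{i:06d}", float(s), True) for i, s in enumerate(pos)
    ] + [
        AnnotatedScore(f"NEG_{i:06d}", float(s), False) for i, s in enumerate(neg)
    ]
    return out


def plant_prevalence_profile(
    spec: UniverseSpec,
    reg: Registry,
    target_fractions: Mapping[str, float],
) -> UniverseSpec:
    """Return a spec planting each monosaccharide with its target probability.

    Rejects targets that violate precursor closure: a registered product
    cannot be declared more prevalent than its precursor, because planting the
    product always implies the precursor.
    """
    for m, p in target_fractions.items():
        if m not in reg.monosaccharides:
            raise ValueError(f"unknown monosaccharide in prevalence targets: {m!r}")
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence target for {m} outside [0, 1]: {p}")
    for pre, prod in reg.precursor_pairs:
        if prod in target_fractions and pre in target_fractions:
            if target_fractions[prod] > target_fractions[pre]:
                raise ValueError(
                    f"prevalence target for product {prod} "
                    f"({target_fractions[prod]}) exceeds its precursor {pre} "
                    f"({target_fractions[pre]}); violates precursor closure"
                )
    targets = tuple(sorted(target_fractions.items()))
    return replace(spec, prevalence_targets=targets)
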