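"""Per-genome monosaccharide presence calls.

The completeness rule: a route is complete iff every one of its steps has at
least one attributed passing homologue; a nucleotide sugar is made iff at
least one of its routes is complete; a monosaccharide is present iff at least
one of its nucleotide sugars is made. Absence of a homologue for even one
step means the monosaccharide is absent (the pathway is reported as partial
with its missing-step count, but never contributes to presence).

After direct calling, paired-product and precursor closures are applied:
members of a product pair (two sugars sharing one pathway up to homologous
final reductases) are always co-called, and the presence of a product
monosaccharide implies the presence of its registered precursor, iterated to
a fixed point. Implied presences are distinguished from detected ones in the
evidence records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from glycoscan.registry import Registry
from glycoscan.resolve import ResolvedHit

__all__ = [
    "StepCall",
    "GenomeAlphabet",
    "call_routes",
    "call_genome",
    "propagate_pairs",
    "alphabet_size",
    "presence_matrix",
    "write_presence_matrix",
]


@dataclass(frozen=True)
class StepCall:
    route_id: str
    step_index: int
    satisfied: bool
    supporting_protein_ids: tuple[str, ...] = ()


@dataclass
class GenomeAlphabet:
    genome_id: str
    #: monosaccharides called present (detected or implied), deduplicated
    present: set[str] = field(default_factory=set)
    #: mono_id -> "detected" | "implied_precursor" | "implied_pair"
    provenance: dict[str, str] = field(default_factory=dict)
    #: route_id -> step calls, for every route of every sugar
    evidence: dict[str, list[StepCall]] = field(default_factory=dict)
    #: incomplete-but-started pathways: (sugar_id, missing step count)
    partial: set[tuple[str, int]] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "present": sorted(self.present),
            "provenance": dict(sorted(self.provenance.items())),
            "partial": sorted([list(p) for p in self.partial]),
            "evidence": {
                rid: [
                    {
                        "step": sc.step_index,
                        "satisfied": sc.satisfied,
                        "proteins": list(sc.supporting_protein_ids),
                    }
                    for sc in calls
                ]
                for rid, calls in sorted(self.evidence.items())
            },
        }


def call_routes(
    attributed: Iterable[ResolvedHit], reg: Registry, genome_id: str
) -> dict[str, list[StepCall]]:
    """Evaluate every route of every sugar against this genome's hits."""
    hits = [h for h in attributed if h.genome_id == genome_id]
    # family -> supporting hits
    by_family: dict[str, list[ResolvedHit]] = {}
    for h in hits:
        by_family.setdefault(h.resolved_gpe_id, []).append(h)

    calls: dict[str, list[StepCall]] = {}
    for ns in reg.nucleotide_sugars.values():
        mono = ns.monosaccharide_id
        for route in ns.routes:
            step_calls = []
            for step in route.steps:
                support = []
                for fam in sorted(step.families):
                    for h in by_family.get(fam, ()):
                        if h.allowed_pathways is not None and mono not in h.allowed_pathways:
                            continue  # context rule withholds this pathway
                        support.append(h.protein_id)
                step_calls.append(
                    StepCall(
                        route_id=route.route_id,
                        step_index=step.step_index,
                        satisfied=bool(support),
                        supporting_protein_ids=tuple(sorted(set(support))),
                    )
                )
            calls[route.route_id] = step_calls
    return calls


def _direct_alphabet(calls: Mapping[str, list[StepCall]], reg: Registry,
                     genome_id: str) -> GenomeAlphabet:
    ga = GenomeAlphabet(genome_id=genome_id, evidence=dict(calls))
    for ns in reg.nucleotide_sugars.values():
        made = False
        best_missing: int | None = None
        any_hit = False
        for route in ns.routes:
            scs = calls.get(route.route_id, [])
            missing = sum(1 for sc in scs if not sc.satisfied)
            hit_steps = sum(1 for sc in scs if sc.satisfied)
            any_hit = any_hit or hit_steps > 0
            if scs and missing == 0:
                made = True
            if best_missing is None or missing < best_missing:
                best_missing = missing
        if made:
            ga.present.add(ns.monosaccharide_id)
            ga.provenance.setdefault(ns.monosaccharide_id, "detected")
        elif any_hit and best_missing:
            ga.partial.add((ns.sugar_id, best_missing))
    return ga


def propagate_pairs(ga: GenomeAlphabet, reg: Registry) -> GenomeAlphabet:
    """Apply product-pair co-calling and precursor closure to a fixed point.

    Idempotent: ``propagate_pairs(propagate_pairs(x)) == propagate_pairs(x)``.
    """
    changed = True
    while changed:
        changed = False
        for a, b in reg.product_pairs:
            for x, y in ((a, b), (b, a)):
                if x in ga.present and y not in ga.present:
                    ga.present.add(y)
                    ga.provenance.setdefault(y, "implied_pair")
                    changed = True
        for pre, prod in reg.precursor_pairs:
            if prod in ga.present and pre not in ga.present:
                ga.present.add(pre)
                ga.provenance.setdefault(pre, "implied_precursor")
                changed = True
    return ga


def call_genome(
    attributed: Iterable[ResolvedHit], reg: Registry, genome_id: str
) -> GenomeAlphabet:
    """Full per-genome inference: route calls, direct alphabet, closures."""
    calls = call_routes(attributed, reg, genome_id)
    return propagate_pairs(_direct_alphabet(calls, reg, genome_id), reg)


def alphabet_size(ga: GenomeAlphabet) -> int:
    """Number of distinct monosaccharides present (nucleotide forms deduplicated)."""
    return len(ga.present)


# ---------------------------------------------------------------------------
# matrix output
# ---------------------------------------------------------------------------


def presence_matrix(alphabets: Sequence[GenomeAlphabet], reg: Registry) -> pd.DataFrame:
    """Genomes x monosaccharides 0/1 matrix (all registry monos as columns)."""
    cols = sorted(reg.monosaccharides)
    data = {
        ga.genome_id: [1 if m in ga.present else 0 for m in cols] for ga in alphabets
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "genome_id"
    return df


def write_presence_matrix(
    alphabets: Sequence[GenomeAlphabet], reg: Registry, path: str | Path
) -> None:
    presence_matrix(alphabets, reg).to_csv(path, sep="\t")


def write_evidence_bundle(ga: GenomeAlphabet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ga.to_json_dict(), indent=1, sort_keys=False) + "\n")
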