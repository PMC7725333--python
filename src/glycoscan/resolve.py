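"""Single-annotation resolution and genomic-context disambiguation.

A protein can pass thresholds for several profiles (broad families, homologous
siblings). Each passing protein is assigned exactly one winning family:

1. only one profile passed -> that profile (``single_pass``);
2. a narrow profile and the broad profile generated from a superset of its
   seeds both passed -> the narrow one (``narrow_over_broad``);
3. otherwise the profile with the largest margin above its threshold
   (best-1-domain bits minus threshold), ties broken by lexicographically
   smallest family id (``margin``).

Substrate-promiscuous families additionally carry context rules: a hit is
attributed to the rule's default pathway unless another enzyme of one of the
override pathways lies in the same gene neighbourhood (or anywhere in the
genome when no feature table is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from glycoscan.hits import FeatureRecord, ProteinHit
from glycoscan.registry import ContextRule, Registry

__all__ = ["ResolvedHit", "resolve_multi_profile", "apply_context_rules", "audit_table"]


@dataclass
class ResolvedHit:
    hit: ProteinHit
    resolved_gpe_id: str
    resolution_reason: str  # single_pass | narrow_over_broad | margin | context
    candidate_gpe_ids: tuple[str, ...] = ()
    #: monosaccharide pathways this hit may support; None = unrestricted
    #: (every route step naming the family). Filled by apply_context_rules.
    allowed_pathways: frozenset[str] | None = None
    context_reason: str | None = None

    @property
    def protein_id(self) -> str:
        return self.hit.protein_id

    @property
    def genome_id(self) -> str:
        return self.hit.genome_id


def _margin(hit: ProteinHit, reg: Registry) -> float:
    fam = reg.enzyme_families[hit.gpe_id]
    if fam.is_hmm:
        return float(hit.best1dom_bits) - float(fam.threshold_bits)
    # blast families: distance above the similarity cutoff plays the margin role
    return float(hit.similarity_pct) - float(fam.blast_min_similarity)


def resolve_multi_profile(
    hits: Iterable[ProteinHit], reg: Registry
) -> list[ResolvedHit]:
    """Assign exactly one family annotation per passing protein.

    Non-passing hits are ignored. The outcome is deterministic and invariant
    under permutation of the input hit order.
    """
    by_protein: dict[tuple[str, str], list[ProteinHit]] = {}
    for h in hits:
        if h.passes_threshold:
            by_protein.setdefault((h.genome_id, h.protein_id), []).append(h)

    resolved: list[ResolvedHit] = []
    for key in sorted(by_protein):
        cand = sorted(by_protein[key], key=lambda h: h.gpe_id)
        cand_ids = tuple(h.gpe_id for h in cand)
        if len(cand) == 1:
            resolved.append(
                ResolvedHit(cand[0], cand[0].gpe_id, "single_pass", cand_ids)
            )
            continue
        # narrow-over-broad: drop any broad profile whose seed set contains a
        # passing narrow profile's seeds
        passing = {h.gpe_id for h in cand}
        shadowed = {
            reg.enzyme_families[g].broad_parent
            for g in passing
            if reg.enzyme_families[g].broad_parent in passing
        }
        kept = [h for h in cand if h.gpe_id not in shadowed]
        if len(kept) == 1:
            resolved.append(
                ResolvedHit(kept[0], kept[0].gpe_id, "narrow_over_broad", cand_ids)
            )
            continue
        # max margin, ties -> lexicographically smallest id (kept is id-sorted)
        best = max(_margin(h, reg) for h in kept)
        winner = next(h for h in kept if _margin(h, reg) == best)
        resolved.append(ResolvedHit(winner, winner.gpe_id, "margin", cand_ids))
    return resolved


# ---------------------------------------------------------------------------
# context rules
# ---------------------------------------------------------------------------


def _neighbourhoods(
    features: Sequence[FeatureRecord],
) -> dict[str, tuple[str, int]]:
    return {f.protein_id: (f.replicon_id, f.ordinal_index) for f in features}


def derived_products(mono: str, reg: Registry) -> set[str]:
    """Transitive closure of registered precursor->product relations from ``mono``.

    A hit attributed to a pathway also serves the routes of that pathway's
    registered downstream products (which pass through the same step).
    """
    out = {mono}
    frontier = [mono]
    while frontier:
        cur = frontier.pop()
        for pre, prod in reg.precursor_pairs:
            if pre == cur and prod not in out:
                out.add(prod)
                frontier.append(prod)
    return out


def apply_context_rules(
    resolved: Iterable[ResolvedHit],
    reg: Registry,
    features: Sequence[FeatureRecord] | None = None,
) -> list[ResolvedHit]:
    """Attribute ambiguous-family hits to pathways using gene neighbourhood.

    For a family with a ``default_unless_override`` rule, each hit supports the
    default pathway, plus every override pathway for which at least one *other*
    resolved enzyme of that pathway is found within the rule's window on the
    same replicon (whole-genome context when no feature table is given; this
    degradation is recorded in ``context_reason``). ``mode: all`` rules and
    un-ruled families leave attribution unrestricted.
    """
    resolved = list(resolved)
    pos = _neighbourhoods(features) if features else {}

    # family -> pathways(monosaccharides) whose routes use it
    fam_pathways: dict[str, set[str]] = {}
    for gid in reg.enzyme_families:
        fam_pathways[gid] = reg.monos_with_family(gid)

    out: list[ResolvedHit] = []
    for rh in resolved:
        rule = reg.context_rule_for(rh.resolved_gpe_id)
        if rule is None or rule.mode == "all":
            out.append(
                ResolvedHit(
                    rh.hit, rh.resolved_gpe_id, rh.resolution_reason,
                    rh.candidate_gpe_ids, allowed_pathways=None,
                    context_reason="all_pathways" if rule else None,
                )
            )
            continue
        allowed = derived_products(rule.default_pathway, reg)
        reasons = [f"default:{rule.default_pathway}"]
        for ov in rule.override_pathways:
            if _override_present(rh, ov, resolved, fam_pathways, rule, pos):
                allowed |= derived_products(ov, reg)
                reasons.append(f"override:{ov}")
        if features is None:
            reasons.append("whole_genome_context")
        out.append(
            ResolvedHit(
                rh.hit, rh.resolved_gpe_id, "context", rh.candidate_gpe_ids,
                allowed_pathways=frozenset(allowed), context_reason=";".join(reasons),
            )
        )
    return out


def _override_present(
    rh: ResolvedHit,
    pathway: str,
    resolved: Sequence[ResolvedHit],
    fam_pathways: Mapping[str, set[str]],
    rule: ContextRule,
    pos: Mapping[str, tuple[str, int]],
) -> bool:
    """Is another enzyme of ``pathway`` near this hit (same genome)?"""
    here = pos.get(rh.protein_id)
    for other in resolved:
        if other.genome_id != rh.genome_id or other.protein_id == rh.protein_id:
            continue
        if other.resolved_gpe_id == rh.resolved_gpe_id:
            continue  # another copy of the ambiguous family is not evidence
        if pathway not in fam_pathways.get(other.resolved_gpe_id, ()):
            continue
        if not pos or here is None:
            return True  # no feature table: whole-genome context
        there = pos.get(other.protein_id)
        if there is None:
            return True
        if there[0] == here[0] and abs(there[1] - here[1]) <= rule.window:
            return True
    return False


def audit_table(resolved: Sequence[ResolvedHit]) -> pd.DataFrame:
    """Per-protein audit of the resolution decisions (one row per protein)."""
    rows = []
    for rh in resolved:
        rows.append(
            {
                "genome_id": rh.genome_id,
                "protein_id": rh.protein_id,
                "candidates": ",".join(rh.candidate_gpe_ids),
                "winner": rh.resolved_gpe_id,
                "reason": rh.resolution_reason,
                "pathways": (
                    "*" if rh.allowed_pathways is None
                    else ",".join(sorted(rh.allowed_pathways))
                ),
                "context": rh.context_reason or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "protein_id", "candidates", "winner", "reason",
            "pathways", "context",
        ],
    )
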