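"""Curated knowledge base of nucleotide-sugar biosynthesis pathways.

The registry is the single source of truth the whole pipeline runs against:
which monosaccharides exist, through which nucleotide-activated forms they are
made, which enzyme families (profile-HMM or blastp-query detected) catalyse
each route step, which monosaccharide pairs are precursor/product related, and
which families need genomic-context disambiguation.

It is shipped as one human-editable YAML file and round-trips bit-exactly
through :func:`load_registry` / :meth:`Registry.dump`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "EnzymeFamily",
    "PathwayStep",
    "PathwayRoute",
    "NucleotideSugar",
    "Monosaccharide",
    "ContextRule",
    "Registry",
    "RegistryValidationError",
    "load_registry",
    "default_registry_path",
    "registry_summary",
    "precursor_closure_pairs",
]

GPE_ID_RE = re.compile(r"^GPE\d{5}$")

NUCLEOTIDES = ("ADP", "CDP", "CMP", "GDP", "TDP/dTDP", "UDP")
PRECURSORS = ("Glc-1-P", "Fruf-6-P", "GDP-Man", "UDP-Glc2NAc", "Glc2NAc-1-P", "Sed-7-P")
BACKBONES = ("pentose", "hexose", "heptulose", "nonulose")
THRESHOLD_METHODS = ("roc", "scatter", "t_exp", "t_extend", "manual")

# blastp defaults; per-family overrides live on the EnzymeFamily record
DEFAULT_BLAST_MIN_SIMILARITY = 30.0
DEFAULT_BLAST_MIN_COVERAGE = 90.0
# recorded search-invocation constant (hit tables are the input boundary)
BLASTP_WORD_SIZE = 2


class RegistryValidationError(ValueError):
    """Raised with *every* violation found, not just the first."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        msg = "registry validation failed with %d problem(s):\n" % len(self.problems)
        super().__init__(msg + "\n".join("  - " + p for p in self.problems))


@dataclass(frozen=True)
class EnzymeFamily:
    """One detection unit: a profile HMM or a set of blastp query sequences."""

    gpe_id: str
    annotation: str
    detection_mode: str  # "hmm_profile" | "blast_query"
    threshold_bits: float | None = None
    blast_min_similarity: float | None = None
    blast_min_coverage: float | None = None
    threshold_method: str | None = None
    specificity_class: str = "narrow"  # "narrow" | "broad"
    seed_count: int = 4
    broad_parent: str | None = None  # gpe_id of the broad profile built from a seed superset
    query_name: str | None = None  # human name for blast queries (e.g. "PdeG")

    @property
    def is_hmm(self) -> bool:
        return self.detection_mode == "hmm_profile"


@dataclass(frozen=True)
class PathwayStep:
    step_index: int  # 1-based position in the route
    families: frozenset[str]  # any one family satisfies the step


@dataclass(frozen=True)
class PathwayRoute:
    route_id: str
    nucleotide_sugar_id: str
    precursor: str
    steps: tuple[PathwayStep, ...]

    @property
    def family_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.steps:
            out |= s.families
        return frozenset(out)


@dataclass(frozen=True)
class NucleotideSugar:
    sugar_id: str
    monosaccharide_id: str
    nucleotide: str
    precursor: str  # primary precursor; individual routes may override
    routes: tuple[PathwayRoute, ...]


@dataclass(frozen=True)
class Monosaccharide:
    mono_id: str
    full_name: str
    short_name: str
    enantiomer: str  # "d" | "l"
    ring: str  # "pyranose" | "furanose"
    backbone: str
    nucleotide_sugars: frozenset[str]


@dataclass(frozen=True)
class ContextRule:
    """Disambiguation of a substrate-promiscuous family by gene neighbourhood.

    mode "default_unless_override": hits count for ``default_pathway`` always,
    and for an override pathway only when another enzyme of that pathway is in
    the neighbourhood (or anywhere in the genome when no feature table exists).
    mode "all": hits count for every pathway containing the family (documented
    over-call, e.g. the xylose / l-arabinose C4-epimerase caveat).
    """

    family: str
    mode: str = "default_unless_override"
    default_pathway: str | None = None
    override_pathways: tuple[str, ...] = ()
    window: int = 10  # gene-count radius defining "same neighbourhood"


@dataclass(frozen=True)
class Registry:
    monosaccharides: dict[str, Monosaccharide]
    nucleotide_sugars: dict[str, NucleotideSugar]
    enzyme_families: dict[str, EnzymeFamily]
    precursor_pairs: tuple[tuple[str, str], ...]  # (precursor mono, product mono)
    product_pairs: tuple[tuple[str, str], ...]  # co-called pairs sharing one pathway
    context_rules: tuple[ContextRule, ...]
    _raw: dict = field(default=None, repr=False, compare=False)

    # -- convenience lookups -------------------------------------------------
    def routes(self) -> Iterable[PathwayRoute]:
        for ns in self.nucleotide_sugars.values():
            yield from ns.routes

    def route_map(self) -> dict[str, PathwayRoute]:
        return {r.route_id: r for r in self.routes()}

    def hmm_families(self) -> dict[str, EnzymeFamily]:
        return {k: f for k, f in self.enzyme_families.items() if f.is_hmm}

    def blast_families(self) -> dict[str, EnzymeFamily]:
        return {k: f for k, f in self.enzyme_families.items() if not f.is_hmm}

    def family_by_query_name(self, name: str) -> EnzymeFamily:
        for f in self.enzyme_families.values():
            if f.query_name == name:
                return f
        raise KeyError(name)

    def sugars_of_mono(self, mono_id: str) -> list[NucleotideSugar]:
        return [
            self.nucleotide_sugars[s]
            for s in sorted(self.monosaccharides[mono_id].nucleotide_sugars)
        ]

    def monos_with_family(self, gpe_id: str) -> set[str]:
        """Monosaccharides having >=1 route containing the family in some step."""
        out = set()
        for ns in self.nucleotide_sugars.values():
            for r in ns.routes:
                if gpe_id in r.family_ids:
                    out.add(ns.monosaccharide_id)
        return out

    def context_rule_for(self, gpe_id: str) -> ContextRule | None:
        for cr in self.context_rules:
            if cr.family == gpe_id:
                return cr
        return None

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        if self._raw is not None:
            return self._raw
        raise NotImplementedError("registry was not built from a mapping")

    def dump(self, path: str | Path | None = None) -> str:
        """Serialize back to the canonical YAML text (bit-exact round-trip)."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def default_registry_path() -> Path:
    """Path of the registry packaged with glycoscan."""
    return Path(resources.files("glycoscan").joinpath("data/registry.yaml"))


def load_registry(path: str | Path | None = None) -> Registry:
    """Load and fully validate a registry file.

    Every schema or referential-integrity violation is collected and reported
    in a single :class:`RegistryValidationError`.
    """
    if path is None:
        path = default_registry_path()
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise RegistryValidationError(["registry file is empty or not a mapping"])
    return _build(raw)


def _build(raw: Mapping) -> Registry:
    problems: list[str] = []

    def need(mapping: Mapping, key: str, where: str, default=None):
        if key not in mapping:
            problems.append(f"{where}: missing required field '{key}'")
            return default
        return mapping[key]

    # enzyme families -------------------------------------------------------
    families: dict[str, EnzymeFamily] = {}
    for i, f in enumerate(raw.get("enzyme_families") or []):
        where = f"enzyme_families[{i}]"
        gid = need(f, "id", where, f"GPE<missing:{i}>")
        if not GPE_ID_RE.match(str(gid)):
            problems.append(f"{where}: id {gid!r} does not match 'GPE' + 5 digits")
        if gid in families:
            problems.append(f"{where}: duplicate family id {gid!r}")
        mode = need(f, "detection", where, "hmm_profile")
        thr = f.get("threshold_bits")
        sim = f.get("blast_min_similarity")
        cov = f.get("blast_min_coverage")
        if mode == "hmm_profile":
            if thr is None:
                problems.append(f"{where} ({gid}): hmm_profile family lacks threshold_bits")
            elif thr <= 0:
                problems.append(f"{where} ({gid}): threshold_bits must be > 0, got {thr}")
            if sim is not None or cov is not None:
                problems.append(f"{where} ({gid}): blast cutoffs set on an hmm_profile family")
            method = f.get("threshold_method")
            if method not in THRESHOLD_METHODS:
                problems.append(f"{where} ({gid}): bad threshold_method {method!r}")
        elif mode == "blast_query":
            if thr is not None:
                problems.append(f"{where} ({gid}): threshold_bits set on a blast_query family")
            sim = DEFAULT_BLAST_MIN_SIMILARITY if sim is None else float(sim)
            cov = DEFAULT_BLAST_MIN_COVERAGE if cov is None else float(cov)
            method = f.get("threshold_method")
        else:
            problems.append(f"{where} ({gid}): unknown detection mode {mode!r}")
            method = None
        seeds = f.get("seed_count", 4)
        if not isinstance(seeds, int) or seeds < 1:
            problems.append(f"{where} ({gid}): seed_count must be an integer >= 1")
        families[str(gid)] = EnzymeFamily(
            gpe_id=str(gid),
            annotation=str(need(f, "annotation", where, "")),
            detection_mode=str(mode),
            threshold_bits=None if mode != "hmm_profile" else (float(thr) if thr else None),
            blast_min_similarity=sim if mode == "blast_query" else None,
            blast_min_coverage=cov if mode == "blast_query" else None,
            threshold_method=method,
            specificity_class=f.get("specificity", "narrow"),
            seed_count=seeds if isinstance(seeds, int) else 1,
            broad_parent=f.get("broad_parent"),
            query_name=f.get("query_name"),
        )

    for fam in families.values():
        if fam.broad_parent is not None and fam.broad_parent not in families:
            problems.append(f"family {fam.gpe_id}: broad_parent {fam.broad_parent!r} unregistered")

    # nucleotide sugars + routes -------------------------------------------
    sugars: dict[str, NucleotideSugar] = {}
    for i, s in enumerate(raw.get("nucleotide_sugars") or []):
        where = f"nucleotide_sugars[{i}]"
        sid = str(need(s, "id", where, f"<missing:{i}>"))
        if sid in sugars:
            problems.append(f"{where}: duplicate nucleotide sugar id {sid!r}")
        nuc = need(s, "nucleotide", where)
        if nuc not in NUCLEOTIDES:
            problems.append(f"{where} ({sid}): unknown nucleotide {nuc!r}")
        prec = need(s, "precursor", where)
        if prec not in PRECURSORS:
            problems.append(f"{where} ({sid}): unknown precursor {prec!r}")
        routes: list[PathwayRoute] = []
        raw_routes = s.get("routes") or []
        if not raw_routes:
            problems.append(f"{where} ({sid}): every nucleotide sugar needs >= 1 route")
        for j, r in enumerate(raw_routes):
            rwhere = f"{where}.routes[{j}]"
            rid = str(r.get("id", f"{sid}.{j}"))
            rprec = r.get("precursor", prec)
            if rprec not in PRECURSORS:
                problems.append(f"{rwhere} ({rid}): unknown precursor {rprec!r}")
            steps: list[PathwayStep] = []
            raw_steps = r.get("steps") or []
            if not raw_steps:
                problems.append(f"{rwhere} ({rid}): route has no steps")
            for k, fams in enumerate(raw_steps, start=1):
                fams = [fams] if isinstance(fams, str) else list(fams)
                if not fams:
                    problems.append(f"{rwhere} ({rid}) step {k}: empty family set")
                for g in fams:
                    if g not in families:
                        problems.append(f"{rwhere} ({rid}) step {k}: unregistered family {g!r}")
                steps.append(PathwayStep(step_index=k, families=frozenset(map(str, fams))))
            routes.append(
                PathwayRoute(
                    route_id=rid, nucleotide_sugar_id=sid, precursor=str(rprec), steps=tuple(steps)
                )
            )
        sugars[sid] = NucleotideSugar(
            sugar_id=sid,
            monosaccharide_id=str(need(s, "monosaccharide", where, "")),
            nucleotide=str(nuc),
            precursor=str(prec),
            routes=tuple(routes),
        )

    # monosaccharides -------------------------------------------------------
    monos: dict[str, Monosaccharide] = {}
    sugar_by_mono: dict[str, set[str]] = {}
    for sid, s in sugars.items():
        sugar_by_mono.setdefault(s.monosaccharide_id, set()).add(sid)
    for i, m in enumerate(raw.get("monosaccharides") or []):
        where = f"monosaccharides[{i}]"
        mid = str(need(m, "id", where, f"<missing:{i}>"))
        if mid in monos:
            problems.append(f"{where}: duplicate monosaccharide id {mid!r}")
        for key, allowed in (("enantiomer", ("d", "l")), ("ring", ("pyranose", "furanose")),
                             ("backbone", BACKBONES)):
            if need(m, key, where) not in allowed:
                problems.append(f"{where} ({mid}): {key} must be one of {allowed}")
        linked = sugar_by_mono.get(mid, set())
        if not linked:
            problems.append(f"{where} ({mid}): no nucleotide sugar is linked to this monosaccharide")
        monos[mid] = Monosaccharide(
            mono_id=mid,
            full_name=str(m.get("full_name", mid)),
            short_name=str(need(m, "short_name", where, mid)),
            enantiomer=str(m.get("enantiomer", "d")),
            ring=str(m.get("ring", "pyranose")),
            backbone=str(m.get("backbone", "hexose")),
            nucleotide_sugars=frozenset(linked),
        )
    if not monos:
        problems.append("registry declares no monosaccharides")
    for mid in sugar_by_mono:
        if mid not in monos:
            problems.append(f"nucleotide sugars reference unknown monosaccharide {mid!r}")

    # pairs ------------------------------------------------------------------
    def _pairs(key: str) -> tuple[tuple[str, str], ...]:
        out = []
        for i, p in enumerate(raw.get(key) or []):
            if not (isinstance(p, (list, tuple)) and len(p) == 2):
                problems.append(f"{key}[{i}]: expected a 2-item pair, got {p!r}")
                continue
            a, b = map(str, p)
            for m in (a, b):
                if m not in monos:
                    problems.append(f"{key}[{i}]: unknown monosaccharide {m!r}")
            out.append((a, b))
        return tuple(out)

    precursor_pairs = _pairs("precursor_pairs")
    product_pairs = _pairs("product_pairs")

    # product pairs must share route structure up to the final divergent step
    for a, b in product_pairs:
        if a in monos and b in monos:
            ra = [r for s in sugar_by_mono.get(a, ()) for r in sugars[s].routes]
            rb = [r for s in sugar_by_mono.get(b, ()) for r in sugars[s].routes]
            shapes_a = {tuple(tuple(sorted(st.families)) for st in r.steps[:-1]) for r in ra}
            shapes_b = {tuple(tuple(sorted(st.families)) for st in r.steps[:-1]) for r in rb}
            if not shapes_a & shapes_b:
                problems.append(
                    f"product pair ({a}, {b}): no route pair shares structure up to the final step"
                )

    # precursor pairs must be acyclic (propagation iterates to a fixed point)
    adj: dict[str, set[str]] = {}
    for pre, prod in precursor_pairs:
        adj.setdefault(prod, set()).add(pre)  # edge product -> precursor
    seen: dict[str, int] = {}

    def _dfs(node: str, stack: set[str]) -> None:
        if node in stack:
            problems.append(f"precursor_pairs contain a cycle through {node!r}")
            return
        if seen.get(node):
            return
        seen[node] = 1
        for nxt in adj.get(node, ()):
            _dfs(nxt, stack | {node})

    for node in list(adj):
        _dfs(node, set())

    # context rules ----------------------------------------------------------
    rules: list[ContextRule] = []
    for i, c in enumerate(raw.get("context_rules") or []):
        where = f"context_rules[{i}]"
        fam = str(need(c, "family", where, ""))
        if fam not in families:
            problems.append(f"{where}: unregistered family {fam!r}")
        mode = c.get("mode", "default_unless_override")
        default = c.get("default_pathway")
        overrides = tuple(map(str, c.get("override_pathways") or ()))
        if mode == "default_unless_override":
            if default is None:
                problems.append(f"{where} ({fam}): default_pathway is required")
            elif default not in monos:
                problems.append(f"{where} ({fam}): unknown default_pathway {default!r}")
            for o in overrides:
                if o not in monos:
                    problems.append(f"{where} ({fam}): unknown override pathway {o!r}")
        elif mode != "all":
            problems.append(f"{where} ({fam}): unknown mode {mode!r}")
        rules.append(
            ContextRule(
                family=fam,
                mode=str(mode),
                default_pathway=None if default is None else str(default),
                override_pathways=overrides,
                window=int(c.get("window", 10)),
            )
        )

    if problems:
        raise RegistryValidationError(problems)

    return Registry(
        monosaccharides=monos,
        nucleotide_sugars=sugars,
        enzyme_families=families,
        precursor_pairs=precursor_pairs,
        product_pairs=product_pairs,
        context_rules=tuple(rules),
        _raw=dict(raw),
    )


# ---------------------------------------------------------------------------
# aggregate summary (the printed-table reproduction)
# ---------------------------------------------------------------------------

_SUMMARY_ROWS = (
    "nucleotide_sugars",
    "monosaccharides",
    "backbone:pentose",
    "backbone:hexose",
    "backbone:heptulose",
    "backbone:nonulose",
    "enantiomer:d",
    "enantiomer:l",
    "ring:pyranose",
    "ring:furanose",
    "nucleotide:ADP",
    "nucleotide:CDP",
    "nucleotide:CMP",
    "nucleotide:GDP",
    "nucleotide:TDP/dTDP",
    "nucleotide:UDP",
)


def registry_summary(reg: Registry) -> pd.DataFrame:
    """Per-precursor aggregate counts, one column per precursor plus totals.

    Nucleotide rows count nucleotide sugars; backbone / enantiomer / ring rows
    count monosaccharides. A sugar with routes from two precursors appears in
    both columns but only once in the distinct totals (printed footnote
    convention), so the grand total of sugars can be less than the row sum.
    """
    col_sugars: dict[str, set[str]] = {p: set() for p in PRECURSORS}
    for ns in reg.nucleotide_sugars.values():
        for r in ns.routes:
            col_sugars[r.precursor].add(ns.sugar_id)

    data: dict[str, dict[str, int]] = {p: {} for p in PRECURSORS}
    for p in PRECURSORS:
        sids = col_sugars[p]
        mids = {reg.nucleotide_sugars[s].monosaccharide_id for s in sids}
        d = data[p]
        d["nucleotide_sugars"] = len(sids)
        d["monosaccharides"] = len(mids)
        for bb in BACKBONES:
            d[f"backbone:{bb}"] = sum(1 for m in mids if reg.monosaccharides[m].backbone == bb)
        for e in ("d", "l"):
            d[f"enantiomer:{e}"] = sum(1 for m in mids if reg.monosaccharides[m].enantiomer == e)
        for r in ("pyranose", "furanose"):
            d[f"ring:{r}"] = sum(1 for m in mids if reg.monosaccharides[m].ring == r)
        for n in NUCLEOTIDES:
            d[f"nucleotide:{n}"] = sum(
                1 for s in sids if reg.nucleotide_sugars[s].nucleotide == n
            )

    df = pd.DataFrame(data, index=list(_SUMMARY_ROWS)).loc[:, list(PRECURSORS)]
    df["row_sum"] = df.sum(axis=1)
    distinct = pd.Series(0, index=df.index, dtype=int)
    distinct["nucleotide_sugars"] = len(reg.nucleotide_sugars)
    distinct["monosaccharides"] = len(reg.monosaccharides)
    for bb in BACKBONES:
        distinct[f"backbone:{bb}"] = sum(
            1 for m in reg.monosaccharides.values() if m.backbone == bb
        )
    for e in ("d", "l"):
        distinct[f"enantiomer:{e}"] = sum(
            1 for m in reg.monosaccharides.values() if m.enantiomer == e
        )
    for r in ("pyranose", "furanose"):
        distinct[f"ring:{r}"] = sum(1 for m in reg.monosaccharides.values() if m.ring == r)
    for n in NUCLEOTIDES:
        distinct[f"nucleotide:{n}"] = sum(
            1 for s in reg.nucleotide_sugars.values() if s.nucleotide == n
        )
    df["distinct_total"] = distinct
    return df


def write_summary_tsv(reg: Registry, path: str | Path) -> None:
    registry_summary(reg).to_csv(path, sep="\t")


def precursor_closure_pairs(reg: Registry) -> list[tuple[str, str]]:
    """The ordered (precursor, product) pair list, exactly as registered."""
    return list(reg.precursor_pairs)
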