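"""Parsing and filtering of homology-search outputs.

Reads HMMER3 per-sequence tables (``tblout`` / ``domtblout``), BLAST tabular
output (outfmt-6 style with a declared column order) and NCBI assembly feature
tables into typed records, and applies the per-family score / coverage
thresholds from the registry.

HMM hits are judged on the *best one domain* bit score, which is independent
of database size; blastp hits are judged on global-alignment style criteria
(query coverage and percent similarity). All threshold comparisons are
inclusive (``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from glycoscan.registry import Registry

__all__ = [
    "ProteinHit",
    "FeatureRecord",
    "HitTableError",
    "read_hmmer_table",
    "read_blast_table",
    "read_feature_table",
    "filter_hmm_hits",
    "filter_blast_hits",
]


class HitTableError(ValueError):
    """Malformed hit-table input; message carries the file and line number."""


@dataclass
class ProteinHit:
    """One homology-search match of a genome protein against one family."""

    genome_id: str
    protein_id: str
    gpe_id: str
    best1dom_bits: float | None = None
    full_bits: float | None = None
    evalue: float | None = None
    similarity_pct: float | None = None
    coverage_pct: float | None = None
    passes_threshold: bool = False


@dataclass(frozen=True)
class FeatureRecord:
    """Gene-order record for one CDS, used for neighbourhood context."""

    genome_id: str
    protein_id: str
    replicon_id: str
    ordinal_index: int  # 1-based gene order on the replicon, by genomic start
    strand: str


# ---------------------------------------------------------------------------
# HMMER tables
# ---------------------------------------------------------------------------

# whitespace-token counts before the free-text description column
_TBLOUT_FIELDS = 18
_DOMTBLOUT_FIELDS = 22

# Parsed by hand rather than through Bio.SearchIO: the tables must tolerate
# duplicate (protein, profile) rows (merged by max score), which SearchIO's
# container model rejects. The format is stable whitespace-delimited text.


def read_hmmer_table(
    path: str | Path, dialect: str = "tblout", genome_id: str | None = None
) -> list[ProteinHit]:
    """Parse an HMMER3 per-sequence (``tblout``) or per-domain (``domtblout``) table.

    Returns one :class:`ProteinHit` per (protein, profile) pair, keeping the
    best one-domain bit score when a pair appears on several rows. ``#``
    comment lines are ignored. Malformed rows raise :class:`HitTableError`
    naming the offending line.
    """
    if dialect not in ("tblout", "domtblout"):
        raise HitTableError(f"unknown HMMER dialect {dialect!r}")
    nfields = _TBLOUT_FIELDS if dialect == "tblout" else _DOMTBLOUT_FIELDS
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    best: dict[tuple[str, str], ProteinHit] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tok = line.split()
        if len(tok) < nfields:
            raise HitTableError(
                f"{path}:{lineno}: truncated {dialect} row "
                f"({len(tok)} fields, expected >= {nfields})"
            )
        try:
            if dialect == "tblout":
                protein, profile = tok[0], tok[2]
                full_e, full_bits = float(tok[4]), float(tok[5])
                b1_bits = float(tok[8])
            else:
                protein, profile = tok[0], tok[3]
                full_e, full_bits = float(tok[6]), float(tok[7])
                b1_bits = float(tok[13])  # this domain's score
        except ValueError as exc:
            raise HitTableError(f"{path}:{lineno}: unparsable numeric field ({exc})") from None
        key = (protein, profile)
        prev = best.get(key)
        if prev is None:
            best[key] = ProteinHit(
                genome_id=gid, protein_id=protein, gpe_id=profile,
                best1dom_bits=b1_bits, full_bits=full_bits, evalue=full_e,
            )
            order.append(key)
        elif b1_bits > prev.best1dom_bits:
            best[key] = replace(prev, best1dom_bits=b1_bits)
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

#: minimal columns for computing coverage when no explicit coverage column exists
_BLAST_BASE = ("qseqid", "sseqid", "ppos")


def read_blast_table(
    path: str | Path,
    columns: Sequence[str],
    genome_id: str | None = None,
    query_to_family: dict[str, str] | None = None,
) -> list[ProteinHit]:
    """Parse BLAST tabular output with a declared column order.

    ``columns`` names the fields in file order (outfmt-6 vocabulary). Required:
    ``qseqid`` (the characterized query enzyme), ``sseqid`` (genome protein)
    and ``ppos`` (percent positives, used as sequence similarity). Coverage is
    taken from a ``qcovs`` column when declared, otherwise computed as
    ``100 * length / qlen`` (query-side coverage) and clamped to 100. With
    several HSPs per (protein, query) pair the max-``bitscore`` HSP is kept.
    """
    path = Path(path)
    cols = list(columns)
    for c in _BLAST_BASE:
        if c not in cols:
            raise HitTableError(f"{path}: required BLAST column {c!r} not declared")
    has_qcovs = "qcovs" in cols
    if not has_qcovs and not ("length" in cols and "qlen" in cols):
        raise HitTableError(
            f"{path}: need either a 'qcovs' column or both 'length' and 'qlen'"
        )
    gid = genome_id if genome_id is not None else path.stem
    df = pd.read_csv(path, sep="\t", names=cols, comment="#", header=None)
    if df.empty:
        return []
    if has_qcovs:
        df["_cov"] = df["qcovs"].astype(float)
    else:
        df["_cov"] = 100.0 * df["length"].astype(float) / df["qlen"].astype(float)
        if (df["_cov"] > 100.0).any():
            import warnings

            warnings.warn(
                f"{path}: alignment longer than query on some rows; coverage clamped to 100",
                stacklevel=2,
            )
        df["_cov"] = df["_cov"].clip(upper=100.0)
    rank = df["bitscore"].astype(float) if "bitscore" in cols else df["ppos"].astype(float)
    df = df.assign(_rank=rank)
    idx = df.groupby(["sseqid", "qseqid"], sort=False)["_rank"].idxmax()
    df = df.loc[idx]
    q2f = query_to_family or {}
    hits: list[ProteinHit] = []
    for row in df.to_dict("records"):
        fam = q2f.get(str(row["qseqid"]), str(row["qseqid"]))
        hits.append(
            ProteinHit(
                genome_id=gid,
                protein_id=str(row["sseqid"]),
                gpe_id=fam,
                evalue=float(row["evalue"]) if "evalue" in cols else None,
                full_bits=float(row["bitscore"]) if "bitscore" in cols else None,
                similarity_pct=float(row["ppos"]),
                coverage_pct=float(row["_cov"]),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# NCBI feature tables
# ---------------------------------------------------------------------------

_FEATURE_COLS = ("feature", "genomic_accession", "start", "strand", "product_accession")


def read_feature_table(path: str | Path, genome_id: str | None = None) -> list[FeatureRecord]:
    """Parse an NCBI assembly ``*_feature_table.txt`` into CDS gene-order records.

    Only CDS rows are kept; ``ordinal_index`` numbers genes 1..n per replicon
    in order of genomic start coordinate.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("# ").strip() for c in df.columns]
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise HitTableError(
            f"{path}: feature table lacks expected column(s) {missing}; "
            f"expected at least {list(_FEATURE_COLS)}"
        )
    cds = df[df["feature"] == "CDS"].copy()
    cds = cds[cds["product_accession"].notna()]
    cds["start"] = cds["start"].astype(int)
    out: list[FeatureRecord] = []
    for replicon, grp in cds.groupby("genomic_accession", sort=False):
        grp = grp.sort_values("start", kind="mergesort")
        for i, row in enumerate(grp.itertuples(index=False), start=1):
            out.append(
                FeatureRecord(
                    genome_id=gid,
                    protein_id=str(row.product_accession),
                    replicon_id=str(replicon),
                    ordinal_index=i,
                    strand=str(row.strand),
                )
            )
    return out


# ---------------------------------------------------------------------------
# threshold filters
# ---------------------------------------------------------------------------


def filter_hmm_hits(hits: Iterable[ProteinHit], reg: Registry) -> list[ProteinHit]:
    """Set ``passes_threshold`` on HMM hits: best-1-domain bits >= family threshold."""
    out = []
    for h in hits:
        fam = reg.enzyme_families.get(h.gpe_id)
        if fam is None or not fam.is_hmm:
            raise KeyError(
                f"hit for {h.protein_id} targets {h.gpe_id!r}, which is not a "
                "registered hmm_profile family"
            )
        if h.best1dom_bits is None:
            raise HitTableError(f"hit for {h.protein_id} vs {h.gpe_id} lacks a bit score")
        out.append(replace(h, passes_threshold=h.best1dom_bits >= fam.threshold_bits))
    return out


def filter_blast_hits(hits: Iterable[ProteinHit], reg: Registry) -> list[ProteinHit]:
    """Set ``passes_threshold`` on blast hits: coverage AND similarity cutoffs met."""
    out = []
    for h in hits:
        fam = reg.enzyme_families.get(h.gpe_id)
        if fam is None or fam.is_hmm:
            raise KeyError(
                f"hit for {h.protein_id} targets {h.gpe_id!r}, which is not a "
                "registered blast_query family"
            )
        if h.similarity_pct is None or h.coverage_pct is None:
            raise HitTableError(
                f"hit for {h.protein_id} vs {h.gpe_id} lacks similarity/coverage"
            )
        ok = (
            h.coverage_pct >= fam.blast_min_coverage
            and h.similarity_pct >= fam.blast_min_similarity
        )
        out.append(replace(h, passes_threshold=ok))
    return out
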