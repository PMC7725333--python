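"""End-to-end orchestration: universe directory -> called alphabets.

Layout expected on disk (as written by :meth:`SyntheticUniverse.write`, and
matching what a practitioner would assemble from real hmmsearch/blastp runs):

    <dir>/genomes/<genome_id>/hits.tblout      HMMER3 per-sequence table
    <dir>/genomes/<genome_id>/hits.blast.tsv   BLAST tabular (declared columns)
    <dir>/genomes/<genome_id>/features.txt     NCBI feature table (optional)
    <dir>/taxonomy.tsv                         genome -> species/genus/phylum
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from glycoscan.calling import GenomeAlphabet, call_genome
from glycoscan.hits import (
    filter_blast_hits,
    filter_hmm_hits,
    read_blast_table,
    read_feature_table,
    read_hmmer_table,
)
from glycoscan.registry import Registry
from glycoscan.resolve import ResolvedHit, apply_context_rules, resolve_multi_profile
from glycoscan.simulate import SyntheticUniverse, blast_query_map

__all__ = ["scan_genome_dir", "call_universe_dir", "genome_dirs"]


def genome_dirs(universe_dir: str | Path) -> list[Path]:
    root = Path(universe_dir) / "genomes"
    if not root.is_dir():
        raise FileNotFoundError(f"no genomes/ directory under {universe_dir}")
    return sorted(p for p in root.iterdir() if p.is_dir())


def scan_genome_dir(
    gdir: Path, reg: Registry, use_features: bool = True
) -> list[ResolvedHit]:
    """Parse, filter, resolve and context-attribute one genome's hit tables."""
    gid = gdir.name
    hits = []
    tbl = gdir / "hits.tblout"
    if tbl.exists():
        hits += filter_hmm_hits(read_hmmer_table(tbl, "tblout", genome_id=gid), reg)
    bla = gdir / "hits.blast.tsv"
    if bla.exists():
        raw = read_blast_table(
            bla,
            columns=SyntheticUniverse.BLAST_COLUMNS,
            genome_id=gid,
            query_to_family=blast_query_map(reg),
        )
        hits += filter_blast_hits(raw, reg)
    resolved = resolve_multi_profile(hits, reg)
    feats = None
    ftab = gdir / "features.txt"
    if use_features and ftab.exists():
        feats = read_feature_table(ftab, genome_id=gid)
    return apply_context_rules(resolved, reg, feats)


def call_universe_dir(
    universe_dir: str | Path, reg: Registry, use_features: bool = True
) -> list[GenomeAlphabet]:
    """Call the glycan alphabet of every genome under a universe directory."""
    out = []
    for gdir in genome_dirs(universe_dir):
        attributed = scan_genome_dir(gdir, reg, use_features=use_features)
        out.append(call_genome(attributed, reg, gdir.name))
    return out
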