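"""Prevalence analytics over called glycan alphabets.

Aggregates per-genome presence/absence calls into prevalence groups (common /
less common / rare), per-species alphabet sizes and strain ranges, phylum
prevalence tables, co-occurrence counts, and the alphabet-size vs proteome-size
independence check.

Group cutoffs follow the published convention: common means found in >= 50 %
of genomes and rare means found in <= 10 %, both boundaries inclusive toward
their own group; everything between is less common.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycoscan.calling import GenomeAlphabet

__all__ = [
    "TaxonomyRecord",
    "PrevalenceRecord",
    "read_taxonomy",
    "prevalence_fractions",
    "classify_groups",
    "species_aggregate",
    "strain_range",
    "phylum_prevalence",
    "cooccurrence_pairs",
    "size_vs_proteome",
]

GROUP_HI = 0.50
GROUP_LO = 0.10


@dataclass(frozen=True)
class TaxonomyRecord:
    genome_id: str
    species: str
    genus: str
    phylum: str
    domain: str  # Archaea | Bacteria
    proteome_size: int = 0


@dataclass(frozen=True)
class PrevalenceRecord:
    mono_id: str
    n_genomes_present: int
    fraction: float
    group: str  # common | less_common | rare


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species", "genus", "phylum", "domain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: taxonomy table lacks column(s) {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        rec = TaxonomyRecord(
            genome_id=row.genome_id,
            species=row.species,
            genus=row.genus,
            phylum=row.phylum,
            domain=row.domain,
            proteome_size=int(getattr(row, "proteome_size", 0) or 0),
        )
        if rec.genome_id in out:
            raise ValueError(f"{path}: duplicate genome_id {rec.genome_id!r}")
        out[rec.genome_id] = rec
    return out


def prevalence_fractions(matrix: pd.DataFrame) -> pd.Series:
    """Fraction of genomes containing each monosaccharide (matrix rows = genomes)."""
    if matrix.empty:
        raise ValueError("empty presence/absence matrix")
    return matrix.mean(axis=0)


def classify_groups(
    fractions: Mapping[str, float] | pd.Series,
    n_genomes: int | None = None,
    hi: float = GROUP_HI,
    lo: float = GROUP_LO,
) -> list[PrevalenceRecord]:
    """Assign each monosaccharide to common / less_common / rare.

    ``fraction >= hi`` -> common; ``fraction <= lo`` -> rare; otherwise
    less_common. Both printed boundaries are inclusive toward their own group.
    """
    if hi <= lo:
        raise ValueError(f"group cutoffs must satisfy hi > lo, got hi={hi}, lo={lo}")
    fr = pd.Series(fractions, dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("prevalence fractions must lie in [0, 1]")
    out = []
    for mono, f in fr.items():
        group = "common" if f >= hi else ("rare" if f <= lo else "less_common")
        n = int(round(f * n_genomes)) if n_genomes else 0
        out.append(PrevalenceRecord(str(mono), n, float(f), group))
    return out


def _sizes_by_species(
    alphabets: Sequence[GenomeAlphabet],
    taxonomy: Mapping[str, TaxonomyRecord],
) -> dict[str, list[tuple[str, int]]]:
    """species -> [(genome_id, alphabet size)]; missing taxonomy -> 'unassigned'."""
    out: dict[str, list[tuple[str, int]]] = {}
    for ga in alphabets:
        rec = taxonomy.get(ga.genome_id)
        species = rec.species if rec is not None else "unassigned"
        out.setdefault(species, []).append((ga.genome_id, len(ga.present)))
    return out


def species_aggregate(
    alphabets: Sequence[GenomeAlphabet],
    taxonomy: Mapping[str, TaxonomyRecord],
    include_zero: bool = True,
) -> pd.DataFrame:
    """Per species, the max alphabet size over its strains and the arg-max genome.

    Genomes without a taxonomy record are bucketed under species
    ``"unassigned"`` rather than silently dropped. ``include_zero=False``
    drops species whose best strain has no monosaccharide at all.
    """
    rows = []
    for species, members in sorted(_sizes_by_species(alphabets, taxonomy).items()):
        gid, size = max(members, key=lambda t: (t[1], t[0]))
        rows.append({"species": species, "max_size": size, "best_genome": gid,
                     "n_strains": len(members)})
    df = pd.DataFrame(rows, columns=["species", "max_size", "best_genome", "n_strains"])
    if not include_zero:
        df = df[df["max_size"] > 0].reset_index(drop=True)
    return df


def strain_range(
    alphabets: Sequence[GenomeAlphabet],
    taxonomy: Mapping[str, TaxonomyRecord],
) -> pd.DataFrame:
    """Per-species (min, max) alphabet sizes over strains.

    Only species with more than one sequenced strain and at least one
    monosaccharide predicted in one of the strains qualify.
    """
    rows = []
    for species, members in sorted(_sizes_by_species(alphabets, taxonomy).items()):
        sizes = [s for _, s in members]
        if len(sizes) < 2 or max(sizes) == 0:
            continue
        rows.append(
            {"species": species, "n_strains": len(sizes),
             "min_size": min(sizes), "max_size": max(sizes)}
        )
    return pd.DataFrame(rows, columns=["species", "n_strains", "min_size", "max_size"])


def phylum_prevalence(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyRecord],
    min_genomes: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phylum x monosaccharide prevalence fractions.

    Returns ``(rendered, raw)``: phyla with fewer than ``min_genomes`` genomes
    are excluded from the rendered table but kept in the raw one.
    """
    phyla = pd.Series(
        {g: taxonomy[g].phylum if g in taxonomy else "unassigned" for g in matrix.index}
    )
    raw = matrix.groupby(phyla).mean()
    counts = matrix.groupby(phyla).size()
    raw.index.name = "phylum"
    rendered = raw.loc[counts[counts >= min_genomes].index]
    return rendered, raw


def cooccurrence_pairs(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyRecord],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Genome counts containing both members of each pair, with taxon breakdown."""
    rows = []
    for a, b in pairs:
        for m in (a, b):
            if m not in matrix.columns:
                raise KeyError(f"monosaccharide {m!r} not in presence matrix")
        both = matrix.index[(matrix[a] == 1) & (matrix[b] == 1)]
        phyla = sorted({taxonomy[g].phylum for g in both if g in taxonomy})
        rows.append(
            {"pair": f"{a}+{b}", "n_genomes": int(len(both)),
             "phyla": ",".join(phyla)}
        )
    return pd.DataFrame(rows, columns=["pair", "n_genomes", "phyla"])


def size_vs_proteome(
    alphabets: Sequence[GenomeAlphabet],
    taxonomy: Mapping[str, TaxonomyRecord],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Alphabet size vs proteome size with Spearman rho and a permutation p-value.

    Degenerate inputs (either variable constant) report rho = 0, p = 1.
    """
    rows = [
        {
            "genome_id": ga.genome_id,
            "proteome_size": taxonomy[ga.genome_id].proteome_size,
            "alphabet_size": len(ga.present),
        }
        for ga in alphabets
        if ga.genome_id in taxonomy
    ]
    df = pd.DataFrame(rows, columns=["genome_id", "proteome_size", "alphabet_size"])
    x = df["proteome_size"].to_numpy(float)
    y = df["alphabet_size"].to_numpy(float)
    if len(df) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return df, 0.0, 1.0
    rho = float(stats.spearmanr(x, y).statistic)
    # permutation null: Spearman rho is Pearson on ranks, so shuffle the rank
    # vector and correlate in one vectorized pass
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = (rx - rx.mean()) / rx.std()
    ryc = (ry - ry.mean()) / ry.std()
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = float(np.mean(rxc * rng.permutation(ryc)))
    p = float((np.sum(np.abs(perm) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    return df, rho, p
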