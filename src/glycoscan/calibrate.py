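"""Bit-score threshold calibration for enzyme-family profiles.

Three procedures are provided, mirroring how family thresholds are set in
practice:

* ROC sweep against a reference database whose annotations are taken as
  ground truth, with an operating point chosen by a stated criterion
  (default: maximum Matthews correlation, ties resolved toward the most
  stringent threshold);
* bit-score scatter partitioning for pairs of homologous sibling profiles
  whose database annotations are too incomplete for a ROC curve;
* seed self-score thresholds T_exp / T_extend — the minimum self-score of the
  experimentally characterized seed set, or of the extended homologue set.

A "largest score gap" mode is also available for families whose matching-
annotation scores are discontinuous (the threshold is put at the bottom edge
of the upper score block).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedScore",
    "SeedScores",
    "RocPoint",
    "roc_curve",
    "choose_threshold",
    "largest_gap_threshold",
    "scatter_partition",
    "ScatterResult",
    "seed_threshold",
    "read_annotated_scores",
]


@dataclass(frozen=True)
class AnnotatedScore:
    sequence_id: str
    score_bits: float
    db_annotation_matches_profile: bool


@dataclass(frozen=True)
class SeedScores:
    gpe_id: str
    exp_scores: tuple[float, ...]  # self-scores of experimentally characterized seeds
    extend_scores: tuple[float, ...] | None = None  # extended dataset, may be absent


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tpr: float
    fpr: float
    precision: float
    tp: int
    fp: int
    fn: int
    tn: int


def read_annotated_scores(path: str | Path, profile_key: str) -> list[AnnotatedScore]:
    """TSV of (sequence_id, score_bits, annotation_key) -> labelled scores.

    A sequence is a positive iff its normalized annotation key equals the
    profile's; the reference annotations are assumed correct.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "annotation_key": str})
    for c in ("sequence_id", "score_bits", "annotation_key"):
        if c not in df.columns:
            raise ValueError(f"{path}: annotated-score table lacks column {c!r}")
    return [
        AnnotatedScore(r.sequence_id, float(r.score_bits), r.annotation_key == profile_key)
        for r in df.itertuples(index=False)
    ]


def roc_curve(scores: Sequence[AnnotatedScore]) -> list[RocPoint]:
    """One confusion-matrix point per distinct score value, by descending sweep.

    A sequence is predicted positive iff its score >= the candidate threshold
    (inclusive, matching the filtering convention). Points are returned in
    ascending threshold order, so TPR and FPR are non-increasing along the
    list.
    """
    y = np.array([s.db_annotation_matches_profile for s in scores], dtype=bool)
    x = np.array([s.score_bits for s in scores], dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes: got {n_pos} positives and {n_neg} negatives"
        )
    points = []
    for t in np.unique(x):  # ascending distinct thresholds
        pred = x >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        points.append(
            RocPoint(
                threshold=float(t),
                tpr=tp / n_pos,
                fpr=fp / n_neg,
                precision=tp / (tp + fp) if tp + fp else 1.0,
                tp=tp, fp=fp, fn=fn, tn=tn,
            )
        )
    return points


def _mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _f1(tp: int, fp: int, fn: int, tn: int) -> float:
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def _youden(tp: int, fp: int, fn: int, tn: int) -> float:
    return tp / (tp + fn) - fp / (fp + tn)


_CRITERIA = {"max_mcc": _mcc, "max_f1": _f1, "youden": _youden}


def choose_threshold(points: Sequence[RocPoint], criterion: str = "max_mcc") -> float:
    """Operating point maximizing the criterion; ties go to the *highest*
    threshold (most stringent), reflecting the conservative calling policy."""
    try:
        fn = _CRITERIA[criterion]
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; one of {sorted(_CRITERIA)}"
        ) from None
    best = max(fn(p.tp, p.fp, p.fn, p.tn) for p in points)
    eps = 1e-12
    return max(p.threshold for p in points if fn(p.tp, p.fp, p.fn, p.tn) >= best - eps)


def largest_gap_threshold(scores: Iterable[float]) -> float:
    """Bottom edge of the score block above the largest gap.

    For score sets that fall in discontinuous blocks (e.g. 705..303 then
    57..41 bits), the threshold is the smallest score of the upper block.
    """
    xs = np.unique(np.asarray(list(scores), dtype=float))
    if len(xs) < 2:
        raise ValueError("need at least two distinct scores to find a gap")
    gaps = np.diff(xs)
    i = int(np.argmax(gaps))
    return float(xs[i + 1])


# ---------------------------------------------------------------------------
# scatter partitioning for sibling profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScatterResult:
    threshold_a: float
    threshold_b: float
    separable_a: bool  # clean inter-cloud gap along the profile-A axis
    separable_b: bool
    #: full scatter data for curator review (the decision is manual practice)
    table: pd.DataFrame = None
    curator_review: bool = True


def _axis_threshold(self_scores: np.ndarray, cross_scores: np.ndarray) -> tuple[float, bool]:
    """Threshold separating the self cloud (above) from the cross cloud (below).

    With a clean gap the threshold sits at the gap midpoint; with overlap it
    is the value minimizing misclassification, ties toward the more stringent
    (higher) cut, and the axis is flagged non-separable.
    """
    lo, hi = float(np.max(cross_scores)), float(np.min(self_scores))
    if hi > lo:
        return (lo + hi) / 2.0, True
    candidates = np.unique(np.concatenate([self_scores, cross_scores]))
    best_t, best_err = None, None
    for t in candidates:
        err = int(np.sum(self_scores < t)) + int(np.sum(cross_scores >= t))
        if best_err is None or err < best_err or (err == best_err and t > best_t):
            best_t, best_err = float(t), err
    return best_t, False


def scatter_partition(
    points_a: np.ndarray, points_b: np.ndarray
) -> ScatterResult:
    """Per-profile thresholds from a two-profile bit-score scatter.

    ``points_a`` are (score_vs_A, score_vs_B) rows for sequences of family A,
    ``points_b`` likewise for family B. The profile-A threshold separates the
    A cloud from the B cloud along the score-vs-A axis (and symmetrically for
    B), maximizing the inter-cloud margin. Identical clouds raise an error.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    for name, arr in (("A", a), ("B", b)):
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError(f"cloud {name} needs >= 2 sequences with 2 scores each")
    if a.shape == b.shape and np.allclose(np.sort(a, axis=0), np.sort(b, axis=0)):
        raise ValueError("the two score clouds are identical; scatter cannot partition them")
    ta, sep_a = _axis_threshold(a[:, 0], b[:, 0])
    tb, sep_b = _axis_threshold(b[:, 1], a[:, 1])
    table = pd.DataFrame(
        np.vstack([a, b]),
        columns=["score_vs_a", "score_vs_b"],
    )
    table["family"] = ["A"] * len(a) + ["B"] * len(b)
    return ScatterResult(
        threshold_a=ta, threshold_b=tb, separable_a=sep_a, separable_b=sep_b,
        table=table,
    )


# ---------------------------------------------------------------------------
# seed self-score thresholds
# ---------------------------------------------------------------------------


def seed_threshold(seeds: SeedScores, mode: str = "t_exp") -> float:
    """T_exp / T_extend: minimum self-score of the requested seed set."""
    if mode == "t_exp":
        if not seeds.exp_scores:
            raise ValueError(f"{seeds.gpe_id}: no experimental seed scores")
        return float(min(seeds.exp_scores))
    if mode == "t_extend":
        if not seeds.extend_scores:
            raise ValueError(
                f"{seeds.gpe_id}: no extended dataset exists for this profile"
            )
        return float(min(seeds.extend_scores))
    raise ValueError(f"unknown seed-threshold mode {mode!r}")
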