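"""Phonological (acoustic-feature) variability analysis.

Summarizes how variable a bird's syllable *phonology* — the spectral
structure of individual syllables — is across renditions, via the
coefficient of variation (CV = SD / mean over ~25 renditions of the same
syllable), and aggregates all-vs-all similarity/accuracy score batches of
the kind produced by spectrogram-comparison software.

Also provides a deliberately simplified feature-trajectory similarity
scorer: syllables are represented by per-frame acoustic features (pitch,
FM, Wiener entropy, pitch goodness); similarity is derived from scaled
Euclidean distances between 70 ms windows (best-match search in
asymmetric mode) and accuracy from frame-by-frame 9 ms comparisons.  It
captures the qualitative behaviour — identical sounds score 100, noisier
pairs score lower, time-shifted copies score higher under asymmetric
comparison — without replicating any proprietary calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import FEATURE_COLUMNS

__all__ = [
    "FeatureTrajectory",
    "ScoreMatrix",
    "ScoreBatchSummary",
    "StabilizationResult",
    "TRAJECTORY_FEATURES",
    "feature_summary",
    "aggregate_cv",
    "aggregate_scores",
    "identity_score",
    "mad_scale",
    "trajectory_similarity",
    "stabilize_sample_count",
]

#: Features entering the trajectory-distance computation.
TRAJECTORY_FEATURES = ["pitch", "FM", "wiener_entropy", "pitch_goodness"]

#: Local-score decay constant: a mean scaled distance of 1 scores 50.
DEFAULT_TAU = 1.0 / math.log(2.0)


def feature_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-syllable, per-condition variability summary of acoustic features.

    For each (bird, syllable, condition, feature) computes the mean, sample
    SD (n-1 denominator), SE = SD/sqrt(n) and CV = SD/|mean| over the
    renditions.  CV is reported as missing (with a warning) when the
    feature mean is zero.

    Returns a long-format frame with columns
    ``bird, syllable, condition, feature, mean, sd, se, cv, n_renditions``.
    """
    rows = []
    zero_mean = []
    for (bird, syl, cond), grp in table.groupby(
        ["bird", "syllable", "condition"], sort=True
    ):
        n = len(grp)
        if n < 2:
            raise ValueError(
                f"need >= 2 renditions for ({bird}, {syl}, {cond}); got {n}"
            )
        for feat in FEATURE_COLUMNS:
            vals = grp[feat].to_numpy(dtype=float)
            mean = vals.mean()
            sd = vals.std(ddof=1)
            if mean == 0:
                cv = np.nan
                zero_mean.append((bird, syl, cond, feat))
            else:
                cv = sd / abs(mean)
            rows.append(
                {
                    "bird": bird,
                    "syllable": syl,
                    "condition": cond,
                    "feature": feat,
                    "mean": mean,
                    "sd": sd,
                    "se": sd / math.sqrt(n),
                    "cv": cv,
                    "n_renditions": n,
                }
            )
    if zero_mean:
        warnings.warn(
            f"CV undefined (zero mean) for {len(zero_mean)} feature group(s)",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def aggregate_cv(summaries: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate per-syllable CVs to group means with SE.

    Two aggregation levels, chosen in practice by a bootstrap ANOVA on the
    independent-variable question (does bird or syllable drive the CVs?):

    * ``"per_bird_then_group"`` — average CVs within each bird first, then
      average the per-bird means (bird is the unit).
    * ``"per_syllable"`` — average over all syllables, ignoring which bird
      sang them (syllable is the unit).

    Returns one row per (condition, feature): ``mean_cv, se, n_units``.
    """
    if summaries.empty:
        raise ValueError("no summaries to aggregate")
    if level == "per_bird_then_group":
        per_bird = (
            summaries.groupby(["condition", "feature", "bird"])["cv"]
            .mean()
            .reset_index()
        )
        grouped = per_bird.groupby(["condition", "feature"])["cv"]
    elif level == "per_syllable":
        grouped = summaries.groupby(["condition", "feature"])["cv"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    out = grouped.agg(
        mean_cv="mean",
        se=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
        n_units="count",
    ).reset_index()
    return out


@dataclass
class ScoreMatrix:
    """All-vs-all pairwise comparison scores for a batch of song items.

    ``similarity[i, j]`` (and optionally ``accuracy[i, j]``) is the score
    of comparing item i against item j on the 0-100 scale.  The diagonal
    holds self-comparisons and is excluded from every aggregate.
    """

    similarity: np.ndarray
    accuracy: Optional[np.ndarray] = None
    unit: str = "motif"          # motif | clip | syllable
    mode: str = "asymmetric"     # asymmetric | symmetric
    items: Optional[list] = None

    def __post_init__(self) -> None:
        self.similarity = np.asarray(self.similarity, dtype=float)
        if self.similarity.ndim != 2 or self.similarity.shape[0] != self.similarity.shape[1]:
            raise ValueError("similarity must be a square matrix")
        if self.accuracy is not None:
            self.accuracy = np.asarray(self.accuracy, dtype=float)
            if self.accuracy.shape != self.similarity.shape:
                raise ValueError("accuracy shape must match similarity")
        for name, arr in (("similarity", self.similarity), ("accuracy", self.accuracy)):
            if arr is not None:
                off = arr[~np.eye(arr.shape[0], dtype=bool)]
                if np.nanmin(off) < 0 or np.nanmax(off) > 100:
                    raise ValueError(f"{name} scores must lie in [0, 100]")

    @property
    def m(self) -> int:
        return self.similarity.shape[0]


@dataclass
class ScoreBatchSummary:
    n_scores: int
    similarity_mean: float
    similarity_se: float
    accuracy_mean: Optional[float] = None
    accuracy_se: Optional[float] = None


def aggregate_scores(matrix: ScoreMatrix) -> ScoreBatchSummary:
    """Mean and SE of the off-diagonal scores of an all-vs-all batch.

    An m-item batch yields exactly ``m**2 - m`` scores (self-comparisons
    excluded): 20 motifs give 380 scores, 30 clips give 870.
    """
    m = matrix.m
    if m < 2:
        raise ValueError("need at least 2 items")
    off = ~np.eye(m, dtype=bool)
    n = m * m - m

    def _stats(arr: np.ndarray) -> tuple[float, float]:
        vals = arr[off]
        return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n))

    sim_mean, sim_se = _stats(matrix.similarity)
    acc_mean = acc_se = None
    if matrix.accuracy is not None:
        acc_mean, acc_se = _stats(matrix.accuracy)
    return ScoreBatchSummary(
        n_scores=n,
        similarity_mean=sim_mean,
        similarity_se=sim_se,
        accuracy_mean=acc_mean,
        accuracy_se=acc_se,
    )


def identity_score(similarity, accuracy):
    """Identity = similarity x accuracy / 100, on the 0-100 scale.

    Applied per comparison *before* any averaging; the mean of identities
    is not the product of mean similarity and mean accuracy.
    """
    sim = np.asarray(similarity, dtype=float)
    acc = np.asarray(accuracy, dtype=float)
    if np.any((sim < 0) | (sim > 100)) or np.any((acc < 0) | (acc > 100)):
        raise ValueError("similarity and accuracy must lie in [0, 100]")
    out = sim * acc / 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureTrajectory:
    """Per-frame acoustic features of one song item.

    ``frame_ms`` is the frame period; pitch (Hz), FM, Wiener entropy and
    pitch goodness are equal-length per-frame series.
    """

    pitch: np.ndarray
    fm: np.ndarray
    wiener_entropy: np.ndarray
    pitch_goodness: np.ndarray
    frame_ms: float = 9.0

    def __post_init__(self) -> None:
        arrs = [
            np.asarray(a, dtype=float)
            for a in (self.pitch, self.fm, self.wiener_entropy, self.pitch_goodness)
        ]
        lengths = {len(a) for a in arrs}
        if len(lengths) != 1 or 0 in lengths:
            raise ValueError("feature series must be non-empty and equal length")
        self.pitch, self.fm, self.wiener_entropy, self.pitch_goodness = arrs

    def stacked(self) -> np.ndarray:
        """(n_frames, 4) feature array."""
        return np.column_stack(
            [self.pitch, self.fm, self.wiener_entropy, self.pitch_goodness]
        )

    @property
    def n_frames(self) -> int:
        return len(self.pitch)


def mad_scale(trajectories: Sequence[FeatureTrajectory]) -> np.ndarray:
    """Per-feature median absolute deviation over a pooled comparison set.

    Used to put the four trajectory features on a common scale before
    computing distances; zero MADs (constant features) fall back to 1.
    """
    pooled = np.vstack([t.stacked() for t in trajectories])
    med = np.median(pooled, axis=0)
    mad = np.median(np.abs(pooled - med), axis=0)
    mad[mad == 0] = 1.0
    return mad


def _frame_distances(a: FeatureTrajectory, b: FeatureTrajectory, scale: np.ndarray) -> np.ndarray:
    """(na, nb) matrix of scaled Euclidean frame distances."""
    xa = a.stacked() / scale
    xb = b.stacked() / scale
    diff = xa[:, None, :] - xb[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def trajectory_similarity(
    a: FeatureTrajectory,
    b: FeatureTrajectory,
    mode: str = "asymmetric",
    scale: Optional[np.ndarray] = None,
    window_ms: float = 70.0,
    tau: float = DEFAULT_TAU,
) -> tuple[float, float]:
    """Similarity and accuracy of two feature trajectories, each in [0, 100].

    A local (single 9 ms frame) score is ``100 * exp(-d / tau)`` with
    ``d`` the per-feature-scaled Euclidean distance; **accuracy** is the
    mean local score over aligned frames.  **Similarity** averages window
    scores over consecutive ``window_ms`` (default 70 ms) windows, where a
    window's score uses the mean frame distance within it: in
    ``"symmetric"`` mode windows are compared at the same position; in
    ``"asymmetric"`` mode each window of ``a`` is matched against the best
    window offset anywhere in ``b`` — comparing the most similar sound
    elements independent of their position, so a time-shifted copy still
    scores high.

    ``scale`` defaults to the pooled MAD of the two inputs; ``tau`` is
    calibrated so a mean scaled distance of 1 scores 50.
    """
    if mode not in ("asymmetric", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    if scale is None:
        scale = mad_scale([a, b])
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale factors must be > 0")

    dists = _frame_distances(a, b, scale)
    na, nb = dists.shape

    # accuracy: frame-by-frame over the aligned overlap
    n_aligned = min(na, nb)
    aligned = np.diagonal(dists)[:n_aligned]
    accuracy = float(np.mean(100.0 * np.exp(-aligned / tau)))

    # similarity: consecutive windows of a, each scored vs b
    w = max(1, int(round(window_ms / a.frame_ms)))
    span = n_aligned if mode == "symmetric" else na
    win_scores = []
    for s in range(0, span, w):
        e = min(s + w, span)
        length = e - s
        if mode == "symmetric":
            # same-position frames only
            mean_d = float(np.mean([dists[i, i] for i in range(s, e)]))
        else:
            if nb < length:
                mean_d = np.mean([dists[s + k, min(k, nb - 1)] for k in range(length)])
            else:
                offsets = nb - length + 1
                cand = np.empty(offsets)
                for o in range(offsets):
                    cand[o] = np.mean(
                        [dists[s + k, o + k] for k in range(length)]
                    )
                mean_d = cand.min()
        win_scores.append(100.0 * math.exp(-mean_d / tau))
    if not win_scores:
        raise ValueError("no comparable windows between trajectories")
    similarity = float(np.mean(win_scores))
    return similarity, accuracy


@dataclass
class StabilizationResult:
    n: int
    stabilized: bool
    trace: pd.DataFrame  # columns: n, similarity_mean, accuracy_mean


def stabilize_sample_count(
    items: Sequence,
    score_fn: Callable,
    start: int = 10,
    step: int = 5,
    tol: float = 0.5,
    consecutive: int = 2,
) -> StabilizationResult:
    """Find the minimum sample count with stable mean batch scores.

    Grows the batch from ``start`` items in increments of ``step``,
    computing the all-vs-all (off-diagonal) mean similarity and accuracy
    each time, and returns the smallest n after which the next
    ``consecutive`` increments each change both means by less than
    ``tol`` score units.  If the means never settle before the items are
    exhausted, all items are used and a warning is issued.

    ``score_fn(item_i, item_j) -> (similarity, accuracy)``.
    """
    n_items = len(items)
    if n_items < start:
        raise ValueError(f"need at least {start} items; got {n_items}")
    if step < 1 or tol <= 0:
        raise ValueError("step must be >= 1 and tol > 0")

    cache: dict = {}

    def pair(i: int, j: int):
        if (i, j) not in cache:
            cache[(i, j)] = score_fn(items[i], items[j])
        return cache[(i, j)]

    def batch_means(n: int) -> tuple[float, float]:
        sims, accs = [], []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                s, a = pair(i, j)
                sims.append(s)
                accs.append(a)
        return float(np.mean(sims)), float(np.mean(accs))

    ns = list(range(start, n_items + 1, step))
    trace = [(n, *batch_means(n)) for n in ns]
    trace_df = pd.DataFrame(trace, columns=["n", "similarity_mean", "accuracy_mean"])

    for idx in range(len(trace) - consecutive):
        ok = True
        for k in range(consecutive):
            _, s0, a0 = trace[idx + k]
            _, s1, a1 = trace[idx + k + 1]
            if abs(s1 - s0) >= tol or abs(a1 - a0) >= tol:
                ok = False
                break
        if ok:
            return StabilizationResult(n=trace[idx][0], stabilized=True, trace=trace_df)

    warnings.warn(
        "batch means did not stabilize before items were exhausted; "
        f"using all {n_items} items",
        stacklevel=2,
    )
    return StabilizationResult(n=n_items, stabilized=False, trace=trace_df)
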