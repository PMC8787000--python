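"""Score coupling, ROC metrics, and the search-space-reduction readout.

The clinical question is not "is each patch classified correctly" but "how
much of the abdominopelvic volume must a radiologist inspect to find the
transition zone with a given risk of missing it". Accordingly, besides
AUROC/precision, this module builds the trade-off curve between the
patch-level false-negative rate and the mean highlighted-volume fraction,
for raw classifier scores and for scores coupled (multiplied) with the
spatial patch prior.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .patches import PatchGrid
from .prior import PatchPrior, assign_region

__all__ = [
    "ScoreMap",
    "ROCResult",
    "EvalCurve",
    "UndefinedMetricError",
    "couple_scores",
    "auroc_score",
    "auroc",
    "precision_at_threshold",
    "youden_threshold",
    "highlight_patches",
    "volume_vs_fn_curve",
    "volume_at_fn",
    "expected_false_positives",
    "region_auroc",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. precision with no
    predicted positives) — signaled, never silently reported as 0."""


@dataclass(frozen=True)
class ScoreMap:
    """Per-patch classifier output for one scan, in grid order."""

    k: int
    scores: np.ndarray
    coupled: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (self.k ** 3,):
            raise ValueError(f"score map must have k^3 = {self.k ** 3} entries")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)


@dataclass(frozen=True)
class ROCResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class EvalCurve:
    """(threshold, patch-level FN rate, mean highlighted-volume fraction)."""

    thresholds: np.ndarray
    fn_rate: np.ndarray
    volume_fraction: np.ndarray


def couple_scores(raw: ScoreMap, prior: PatchPrior) -> ScoreMap:
    """Multiply classifier scores elementwise by the spatial patch prior."""
    if raw.k != prior.k:
        raise ValueError(f"score map k={raw.k} does not match prior k={prior.k}")
    return ScoreMap(k=raw.k, scores=raw.scores * prior.prob, coupled=True)


def auroc_score(scores, labels) -> float:
    """AUROC via the Mann-Whitney pair-concordance statistic (ties = 1/2)."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auroc(scores, labels, n_bootstrap: int = 2000, seed: int = 0) -> ROCResult:
    """Point AUROC plus a percentile-bootstrap confidence interval."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    point = auroc_score(s, y)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xB007])
    stats = []
    n = s.size
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue  # degenerate resample carries no ranking information
        stats.append(auroc_score(s[idx], yb))
    if stats:
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        lo = hi = point
    return ROCResult(
        auroc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_pos=int(y.sum()),
        n_neg=int(y.size - y.sum()),
    )


def precision_at_threshold(scores, labels, threshold: float) -> float:
    """TP / (TP + FP) among patches scoring >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    predicted = s >= threshold
    if not predicted.any():
        raise UndefinedMetricError("no patch passes the threshold; precision undefined")
    return float(np.sum(predicted & y) / np.sum(predicted))


def youden_threshold(scores, labels) -> float:
    """Lowest threshold maximizing the Youden index (sens + spec - 1).

    Candidates are midpoints of consecutive sorted unique scores plus the
    extremes (0 and just above the maximum score); highlighting uses
    ``score >= threshold``. The lowest optimum is returned, favoring
    sensitivity (not missing a TZ) among ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (y.any() and (~y).any()):
        raise ValueError("Youden threshold needs both classes present")
    uniq = np.unique(s)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [np.nextafter(uniq[-1], 2.0)]])
    best_t, best_j = 0.0, -np.inf
    n_pos, n_neg = y.sum(), (~y).sum()
    for t in candidates:
        pred = s >= t
        sens = np.sum(pred & y) / n_pos
        spec = np.sum(~pred & ~y) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def highlight_patches(score_map: ScoreMap, threshold: float) -> tuple[np.ndarray, float]:
    """Indices of patches scoring >= threshold and the highlighted volume
    fraction (#highlighted / k^3; patches are equal-volume up to one-voxel
    slabs)."""
    idx = np.flatnonzero(score_map.scores >= threshold)
    return idx, float(idx.size / score_map.k ** 3)


def volume_vs_fn_curve(score_maps: list[ScoreMap], labels: list[np.ndarray]) -> EvalCurve:
    """Sweep one global threshold over the pooled test scores.

    Per threshold: ``fn_rate`` is the fraction of true TZ patches (over all
    scans; closed-loop scans contribute two) not highlighted, and
    ``volume_fraction`` the mean over scans of the highlighted fraction.
    Endpoints are pinned at (fn 0, fraction 1) and (fn 1, fraction 0).
    """
    if len(score_maps) == 0 or len(score_maps) != len(labels):
        raise ValueError("need matching, non-empty score maps and labels")
    pooled = np.concatenate([m.scores for m in score_maps])
    lab = np.concatenate([np.asarray(l).astype(bool) for l in labels])
    if lab.sum() == 0:
        raise ValueError("no positive patch in the test set")
    thresholds = np.concatenate([[0.0], np.unique(pooled), [np.nextafter(pooled.max(), 2.0)]])
    fn_rate = np.empty(thresholds.size)
    volume_fraction = np.empty(thresholds.size)
    pos_scores = pooled[lab]
    for i, t in enumerate(thresholds):
        fn_rate[i] = np.mean(pos_scores < t)
        volume_fraction[i] = float(
            np.mean([np.mean(m.scores >= t) for m in score_maps])
        )
    return EvalCurve(thresholds=thresholds, fn_rate=fn_rate, volume_fraction=volume_fraction)


def volume_at_fn(curve: EvalCurve, max_fn: float) -> float:
    """Smallest highlighted-volume fraction achievable with fn_rate <= max_fn."""
    ok = curve.fn_rate <= max_fn + 1e-12
    if not ok.any():
        raise ValueError("no operating point satisfies the FN constraint")
    return float(curve.volume_fraction[ok].min())


def expected_false_positives(n_negative: int, fp_rate: float) -> tuple[float, int]:
    """Mean of Binomial(n, p) — the expected number of wrongly highlighted
    patches — and its rounded integer."""
    if n_negative < 0:
        raise ValueError("n_negative must be >= 0")
    if not 0.0 <= fp_rate <= 1.0:
        raise ValueError("fp_rate must be in [0, 1]")
    mean = n_negative * fp_rate
    return float(mean), int(round(mean))


def region_auroc(
    score_maps: list[ScoreMap],
    labels: list[np.ndarray],
    grid: PatchGrid,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict[str, ROCResult | None]:
    """AUROC restricted to the patches whose centers fall in each region.

    Patches are assigned to the nine abdominal regions via their grid-center
    point. Regions whose pooled labels are single-class get None (flagged
    unavailable rather than a fabricated number).
    """
    centers = grid.centers()
    regions = np.array([assign_region(c, grid.roi) for c in centers])
    pooled_scores = np.concatenate([m.scores for m in score_maps])
    pooled_labels = np.concatenate([np.asarray(l).astype(int) for l in labels])
    n_patches = centers.shape[0]
    patch_region = np.tile(regions, len(score_maps))
    if pooled_scores.size != patch_region.size:
        raise ValueError("score maps do not match the grid size")
    out: dict[str, ROCResult | None] = {}
    for region in sorted(set(regions)):
        mask = patch_region == region
        y = pooled_labels[mask]
        if y.size == 0 or y.min() == y.max():
            out[region] = None
            continue
        out[region] = auroc(pooled_scores[mask], y, n_bootstrap=n_bootstrap, seed=seed)
    return out
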