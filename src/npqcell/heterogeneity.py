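"""Noise vs biological variability, CVs, grid-trace maps and trends.

The central diagnostic separates measurement noise from genuine
cell-to-cell heterogeneity: with the same cells imaged in two
consecutive protocol repeats, the distance in NPQ-score space between a
cell and itself across repeats (D_ii) estimates experimental noise,
while the distance between different cells (D_ij, i ≠ j) additionally
carries biological dispersion.  A D_ii distribution much narrower than
D_ij indicates that point-cloud scatter is dominated by biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .npqspace import AXES, ScoreSet
from .preprocess import normalize_to_initial

__all__ = [
    "RepeatDistanceResult",
    "GridTraceMap",
    "TrendResult",
    "repeat_distance_matrix",
    "variance_difference_test",
    "variation_coefficient",
    "grid_traces",
    "affine_trend",
    "centroid_trend",
]


@dataclass
class RepeatDistanceResult:
    """Pairwise score distances between two repeats of the same cells."""

    D: np.ndarray                 # (n, n)
    sd_ii: float
    sd_ij: float
    statistic: float
    p_value: float

    @property
    def D_ii(self) -> np.ndarray:
        return np.diag(self.D)

    @property
    def D_ij(self) -> np.ndarray:
        n = self.D.shape[0]
        return self.D[~np.eye(n, dtype=bool)]

    @property
    def sd_ratio(self) -> float:
        return self.sd_ii / self.sd_ij


def repeat_distance_matrix(scores_a: ScoreSet | np.ndarray,
                           scores_b: ScoreSet | np.ndarray,
                           test: str = "levene") -> RepeatDistanceResult:
    """Distance matrix D[i, j] = ‖score_a(cell i) − score_b(cell j)‖₂.

    Cells must be index-aligned between the repeats (same cell = same
    row).  The diagonal D_ii samples measurement noise, the off-diagonal
    D_ij the population spread; a variance test compares the two.
    """
    a = scores_a.scores if isinstance(scores_a, ScoreSet) else np.asarray(scores_a)
    b = scores_b.scores if isinstance(scores_b, ScoreSet) else np.asarray(scores_b)
    if a.shape != b.shape:
        raise ValueError(f"score shapes differ: {a.shape} vs {b.shape}")
    D = cdist(a, b)
    d_ii = np.diag(D)
    d_ij = D[~np.eye(D.shape[0], dtype=bool)]
    if len(d_ii) >= 3 and len(d_ij) >= 3:
        stat, p = variance_difference_test(d_ii, d_ij, method=test)
    else:           # too few cells for a variance comparison
        stat, p = float("nan"), float("nan")
    return RepeatDistanceResult(D=D, sd_ii=float(d_ii.std(ddof=1)),
                                sd_ij=float(d_ij.std(ddof=1)),
                                statistic=stat, p_value=p)


def variance_difference_test(sample_1, sample_2,
                             method: str = "levene") -> tuple[float, float]:
    """Test whether two samples have different variances.

    Default is the median-centered (Brown–Forsythe) Levene test, robust
    to non-normality; ``method="f"`` gives the classical variance-ratio
    F test.
    """
    s1 = np.asarray(sample_1, dtype=float)
    s2 = np.asarray(sample_2, dtype=float)
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("both samples need at least 3 values")
    if s1.std() == 0 and s2.std() == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    if method == "levene":
        res = stats.levene(s1, s2, center="median")
        return float(res.statistic), float(res.pvalue)
    if method == "f":
        f = s1.var(ddof=1) / s2.var(ddof=1)
        df1, df2 = len(s1) - 1, len(s2) - 1
        p = 2 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
        return float(f), float(min(p, 1.0))
    raise ValueError(f"unknown method {method!r}")


def variation_coefficient(scores: ScoreSet, axis: str) -> float:
    """Coefficient of variation (SD / mean) of one score axis."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    vals = scores.axis(axis)
    m = vals.mean()
    if m <= 0:
        raise ValueError(f"CV undefined: mean {axis} score is {m:.3g} <= 0")
    return float(vals.std(ddof=1) / m)


@dataclass
class GridTraceMap:
    """Average display-normalized traces on a 2D score grid."""

    grid_n: int
    bounds: tuple[float, float, float, float]   # (x0, x1, y0, y1)
    counts: np.ndarray                          # (grid_n, grid_n)
    mean_traces: dict[tuple[int, int], np.ndarray] = field(
        default_factory=dict)
    min_count: int = 3


def grid_traces(scores_2d: np.ndarray, display_traces: np.ndarray,
                bounds: tuple[float, float, float, float] | None = None,
                grid_n: int = 8, min_count: int = 3) -> GridTraceMap:
    """Group cells on an n×n grid of a 2D score plane and average traces.

    Boxes are half-open (the last edge is closed); a mean trace
    (normalized to its first point) is stored only for boxes holding
    strictly more than ``min_count`` cells.  Default bounds are the
    1st–99th percentile rectangle of the points.
    """
    pts = np.asarray(scores_2d, dtype=float)
    traces = np.asarray(display_traces, dtype=float)
    if pts.shape[0] != traces.shape[0]:
        raise ValueError("scores and traces must have matching rows")
    if pts.shape[0] == 0:
        return GridTraceMap(grid_n=grid_n, bounds=(0, 1, 0, 1),
                            counts=np.zeros((grid_n, grid_n), dtype=int),
                            min_count=min_count)
    if bounds is None:
        x0, x1 = np.percentile(pts[:, 0], [1, 99])
        y0, y1 = np.percentile(pts[:, 1], [1, 99])
    else:
        x0, x1, y0, y1 = bounds
    xe = np.linspace(x0, x1, grid_n + 1)
    ye = np.linspace(y0, y1, grid_n + 1)
    ix = np.digitize(pts[:, 0], xe) - 1
    iy = np.digitize(pts[:, 1], ye) - 1
    ix[pts[:, 0] == x1] = grid_n - 1          # close the last edge
    iy[pts[:, 1] == y1] = grid_n - 1
    inside = (ix >= 0) & (ix < grid_n) & (iy >= 0) & (iy < grid_n)
    counts = np.zeros((grid_n, grid_n), dtype=int)
    mean_traces: dict[tuple[int, int], np.ndarray] = {}
    for gx in range(grid_n):
        for gy in range(grid_n):
            sel = inside & (ix == gx) & (iy == gy)
            counts[gx, gy] = int(sel.sum())
            if counts[gx, gy] > min_count:
                mean_traces[(gx, gy)] = normalize_to_initial(
                    traces[sel]).mean(axis=0)
    return GridTraceMap(grid_n=grid_n, bounds=(float(x0), float(x1),
                                               float(y0), float(y1)),
                        counts=counts, mean_traces=mean_traces,
                        min_count=min_count)


@dataclass
class TrendResult:
    """Affine trend of a 2D point cloud."""

    slope: float
    intercept: float
    r: float
    p_value: float
    method: str
    n: int
    angle_to: float | None = None   # degrees, vs a reference fit


def affine_trend(points_2d: np.ndarray,
                 method: str = "orthogonal") -> TrendResult:
    """Affine fit y = slope·x + intercept of a 2D point cloud.

    ``method="orthogonal"`` (default) minimizes perpendicular distances
    (total least squares, appropriate when both axes carry comparable
    noise); ``method="ols"`` is ordinary least squares of y on x.  The
    correlation is always the Pearson r with its two-sided p-value.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a trend")
    x, y = pts[:, 0], pts[:, 1]
    if x.std() == 0 and y.std() == 0:
        raise ValueError("degenerate cloud: zero variance on both axes")
    r, p = stats.pearsonr(x, y)
    if method == "orthogonal":
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if direction[0] == 0:
            raise ValueError("orthogonal fit is vertical; use method='ols' "
                             "on swapped axes")
        slope = direction[1] / direction[0]
    elif method == "ols":
        slope = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = y.mean() - slope * x.mean()
    return TrendResult(slope=float(slope), intercept=float(intercept),
                       r=float(r), p_value=float(p), method=method,
                       n=pts.shape[0])


def centroid_trend(score_sets: list[ScoreSet],
                   axes: tuple[str, str] = ("qT", "qE"),
                   method: str = "orthogonal") -> TrendResult:
    """Affine fit through per-time-point score centroids.

    Each ScoreSet is one time point (e.g. one step of a progressive
    high-light treatment); the fit runs through the (mean axis-x, mean
    axis-y) centroids.  The angle between this centroid trend and the
    pooled per-cloud trend is reported in degrees.
    """
    if len(score_sets) < 3:
        raise ValueError("need at least 3 time points")
    cents = np.array([[s.axis(axes[0]).mean(), s.axis(axes[1]).mean()]
                      for s in score_sets])
    fit = affine_trend(cents, method=method)
    pooled = np.vstack([np.column_stack([s.axis(axes[0]), s.axis(axes[1])])
                        for s in score_sets])
    pooled_fit = affine_trend(pooled, method=method)
    ang = abs(np.degrees(np.arctan(fit.slope) -
                         np.arctan(pooled_fit.slope)))
    fit.angle_to = float(min(ang, 180.0 - ang))
    return fit
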