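"""Medial–lateral expression-gradient statistics for LSO sections.

Cell positions are projected onto a manually annotated medial→lateral axis
and rescaled so each LSO spans [0, 1]; background-corrected intensities are
floored at zero and divided by the brightest cell in the same LSO; the
headline statistics are the OLS slope of normalized intensity on normalized
position and the fraction of cells whose *raw* corrected intensity exceeds a
per-protein threshold.

Also here: the supporting statistics used around those gradients — exact /
tie-corrected Wilcoxon rank-sum comparisons, one-way ANOVA reconstructed
from printed group summaries, percentage summaries, multiplicative
photobleach / imaging-depth intensity correction, and the simple linear-fit
significance screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GeometryError, InsufficientDataError, ParameterError

__all__ = [
    "LsoAxis",
    "GradientFit",
    "GroupSummary",
    "AnovaResult",
    "BleachDepthModel",
    "normalize_positions",
    "normalize_intensities",
    "expression_slope",
    "expressing_fraction",
    "threshold_sweep",
    "compare_groups",
    "anova_from_summary",
    "proportion_summary",
    "correct_gfp_intensity",
    "fit_linear_screen",
]


# ---------------------------------------------------------------------------
# positions and intensities
# ---------------------------------------------------------------------------

@dataclass
class LsoAxis:
    """Medial→lateral axis annotated through the LSO, in (x, y) pixels."""

    medial: tuple[float, float]
    lateral: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.medial, self.lateral):
            raise GeometryError("axis endpoints coincide")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.lateral[0] - self.medial[0],
                              self.lateral[1] - self.medial[1]))


def normalize_positions(
    cells: pd.DataFrame,
    axis: LsoAxis,
    x_col: str = "centroid_x_px",
    y_col: str = "centroid_y_px",
) -> pd.DataFrame:
    """Add a ``position`` column: normalized medial–lateral coordinate.

    Each centroid is orthogonally projected onto the axis segment; the
    scalar coordinate is divided by the axis length (medial endpoint → 0,
    lateral endpoint → 1) and clamped to [0, 1].
    """
    v = np.asarray(axis.lateral, float) - np.asarray(axis.medial, float)
    denom = float(v @ v)
    pts = cells[[x_col, y_col]].to_numpy(float) - np.asarray(axis.medial, float)
    t = (pts @ v) / denom
    out = cells.copy()
    out["position"] = np.clip(t, 0.0, 1.0)
    return out


def normalize_intensities(
    cells: pd.DataFrame,
    channel: str,
    corrected_col: str | None = None,
) -> pd.DataFrame:
    """Add ``normalized_<channel>``: floored at 0, scaled by the brightest cell.

    ``I' = max(corrected, 0) / max_i max(corrected_i, 0)``.  If every
    corrected value is ≤ 0 the normalized column is all zeros and
    ``result.attrs["all_nonpositive"]`` is set.  An empty table round-trips
    to an empty table.
    """
    col = corrected_col or f"corrected_{channel}"
    out = cells.copy()
    out.attrs["all_nonpositive"] = False
    if len(cells) == 0:
        out[f"normalized_{channel}"] = pd.Series(dtype=float)
        return out
    floored = np.maximum(cells[col].to_numpy(float), 0.0)
    peak = floored.max()
    if peak <= 0:
        out[f"normalized_{channel}"] = 0.0
        out.attrs["all_nonpositive"] = True
    else:
        out[f"normalized_{channel}"] = floored / peak
    return out


# ---------------------------------------------------------------------------
# slope and fraction
# ---------------------------------------------------------------------------

@dataclass
class GradientFit:
    """OLS fit of normalized intensity on normalized position.

    ``ci_low``/``ci_high`` is the conventional 95% slope interval from the
    regression standard error.  ``ci_low_adj``/``ci_high_adj`` additionally
    propagates the uncertainty of the brightest-cell normalizer
    (se² + slope²·s², see docs/methods.md); use it when comparing a
    pipeline-estimated slope with an externally known value.
    """

    slope: float
    intercept: float
    r2: float
    stderr: float
    ci_low: float
    ci_high: float
    ci_low_adj: float
    ci_high_adj: float
    n: int

    def summary(self) -> str:
        return (
            f"n={self.n}  slope={self.slope:+.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  "
            f"adj. CI [{self.ci_low_adj:+.4f}, {self.ci_high_adj:+.4f}]  "
            f"intercept={self.intercept:.4f}  r²={self.r2:.4f}"
        )


def expression_slope(
    cells: pd.DataFrame,
    x_col: str = "position",
    y_col: str | None = None,
    channel: str | None = None,
    spatial_cols: tuple[str, str] = ("centroid_x_px", "centroid_y_px"),
) -> GradientFit:
    """Fit the medial–lateral gradient line and return slope statistics.

    Requires ≥ 3 cells with non-constant positions.  ``y_col`` defaults to
    ``normalized_<channel>``.  When the table carries cell coordinates
    (``spatial_cols``), the adjusted CI uses a spatial HAC variance so that
    shared local background among neighbouring cells does not shrink the
    interval; otherwise residuals are ordered along the axis.
    """
    if y_col is None:
        if channel is None:
            raise ParameterError("give either y_col or channel")
        y_col = f"normalized_{channel}"
    x = cells[x_col].to_numpy(float)
    y = cells[y_col].to_numpy(float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 cells, got {n}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("all cell positions identical")

    res = stats.linregress(x, y)
    df = n - 2
    tcrit = stats.t.ppf(0.975, df)
    resid = y - (res.intercept + res.slope * x)
    s2 = float(resid @ resid) / df
    if all(c in cells.columns for c in spatial_cols):
        coords = cells[list(spatial_cols)].to_numpy(float)
        se_hac = _spatial_hac_se(x, resid, coords)
    else:
        se_hac = _hac_slope_se(x, y, res.slope, res.intercept)
    se_adj = float(np.sqrt(max(se_hac, res.stderr) ** 2
                           + res.slope ** 2 * s2))
    return GradientFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        stderr=float(res.stderr),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        ci_low_adj=float(res.slope - tcrit * se_adj),
        ci_high_adj=float(res.slope + tcrit * se_adj),
        n=n,
    )


def _hac_slope_se(x, y, slope, intercept, lags: int | None = None) -> float:
    """Newey–West slope standard error over position-ordered residuals.

    Cells close along the medial–lateral axis share local background, so
    their residuals are positively correlated; the Bartlett-kernel sandwich
    variance (default bandwidth √n) absorbs that into the pipeline CI.
    """
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    xc = xs - xs.mean()
    sxx = float(xc @ xc)
    u = xc * (ys - intercept - slope * xs)
    n = len(u)
    L = int(np.ceil(np.sqrt(n))) if lags is None else lags
    s = float(u @ u)
    for lag in range(1, min(L, n - 1) + 1):
        w = 1.0 - lag / (L + 1.0)
        s += 2.0 * w * float(u[:-lag] @ u[lag:])
    return float(np.sqrt(max(s, 0.0)) / sxx)


def _spatial_hac_se(
    x, resid, coords,
    bin_width_px: float = 20.0,
    max_range_px: float = 240.0,
    min_pairs: int = 40,
) -> float:
    """Spatially robust slope standard error from the residual covariogram.

    Cells that are close in the section share local background, so their
    regression residuals are positively correlated and the iid OLS slope
    variance is too small.  The empirical covariogram (mean residual
    cross-product per distance bin, clipped at zero) is plugged in as the
    off-diagonal covariance of a sandwich variance -- a model-based
    Conley-type estimator without kernel down-weighting.
    """
    xc = x - x.mean()
    sxx = float(xc @ xc)
    d = np.hypot(coords[:, 0, None] - coords[None, :, 0],
                 coords[:, 1, None] - coords[None, :, 1])
    off = ~np.eye(len(x), dtype=bool)
    uu = np.outer(resid, resid)
    xx = np.outer(xc, xc)
    s = float((xc ** 2) @ (resid ** 2))
    lo = 0.0
    while lo < max_range_px:
        sel = (d > lo) & (d <= lo + bin_width_px) & off
        lo += bin_width_px
        if sel.sum() < min_pairs:
            continue
        cov_bin = max(float(uu[sel].mean()), 0.0)
        s += cov_bin * float(xx[sel].sum())
    return float(np.sqrt(max(s, 0.0)) / sxx)


def expressing_fraction(
    cells: pd.DataFrame,
    channel: str,
    threshold: float,
) -> float:
    """Fraction of cells whose raw corrected intensity exceeds ``threshold``.

    Thresholding is on the pre-normalization corrected intensity, because the
    per-protein thresholds are chosen on the raw intensity scale.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    if len(cells) == 0:
        raise InsufficientDataError("expressing fraction undefined on empty table")
    vals = cells[f"corrected_{channel}"].to_numpy(float)
    return float((vals > threshold).mean())


def threshold_sweep(
    cells: pd.DataFrame,
    channel: str,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    """Expressing-fraction curve over candidate thresholds.

    Helper for picking a per-protein threshold that matches manual counts.
    """
    return pd.DataFrame(
        {
            "threshold": np.asarray(thresholds, float),
            "fraction": [expressing_fraction(cells, channel, t) for t in thresholds],
        }
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration when ``n_a + n_b <= 12`` and there are no ties;
    normal approximation with tie correction otherwise.

    Returns ``(U, p)`` with U for the first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    """Printed summary of one group: mean, sample SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"need n >= 2 per group, got {self.n}")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    df_total: int
    p: float

    def summary(self) -> str:
        return (f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
                f"{self.F:.2f}, total DF = {self.df_total}, p = {self.p:.3f}")


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from group means, SDs and sizes alone.

    F = [Σ nᵢ(mᵢ − m̄)² / (k−1)] / [Σ (nᵢ−1)sᵢ² / (N−k)] with m̄ the grand
    (size-weighted) mean; identical to the raw-data ANOVA for any sample
    reproducing these summaries.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    ns = np.array([g.n for g in groups], float)
    means = np.array([g.mean for g in groups], float)
    sds = np.array([g.sd for g in groups], float)
    N = ns.sum()
    k = len(groups)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df_b, df_w = k - 1, int(N - k)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w,
                       df_total=int(N - 1), p=p)


def proportion_summary(count: int, total: int) -> float:
    """Percentage ``100 * count / total`` with domain checks."""
    if total <= 0:
        raise ParameterError("total must be positive")
    if not 0 <= count <= total:
        raise ParameterError("need 0 <= count <= total")
    return 100.0 * count / total


# ---------------------------------------------------------------------------
# photobleach / depth correction and the linear screen
# ---------------------------------------------------------------------------

@dataclass
class BleachDepthModel:
    """Multiplicative intensity-correction model for slice imaging.

    Repeated illumination bleaches the fluorophore and deeper cells appear
    dimmer; both effects are modeled as lines fitted to calibration series,
    giving relative intensity ``1 + bleach_slope·n_flashes`` (slope < 0,
    fraction per flash) and ``1 + depth_slope·depth`` (slope < 0, fraction
    per µm).  The observed intensity is divided by both factors.
    """

    bleach_slope: float = 0.0
    depth_slope: float = 0.0

    @classmethod
    def from_calibration(
        cls,
        flashes: np.ndarray | None = None,
        rel_intensity_flash: np.ndarray | None = None,
        depths: np.ndarray | None = None,
        rel_intensity_depth: np.ndarray | None = None,
    ) -> "BleachDepthModel":
        """Fit the two slopes from calibration series of relative intensity."""
        b = d = 0.0
        if flashes is not None:
            b = float(stats.linregress(np.asarray(flashes, float),
                                       np.asarray(rel_intensity_flash, float)).slope)
        if depths is not None:
            d = float(stats.linregress(np.asarray(depths, float),
                                       np.asarray(rel_intensity_depth, float)).slope)
        return cls(bleach_slope=b, depth_slope=d)


def correct_gfp_intensity(
    raw: float,
    n_flashes: int,
    depth_um: float,
    model: BleachDepthModel,
) -> float:
    """Undo photobleaching and depth attenuation multiplicatively.

    ``corrected = raw / (1 + b·n_flashes) / (1 + d·depth)``; raises if
    either correction factor is non-positive at the given exposure/depth.
    """
    f_bleach = 1.0 + model.bleach_slope * n_flashes
    f_depth = 1.0 + model.depth_slope * depth_um
    if f_bleach <= 0 or f_depth <= 0:
        raise ParameterError(
            f"correction factor non-positive (bleach={f_bleach:.3g}, "
            f"depth={f_depth:.3g}); outside the supported range"
        )
    return float(raw) / f_bleach / f_depth


def fit_linear_screen(x, y) -> tuple[float, float]:
    """OLS slope with its t-test p-value, for screening trends at p < 0.05.

    A constant-y input returns ``(0.0, 1.0)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("x is constant")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    return float(res.slope), p
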