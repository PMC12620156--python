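"""ROI statistics for quantitative-map validation studies.

Implements the agreement and repeatability analyses conventionally reported
for PDFF phantom and in vivo studies: ordinary least-squares regression of
measured against reference values with 95% confidence intervals, Pearson
correlation with a Fisher-z interval, one-sample t statistics on paired
differences, Bland-Altman bias and limits of agreement with their intervals,
the repeatability coefficient RC = 1.96*sqrt(2)*sigma_w (QIBA convention,
sigma_w the pooled within-ROI standard deviation across repetitions) and the
average peak-to-peak range across repetitions.

ROI tables are plain pandas DataFrames with columns
``scan, rep, roi, mean, sd, n`` (one row per scan/repetition/ROI).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "AgreementReport",
    "regress",
    "bland_altman",
    "repeatability_coefficient",
    "average_range",
    "paired_t",
    "roi_table",
    "circular_roi_means",
]

ROI_COLUMNS = ["scan", "rep", "roi", "mean", "sd", "n"]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    slope_ci: tuple
    intercept_ci: tuple
    r_ci: tuple
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple
    loa_low_ci: tuple
    loa_high_ci: tuple
    sd_diff: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def regress(measured, reference) -> RegressionResult:
    """OLS of measured on reference with 95% CIs (t, n-2 df; Fisher z for r)."""
    y = np.asarray(measured, float)
    x = np.asarray(reference, float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need at least three paired points")
    if np.var(x) == 0:
        raise ValueError("reference values are degenerate (zero variance)")
    fit = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    intercept_ci = (
        fit.intercept - tcrit * fit.intercept_stderr,
        fit.intercept + tcrit * fit.intercept_stderr,
    )
    r = float(fit.rvalue)
    if abs(r) >= 1.0 - 1e-15:
        r_ci = (r, r)
    elif n <= 3:  # Fisher-z interval needs n > 3
        r_ci = (float("nan"), float("nan"))
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        r_ci = (float(np.tanh(z - 1.959963984540054 * se)), float(np.tanh(z + 1.959963984540054 * se)))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        slope_ci=tuple(map(float, slope_ci)),
        intercept_ci=tuple(map(float, intercept_ci)),
        r_ci=r_ci,
        n=n,
    )


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement between paired measurements ``a`` and ``b``.

    Differences d = a - b; bias = mean(d); LoA = bias +/- 1.96 SD(d).
    Bias CI uses t_{n-1} * SD/sqrt(n); each LoA CI the standard
    approximation t_{n-1} * SD * sqrt(3/n).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least two paired values")
    d = a - b
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = stats.t.ppf(0.975, n - 1)
    half_bias = tcrit * sd / np.sqrt(n)
    half_loa = tcrit * sd * np.sqrt(3.0 / n)
    return AgreementReport(
        bias=bias,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low_ci=(loa_low - half_loa, loa_low + half_loa),
        loa_high_ci=(loa_high - half_loa, loa_high + half_loa),
        sd_diff=sd,
        n=n,
    )


def _per_roi_groups(table: pd.DataFrame):
    required = {"rep", "roi", "mean"}
    if not required.issubset(table.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    keys = ["scan", "roi"] if "scan" in table.columns else ["roi"]
    groups = [g["mean"].to_numpy(float) for _, g in table.groupby(keys)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every ROI needs at least two repetitions")
    return groups


def repeatability_coefficient(table: pd.DataFrame) -> float:
    """RC = 1.96*sqrt(2)*sigma_w, sigma_w pooled across ROIs.

    sigma_w is the root mean within-ROI variance of the per-repetition ROI
    means; RC is the smallest between-repeat difference detectable with 95%
    confidence.  Adding a constant per ROI leaves RC unchanged.
    """
    groups = _per_roi_groups(table)
    within_var = np.mean([g.var(ddof=1) for g in groups])
    return float(1.96 * np.sqrt(2.0) * np.sqrt(within_var))


def average_range(table: pd.DataFrame) -> float:
    """Mean over ROIs of the peak-to-peak (max - min) range across repetitions."""
    groups = _per_roi_groups(table)
    return float(np.mean([g.max() - g.min() for g in groups]))


def paired_t(measured, reference) -> tuple:
    """One-sample t statistic on the paired differences, two-sided p.

    A zero-variance nonzero-mean difference has an exactly zero p-value
    (flagged by the infinite t); all-zero differences give t = 0, p = 1.
    """
    a = np.asarray(measured, float)
    b = np.asarray(reference, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least two paired values")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# ROI extraction on the simulated phantom
# ----------------------------------------------------------------------


def circular_roi_means(
    value_map: np.ndarray,
    centers,
    radii,
    radius_fraction: float = 0.8,
    slice_index: int | None = None,
) -> list:
    """Mean/SD/count inside circular ROIs on one slice of a (z, y, x) map.

    ROIs are concentric with the vials at ``radius_fraction`` of the vial
    radius (default 80%), on the middle slice unless given.  NaNs ignored.
    """
    vol = np.asarray(value_map, float)
    z = vol.shape[0] // 2 if slice_index is None else slice_index
    sl = vol[z]
    ny, nx = sl.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    out = []
    radii = np.broadcast_to(np.asarray(radii, float), (len(centers),))
    for (cy, cx), r in zip(centers, radii):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius_fraction * r) ** 2
        vals = sl[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("empty ROI")
        out.append((float(vals.mean()), float(vals.std(ddof=0)), int(vals.size)))
    return out


def roi_table(rows) -> pd.DataFrame:
    """Assemble (scan, rep, roi, mean, sd, n) rows into the standard table."""
    df = pd.DataFrame(rows, columns=ROI_COLUMNS)
    if (df["n"] < 1).any():
        raise ValueError("ROI voxel counts must be >= 1")
    if df.duplicated(subset=["scan", "rep", "roi"]).any():
        raise ValueError("duplicate (scan, rep, roi) rows")
    return df
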