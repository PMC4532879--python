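"""SILAC MS1 quantification of crosslinked peptide pairs.

Each crosslinked species is quantified by the area under its extracted
ion chromatogram (XIC) in the light and heavy channels (+-10 ppm by
default). Per-replicate log2 ratios are expressed on the
resistant/sensitive (R/S) scale regardless of label orientation: in a
"forward" replicate the resistant sample is heavy, in a "reverse"
(label-swap) replicate it is light. Replicates are pooled into a mean
with a two-sided Student-t confidence interval; a pair is called
significant when |mean log2(R/S)| > 1 and the full CI width < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "XicTrace",
    "QuantRecord",
    "QuantSummary",
    "extract_xic",
    "linear_rt_alignment",
    "apply_rt_alignment",
    "replicate_ratio",
    "summarize",
    "label_swap_regression",
    "ratio_distribution_stats",
    "RatioDistributionStats",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class XicTrace:
    """An extracted ion chromatogram: (rt, intensity) points and its area."""

    target_mz: float
    ppm_tol: float
    times: tuple[float, ...]
    intensities: tuple[float, ...]

    @property
    def area(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(np.trapezoid(self.intensities, self.times))


@dataclass(frozen=True)
class QuantRecord:
    """One replicate's light/heavy areas and R/S-scale log2 ratio."""

    pair_key: str
    replicate_id: str
    label_orientation: str
    light_area: float
    heavy_area: float
    log2_rs: float | None


@dataclass(frozen=True)
class QuantSummary:
    pair_key: str
    n_replicates: int
    mean_log2_rs: float
    ci_width: float
    significant: bool


def extract_xic(
    ms1_peaks: pd.DataFrame,
    target_mz: float,
    ppm_tol: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XicTrace:
    """XIC at ``target_mz`` +- ``ppm_tol`` ppm inside ``rt_window``.

    ``ms1_peaks`` must carry columns ``rt``, ``mz``, ``intensity``.
    Intensities of matching peaks are summed per scan; scans inside the
    window with no matching peak contribute zero (so the trapezoid does
    not bridge elution gaps); the area is the trapezoidal integral over
    retention time.
    """
    df = ms1_peaks
    if rt_window is not None:
        df = df[(df["rt"] >= rt_window[0]) & (df["rt"] <= rt_window[1])]
    sel = df[np.abs(df["mz"] - target_mz) / target_mz * 1e6 <= ppm_tol]
    if sel.empty:
        return XicTrace(target_mz, ppm_tol, (), ())
    per_scan = sel.groupby("rt", sort=True)["intensity"].sum()
    grid = np.unique(df["rt"].to_numpy())
    filled = per_scan.reindex(grid, fill_value=0.0)
    return XicTrace(
        target_mz,
        ppm_tol,
        tuple(float(t) for t in filled.index),
        tuple(float(v) for v in filled.values),
    )


def linear_rt_alignment(
    reference: pd.DataFrame,
    other: pd.DataFrame,
    n_landmarks: int = 20,
    mz_tol_ppm: float = 10.0,
) -> tuple[float, float]:
    """Global linear retention-time fit of ``other`` onto ``reference``.

    The ``n_landmarks`` most intense reference peaks are matched by m/z
    (within ``mz_tol_ppm``) to the most intense co-m/z peak of the other
    run; an OLS fit of reference rt on matched rt gives (slope,
    intercept) such that ``rt_aligned = slope * rt + intercept``. A
    deliberately simple stand-in for warping-based alignment, adequate
    for runs whose drift is close to affine.
    """
    landmarks = reference.nlargest(n_landmarks, "intensity")
    xs, ys = [], []
    mz_other = other["mz"].to_numpy()
    for row in landmarks.itertuples(index=False):
        near = other[np.abs(mz_other - row.mz) / row.mz * 1e6 <= mz_tol_ppm]
        if near.empty:
            continue
        best = near.loc[near["intensity"].idxmax()]
        xs.append(float(best["rt"]))
        ys.append(float(row.rt))
    if len(set(xs)) < 3:
        raise ValueError(f"only {len(set(xs))} shared landmarks, need >= 3")
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept)


def apply_rt_alignment(peaks: pd.DataFrame, slope: float, intercept: float) -> pd.DataFrame:
    """Return a copy of the peak table with rt mapped through the fit."""
    out = peaks.copy()
    out["rt"] = slope * out["rt"] + intercept
    return out


def replicate_ratio(light_area: float, heavy_area: float, orientation: str) -> float | None:
    """log2(R/S) for one replicate, or None when a channel is missing.

    Forward orientation means the resistant sample carries the heavy
    label, so R/S = heavy/light; reverse swaps the channels.
    """
    if orientation not in (FORWARD, REVERSE):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    if light_area <= 0 or heavy_area <= 0:
        return None
    if orientation == FORWARD:
        return math.log2(heavy_area / light_area)
    return math.log2(light_area / heavy_area)


def summarize(
    records: list[QuantRecord],
    alpha: float = 0.05,
    ratio_threshold: float = 1.0,
    ci_threshold: float = 1.0,
) -> QuantSummary | None:
    """Pool replicate ratios into mean, CI width and a significance call.

    The CI width is the full width of the two-sided (1-alpha) Student-t
    interval, 2 * t_{1-alpha/2, n-1} * s / sqrt(n). With a single
    replicate the CI is undefined (inf) and the pair is never
    significant. Records with missing ratios are ignored; returns None
    when nothing is quantified.
    """
    values = [r.log2_rs for r in records if r.log2_rs is not None and math.isfinite(r.log2_rs)]
    if not values:
        return None
    pair_key = records[0].pair_key
    n = len(values)
    mean = float(np.mean(values))
    if n >= 2:
        s = float(np.std(values, ddof=1))
        ci_width = 2.0 * float(stats.t.ppf(1 - alpha / 2, n - 1)) * s / math.sqrt(n)
    else:
        ci_width = math.inf
    significant = abs(mean) > ratio_threshold and ci_width < ci_threshold
    return QuantSummary(pair_key, n, mean, ci_width, significant)


def label_swap_regression(
    forward_means: dict[str, float], reverse_means: dict[str, float]
) -> tuple[float, float, int]:
    """OLS of forward vs reverse R/S-scale means over shared pairs.

    Returns (slope, r_squared, n). Mirrors the forward/label-swap
    consistency scatter used to validate replicate agreement.
    """
    shared = sorted(set(forward_means) & set(reverse_means))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared pairs, got {len(shared)}")
    x = np.array([reverse_means[k] for k in shared])
    y = np.array([forward_means[k] for k in shared])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2), len(shared)


@dataclass(frozen=True)
class RatioDistributionStats:
    min: float
    max: float
    sd: float
    median_ci: float


def ratio_distribution_stats(summaries: list[QuantSummary]) -> RatioDistributionStats:
    """Sample statistics over pair means and CI widths."""
    if not summaries:
        raise ValueError("no summaries")
    means = np.array([s.mean_log2_rs for s in summaries])
    cis = np.array([s.ci_width for s in summaries if math.isfinite(s.ci_width)])
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return RatioDistributionStats(
        min=float(means.min()),
        max=float(means.max()),
        sd=sd,
        median_ci=float(np.median(cis)) if len(cis) else math.nan,
    )
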