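"""Gradient assembly, threshold overlay, tier conversion and statistics.

Assembles the count-rate gradient from positioned FCS measurements
(background subtraction -> per-sample max normalization -> 40-um
binning -> across-sample aggregation), overlays it with expression
profiles to read off the relative morphogen levels at expression-domain
features, converts distances to cell tiers (14 um/tier), and provides
the group comparison (pooled-variance two-tailed t-test) and Pearson
correlation used for the perturbation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .profiles import SpatialProfile
from .synthetic_embryo import CELL_TIER_UM, GradientCurve

__all__ = [
    "GradientMeasurement",
    "ThresholdFeature",
    "ThresholdMap",
    "assemble_gradient",
    "overlay_thresholds",
    "to_cell_tiers",
    "compare_groups",
    "correlation_with_distance",
    "decay_length",
]


@dataclass
class GradientMeasurement:
    """One positioned FCS count-rate reading."""

    distance_um: float
    count_rate_khz: float
    sample_id: str
    condition: str = "control"

    def __post_init__(self):
        if self.distance_um < 0 or self.count_rate_khz < 0:
            raise ValueError("distance and count rate must be non-negative")


@dataclass
class ThresholdFeature:
    """One mapped feature of an expression profile."""

    label: str
    position_um: float | None
    relative_level: float | None
    absolute_nm: float | None
    reached: bool = True

    @property
    def position_tiers(self) -> float | None:
        if self.position_um is None:
            return None
        return to_cell_tiers(self.position_um)


@dataclass
class ThresholdMap:
    features: list

    def __getitem__(self, label: str) -> ThresholdFeature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "feature": f.label,
            "position_um": f.position_um,
            "position_tiers": f.position_tiers,
            "relative_level": f.relative_level,
            "absolute_nM": f.absolute_nm,
            "reached": f.reached,
        } for f in self.features])

    def to_dict(self) -> dict:
        return {f.label: {
            "position_um": f.position_um,
            "position_tiers": f.position_tiers,
            "relative_level": f.relative_level,
            "absolute_nM": f.absolute_nm,
            "reached": f.reached,
        } for f in self.features}


# ---------------------------------------------------------------------------
# Gradient assembly


def assemble_gradient(measurements, background_khz: float = 0.0,
                      bin_width_um: float = 40.0,
                      extent_um: float | None = None) -> SpatialProfile:
    """Build the count-rate gradient profile from FCS measurements.

    Order of operations is fixed: subtract the background rate (clip at
    zero), normalize each sample to its own maximal rate, bin at 40 um,
    aggregate across samples.  The result is invariant to per-sample
    multiplicative gain.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements")
    if extent_um is None:
        extent_um = max(m.distance_um for m in ms) + bin_width_um
    n_bins = int(np.ceil(extent_um / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    samples = sorted({m.sample_id for m in ms})
    mats = []
    for sid in samples:
        rows = [m for m in ms if m.sample_id == sid]
        rates = np.array([max(m.count_rate_khz - background_khz, 0.0)
                          for m in rows])
        if rates.max() <= 0:
            warnings.warn(f"sample {sid!r} has no signal above background; "
                          "excluded")
            continue
        rates = rates / rates.max()
        x = np.array([m.distance_um for m in rows])
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1,
                      0, n_bins - 1)
        prof = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = idx == b
            if np.any(sel):
                prof[b] = rates[sel].mean()
        mats.append(prof)
    if not mats:
        return SpatialProfile(edges, np.full((1, n_bins), np.nan),
                              "per-sample-max")
    return SpatialProfile(edges, np.array(mats), "per-sample-max")


def _profile_interpolator(profile: SpatialProfile):
    """Monotone-cubic interpolation of an aggregated profile between
    bin centers (constant extrapolation at the ends)."""
    x = profile.bin_centers
    y = profile.mean
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    interp = PchipInterpolator(x, y)

    def f(q):
        q = np.clip(q, x[0], x[-1])
        return interp(q)
    return f


# ---------------------------------------------------------------------------
# Threshold overlay


def _gradient_level(gradient, x: float) -> float:
    if isinstance(gradient, GradientCurve):
        return float(gradient(x))
    if isinstance(gradient, SpatialProfile):
        return float(_profile_interpolator(gradient)(x))
    return float(gradient(x))


def _peak_nm(gradient) -> float | None:
    return gradient.peak_nm if isinstance(gradient, GradientCurve) else None


def overlay_thresholds(gradient, expression: SpatialProfile,
                       features=("peak_domain", "boundary"),
                       label: str = "", peak_tolerance: float = 0.9,
                       intensity_floor: float = 0.1,
                       kind: str = "foci") -> ThresholdMap:
    """Read gradient levels at expression-profile features.

    peak_domain: the contiguous run of bins (containing the maximum)
    whose mean stays within ``peak_tolerance`` of the maximal bin; its
    start and end positions are reported with the gradient level at
    each.  boundary: for foci profiles, the left edge of the first bin
    beyond the maximum with zero mean count ("nullifying"); for
    intensity profiles, the first bin falling below ``intensity_floor``
    of the maximum (intensities never reach exact zero).  Absolute
    levels (nM) are attached when the gradient carries a peak
    concentration.
    """
    mean = expression.mean
    edges = expression.bin_edges
    ok = ~np.isnan(mean)
    if not np.any(ok):
        raise ValueError("expression profile is empty")
    peak_nm = _peak_nm(gradient)
    prefix = (label + "_") if label else ""
    out = []

    i_max = int(np.nanargmax(mean))
    peak_val = mean[i_max]

    def make(name, pos):
        level = _gradient_level(gradient, pos)
        out.append(ThresholdFeature(
            prefix + name, float(pos), level,
            None if peak_nm is None else level * peak_nm))

    if "peak_domain" in features:
        lo = i_max
        while lo > 0 and mean[lo - 1] >= peak_tolerance * peak_val:
            lo -= 1
        hi = i_max
        while hi < len(mean) - 1 and mean[hi + 1] >= peak_tolerance * peak_val:
            hi += 1
        make("peak_domain_start", edges[lo])
        make("peak_domain_end", edges[hi + 1])

    if "boundary" in features:
        if kind == "foci":
            beyond = np.where((np.arange(len(mean)) > i_max) & (mean == 0))[0]
        else:
            beyond = np.where((np.arange(len(mean)) > i_max)
                              & (mean < intensity_floor * peak_val))[0]
        if len(beyond):
            make("boundary", edges[beyond[0]])
        else:
            out.append(ThresholdFeature(prefix + "boundary", None, None,
                                        None, reached=False))
    return ThresholdMap(out)


def to_cell_tiers(distance_um: float) -> float:
    """Distance from the margin in cell tiers (14 um/tier, 1 decimal)."""
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return round(distance_um / CELL_TIER_UM, 1)


# ---------------------------------------------------------------------------
# Statistics


def compare_groups(a, b):
    """Unpaired two-tailed equal-variance (pooled) t-test.

    Returns (t statistic, two-tailed p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance; t-test undefined")
    return float(res.statistic), float(res.pvalue)


def correlation_with_distance(values, distances):
    """Pearson correlation coefficient r of values against distances."""
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(values) != len(distances) or len(values) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(values) == 0 or np.std(distances) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(values, distances).statistic)


@dataclass
class DecayFit:
    length_um: float
    amplitude: float
    decaying: bool


def decay_length(profile: SpatialProfile, min_points: int = 3) -> DecayFit:
    """Exponential length constant of the post-peak profile tail.

    Fits ``A exp(-x/lambda)`` by nonlinear least squares (log-linear
    start) to the mean profile beyond its maximal bin.  A
    non-decreasing tail is flagged (``decaying=False``) with lambda set
    to infinity.
    """
    mean = profile.mean
    x = profile.bin_centers
    i_max = int(np.nanargmax(mean))
    xs = x[i_max:]
    ys = mean[i_max:]
    ok = ~np.isnan(ys)
    xs, ys = xs[ok], ys[ok]
    if len(xs) < min_points:
        raise ValueError(f"need >= {min_points} bins beyond the peak")
    if ys[-1] >= ys[0] or np.all(ys <= 0):
        return DecayFit(np.inf, float(ys[0]), False)
    pos = ys > 0
    slope, intercept = np.polyfit(xs[pos], np.log(ys[pos]), 1)
    lam0 = -1.0 / slope if slope < 0 else (xs[-1] - xs[0])
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, lam: a * np.exp(-t / lam), xs, ys,
            p0=(float(np.exp(intercept)), float(abs(lam0))),
            maxfev=10000)
        a, lam = popt
    except RuntimeError:
        a, lam = float(np.exp(intercept)), float(abs(lam0))
    if lam <= 0:
        return DecayFit(np.inf, float(a), False)
    return DecayFit(float(lam), float(a), True)
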