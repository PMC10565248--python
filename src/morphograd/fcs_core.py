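"""Fluorescence correlation spectroscopy core: autocorrelation models,
multi-tau correlation of photon traces, calibration, curve fitting and
model selection.

The observation volume is modelled as a 3D Gaussian with lateral 1/e²
radius ``omega_o`` and axial radius ``z_o``; the structural parameter is
``S = z_o / omega_o`` (≈5 for a well-aligned confocal spot).  Freely
diffusing species produce the standard 3D diffusion autocorrelation

    G(tau) = [1 + T/(1-T) exp(-tau/tau_T)] * (1/N_p)
             * sum_i F_i (1 + tau/tau_Di)^-1 (1 + tau/(S^2 tau_Di))^-1/2

with particle number ``N_p``, component fractions ``F_i`` (sum 1), dwell
times ``tau_Di`` and a multiplicative triplet-blinking factor with dark
fraction ``T`` and relaxation time ``tau_T``.  Diffusion coefficients and
molar concentrations follow from a dye calibration via ``D = omega_o^2 /
(4 tau_D)`` and ``C = N_p / (V_eff N_A)`` with ``V_eff = pi^{3/2}
omega_o^2 z_o``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import lmfit
from scipy import stats

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "DiffusionComponent",
    "FcsModel",
    "CalibrationResult",
    "FcsFitResult",
    "ModelSelection",
    "DegenerateTraceError",
    "GridMismatchError",
    "CalibrationQualityWarning",
    "model_g",
    "autocorrelate",
    "average_curves",
    "fit_curve",
    "calibrate",
    "select_model",
    "concentration",
    "count_rate",
]

AVOGADRO = 6.02214076e23

# Defaults mirroring the measurement protocol: triplet fraction and
# relaxation time are fixed, the structural parameter is fixed to the
# calibration average for samples.
DEFAULT_TRIPLET_FRACTION = 0.10
DEFAULT_TRIPLET_TIME = 30e-6
DEFAULT_STRUCTURAL_PARAMETER = 5.0


class DegenerateTraceError(ValueError):
    """Raised when a photon trace has no fluctuations to correlate."""


class GridMismatchError(ValueError):
    """Raised when correlation curves do not share a lag grid."""


class CalibrationQualityWarning(UserWarning):
    """Emitted when a calibration fit looks untrustworthy."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class PhotonTrace:
    """Binned photon counts from one confocal spot.

    bin_width : s, counts : non-negative ints per bin.
    """

    bin_width: float
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValueError("counts must be a 1D sequence")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        """Total trace length in seconds."""
        return self.bin_width * len(self.counts)

    @property
    def raw_count_rate_khz(self) -> float:
        """Mean detected count rate in kHz, before background subtraction."""
        return self.counts.sum() / self.duration / 1e3

    def rebin(self, factor: int) -> "PhotonTrace":
        """Sum adjacent bins by an integer factor (drops the remainder)."""
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        n = (len(self.counts) // factor) * factor
        c = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return PhotonTrace(self.bin_width * factor, c, self.label)


@dataclass
class CorrelationCurve:
    """Normalized fluctuation autocorrelation G(tau) on a lag grid.

    ``weights``, when present, are per-lag standard errors of ``g``.
    """

    lags: np.ndarray
    g: np.ndarray
    weights: np.ndarray | None = None
    n_repetitions: int = 1

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.lags.shape:
                raise ValueError("weights must match lags")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    def restrict(self, lo: float, hi: float) -> "CorrelationCurve":
        """Return the sub-curve with lags in [lo, hi]."""
        m = (self.lags >= lo) & (self.lags <= hi)
        w = self.weights[m] if self.weights is not None else None
        return CorrelationCurve(self.lags[m], self.g[m], w, self.n_repetitions)


@dataclass
class DiffusionComponent:
    fraction: float
    dwell_time: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")


@dataclass
class FcsModel:
    """3D-1C or 3D-2C diffusion model with a fixed-by-default triplet term.

    ``vary`` flags which parameters float in a fit; by convention the
    triplet parameters and the structural parameter are fixed for sample
    fits and only the calibration lets S float.
    """

    components: list
    n_particles: float = 1.0
    triplet_fraction: float = DEFAULT_TRIPLET_FRACTION
    triplet_time: float = DEFAULT_TRIPLET_TIME
    structural_parameter: float = DEFAULT_STRUCTURAL_PARAMETER
    vary: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.components) not in (1, 2):
            raise ValueError("model must have 1 or 2 components")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must lie in [0, 1)")
        if self.structural_parameter <= 1.0:
            raise ValueError("structural_parameter must exceed 1")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @classmethod
    def one_component(cls, n_particles=1.0, dwell_time=1e-4, **kw):
        return cls([DiffusionComponent(1.0, dwell_time)], n_particles, **kw)

    @classmethod
    def two_component(cls, n_particles=1.0, dwell_fast=1e-4, dwell_slow=2e-3,
                      fraction_fast=0.9, **kw):
        return cls(
            [DiffusionComponent(fraction_fast, dwell_fast),
             DiffusionComponent(1.0 - fraction_fast, dwell_slow)],
            n_particles, **kw)


@dataclass
class CalibrationResult:
    """Observation-volume geometry from a reference-dye measurement."""

    omega_o: float          # lateral 1/e^2 radius, um
    z_o: float              # axial 1/e^2 radius, um
    reference_d: float      # literature D of the dye, um^2/s
    fit: "FcsFitResult | None" = None

    def __post_init__(self):
        if self.omega_o <= 0:
            raise ValueError("omega_o must be positive")
        if self.z_o <= self.omega_o:
            raise ValueError("z_o must exceed omega_o")

    @property
    def structural_parameter(self) -> float:
        return self.z_o / self.omega_o

    @property
    def v_eff_fl(self) -> float:
        """Effective volume pi^{3/2} omega_o^2 z_o in femtoliters (= um^3)."""
        return np.pi ** 1.5 * self.omega_o ** 2 * self.z_o


@dataclass
class FcsFitResult:
    model: FcsModel
    reduced_chi2: float
    residuals: np.ndarray
    converged: bool
    n_varied: int
    message: str = ""
    calibration: CalibrationResult | None = None

    @property
    def derived_d(self) -> list | None:
        """Diffusion coefficient per component (um^2/s), D = omega^2/(4 tau)."""
        if self.calibration is None:
            return None
        w2 = self.calibration.omega_o ** 2
        return [w2 / (4.0 * c.dwell_time) for c in self.model.components]

    @property
    def concentration_nm(self) -> float | None:
        """Molar concentration in nM from N_p and the calibrated volume."""
        if self.calibration is None:
            return None
        return concentration(self.model.n_particles, self.calibration)

    def to_dict(self) -> dict:
        d = {
            "n_particles": self.model.n_particles,
            "components": [
                {"fraction": c.fraction, "dwell_time_s": c.dwell_time}
                for c in self.model.components
            ],
            "triplet_fraction": self.model.triplet_fraction,
            "triplet_time_s": self.model.triplet_time,
            "structural_parameter": self.model.structural_parameter,
            "vary": dict(self.model.vary),
            "reduced_chi2": self.reduced_chi2,
            "converged": bool(self.converged),
        }
        if self.calibration is not None:
            d["derived_d_um2_s"] = self.derived_d
            d["concentration_nM"] = self.concentration_nm
        return d


@dataclass
class ModelSelection:
    choice: int             # 1 or 2 components
    f_statistic: float
    p_value: float
    window: tuple


# ---------------------------------------------------------------------------
# Model evaluation


def model_g(model: FcsModel, lags) -> np.ndarray:
    """Evaluate G(tau) of a 3D diffusion model on the given lags."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lags must be positive")
    S2 = model.structural_parameter ** 2
    diff = np.zeros_like(tau)
    for c in model.components:
        x = tau / c.dwell_time
        diff += c.fraction / ((1.0 + x) * np.sqrt(1.0 + x / S2))
    T = model.triplet_fraction
    trip = 1.0
    if T > 0:
        trip = 1.0 + T / (1.0 - T) * np.exp(-tau / model.triplet_time)
    return trip * diff / model.n_particles


# ---------------------------------------------------------------------------
# Multi-tau correlation


def multi_tau_lag_grid(n_bins: int, bin_width: float,
                       points_per_cascade: int = 16,
                       max_lag: float | None = None):
    """Quasi-logarithmic (lag, rebin-level) pairs of the multi-tau scheme.

    Cascade 0 holds ``points_per_cascade`` lags at the base bin width;
    every further cascade doubles the bin width and contributes the upper
    half of the lag channels, so coarse lags are estimated from rebinned
    (noise-averaged) signals.
    """
    m = points_per_cascade
    if m < 4 or m % 2:
        raise ValueError("points_per_cascade must be an even number >= 4")
    if max_lag is None:
        max_lag = n_bins * bin_width / 4.0
    out = []  # (lag seconds, level, k in units of level bin width)
    level = 0
    n = n_bins
    while True:
        width = bin_width * (1 << level)
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            lag = k * width
            if k >= n or lag > max_lag:
                return out
            out.append((lag, level, k))
        level += 1
        n //= 2
        if n < 2:
            return out


def _correlate_at(signal: np.ndarray, k: int) -> float:
    """Symmetric-normalized correlation of one channel: E[F_i F_{i+k}] /
    (E[F_head] E[F_tail]) - 1."""
    head = signal[:-k]
    tail = signal[k:]
    mh = head.mean()
    mt = tail.mean()
    if mh == 0.0 or mt == 0.0:
        raise DegenerateTraceError("trace mean vanishes; cannot normalize")
    return float(head @ tail) / (len(head) * mh * mt) - 1.0


def autocorrelate(trace: PhotonTrace, points_per_cascade: int = 16,
                  max_lag: float | None = None) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon-count trace.

    Returns the normalized fluctuation autocorrelation
    ``<dF(t) dF(t+tau)> / <F>^2`` on a quasi-logarithmic lag grid
    (doubling bin width per cascade).  Uses the symmetric normalization
    (separate head/tail means) which removes the leading finite-length
    bias of the naive estimator.
    """
    if len(trace.counts) < 2:
        raise ValueError("trace needs at least 2 bins")
    signal = trace.counts.astype(float)
    if signal.mean() == 0.0:
        raise DegenerateTraceError("zero-mean trace has no signal")
    grid = multi_tau_lag_grid(len(signal), trace.bin_width,
                              points_per_cascade, max_lag)
    lags = np.empty(len(grid))
    g = np.empty(len(grid))
    level_signal = {0: signal}
    cur = signal
    cur_level = 0
    for i, (lag, level, k) in enumerate(grid):
        while cur_level < level:
            n = (len(cur) // 2) * 2
            cur = cur[:n].reshape(-1, 2).sum(axis=1)
            cur_level += 1
            level_signal[cur_level] = cur
        lags[i] = lag
        g[i] = _correlate_at(level_signal[level], k)
    return CorrelationCurve(lags, g)


def average_curves(curves) -> CorrelationCurve:
    """Pointwise mean of repeated curves; weights become standard errors."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    base = curves[0]
    for c in curves[1:]:
        if len(c.lags) != len(base.lags) or not np.allclose(
                c.lags, base.lags, rtol=0, atol=0):
            raise GridMismatchError("curves must share an identical lag grid")
    G = np.stack([c.g for c in curves])
    mean = G.mean(axis=0)
    if len(curves) > 1:
        se = G.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        se = base.weights
    return CorrelationCurve(base.lags.copy(), mean, se,
                            n_repetitions=sum(c.n_repetitions for c in curves))


# ---------------------------------------------------------------------------
# Fitting


def _params_from_model(spec: FcsModel) -> lmfit.Parameters:
    p = lmfit.Parameters()
    v = spec.vary
    p.add("n_particles", value=spec.n_particles, min=1e-6, max=1e6,
          vary=v.get("n_particles", True))
    p.add("triplet_fraction", value=spec.triplet_fraction, min=0.0, max=0.999,
          vary=v.get("triplet_fraction", False))
    p.add("triplet_time", value=spec.triplet_time, min=1e-7, max=1e-3,
          vary=v.get("triplet_time", False))
    p.add("structural_parameter", value=spec.structural_parameter,
          min=1.2, max=20.0, vary=v.get("structural_parameter", False))
    p.add("tau_d1", value=spec.components[0].dwell_time, min=1e-6, max=1.0,
          vary=v.get("dwell_times", True))
    if spec.n_components == 2:
        # slow dwell expressed as a ratio >= 2 of the fast one: keeps the
        # components ordered and prevents collapse onto a single decay
        ratio = spec.components[1].dwell_time / spec.components[0].dwell_time
        p.add("tau_ratio", value=max(ratio, 2.0), min=2.0, max=1e5,
              vary=v.get("dwell_times", True))
        p.add("tau_d2", expr="tau_d1 * tau_ratio")
        p.add("f1", value=spec.components[0].fraction, min=0.0, max=1.0,
              vary=v.get("fractions", True))
    return p


def _model_from_params(p, n_components: int, vary: dict) -> FcsModel:
    if n_components == 1:
        comps = [DiffusionComponent(1.0, p["tau_d1"].value)]
    else:
        f1 = p["f1"].value
        comps = [DiffusionComponent(f1, p["tau_d1"].value),
                 DiffusionComponent(1.0 - f1, p["tau_d2"].value)]
    return FcsModel(comps, p["n_particles"].value,
                    p["triplet_fraction"].value, p["triplet_time"].value,
                    p["structural_parameter"].value, vary=dict(vary))


def _residual(p, lags, g, inv_sigma, n_components):
    S2 = p["structural_parameter"].value ** 2
    x1 = lags / p["tau_d1"].value
    diff = (1.0 if n_components == 1 else p["f1"].value) / (
        (1.0 + x1) * np.sqrt(1.0 + x1 / S2))
    if n_components == 2:
        x2 = lags / p["tau_d2"].value
        diff = diff + (1.0 - p["f1"].value) / (
            (1.0 + x2) * np.sqrt(1.0 + x2 / S2))
    T = p["triplet_fraction"].value
    trip = 1.0 + T / (1.0 - T) * np.exp(-lags / p["triplet_time"].value)
    model = trip * diff / p["n_particles"].value
    r = model - g
    return r * inv_sigma if inv_sigma is not None else r


def fit_curve(curve: CorrelationCurve, spec: FcsModel,
              calibration: CalibrationResult | None = None,
              lag_range: tuple | None = None,
              n_starts: int = 3, seed: int = 0) -> FcsFitResult:
    """Weighted nonlinear least-squares fit of a diffusion model.

    Two-component fits are restarted from ``n_starts`` seeded initial
    dwell-time splits and the lowest-chi-square solution is kept, to
    avoid local minima when the slow component is minor.  Components of
    the returned model are sorted fast-to-slow.
    """
    work = curve if lag_range is None else curve.restrict(*lag_range)
    if len(work.lags) < 10:
        raise ValueError("need >= 10 lag points to fit")
    inv_sigma = None
    if work.weights is not None and np.all(work.weights > 0):
        inv_sigma = 1.0 / work.weights
    amp = max(np.max(work.g), 1e-3)

    starts = [_params_from_model(spec)]
    if spec.n_components == 2 and n_starts > 1:
        rng = np.random.default_rng(seed)
        med = np.median(work.lags)
        for _ in range(n_starts - 1):
            p = _params_from_model(spec)
            p["tau_d1"].value = float(np.clip(
                med * rng.uniform(0.02, 0.3), 1e-6, 1.0))
            p["tau_ratio"].value = rng.uniform(5.0, 50.0)
            p["f1"].value = rng.uniform(0.6, 0.98)
            starts.append(p)
    for p in starts:  # amplitude-informed start for N_p
        if p["n_particles"].vary:
            p["n_particles"].value = float(np.clip(1.0 / amp, 1e-6, 1e6))

    best = None
    for p in starts:
        try:
            res = lmfit.minimize(
                _residual, p, args=(work.lags, work.g, inv_sigma,
                                    spec.n_components),
                method="leastsq", nan_policy="raise")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    model = _model_from_params(best.params, spec.n_components, spec.vary)
    if spec.n_components == 2 and model.components[0].dwell_time > \
            model.components[1].dwell_time:
        model = replace(model, components=model.components[::-1])
    converged = bool(best.success)
    if not converged:
        warnings.warn("FCS fit did not converge: " + str(best.message))
    resid_full = _residual(best.params, curve.lags, curve.g, None,
                           spec.n_components)
    nfree = max(best.nfree, 1)
    return FcsFitResult(model=model, reduced_chi2=best.chisqr / nfree,
                        residuals=np.asarray(resid_full), converged=converged,
                        n_varied=best.nvarys, message=str(best.message),
                        calibration=calibration)


def calibrate(reference_curve: CorrelationCurve, reference_d: float = 435.0,
              lag_range: tuple | None = None) -> CalibrationResult:
    """Calibrate the observation volume from a reference-dye curve.

    Fits 3D-1C with the triplet parameters fixed at the protocol defaults
    and the structural parameter free, then converts the fitted dwell
    time with the literature diffusion coefficient of the dye:
    ``omega_o = sqrt(4 reference_d tau_D)``, ``z_o = S omega_o``.
    """
    if reference_d <= 0:
        raise ValueError("reference_d must be positive")
    spec = FcsModel.one_component(
        n_particles=1.0, dwell_time=2e-5,
        vary={"structural_parameter": True})
    fit = fit_curve(reference_curve, spec, lag_range=lag_range)
    tau_d = fit.model.components[0].dwell_time
    S = fit.model.structural_parameter
    if not 2.0 <= S <= 10.0:
        warnings.warn(
            f"fitted structural parameter {S:.2f} outside [2, 10]; "
            "calibration may be unreliable", CalibrationQualityWarning)
    omega = np.sqrt(4.0 * reference_d * tau_d)  # um
    cal = CalibrationResult(omega_o=omega, z_o=S * omega,
                            reference_d=reference_d, fit=fit)
    return cal


def select_model(curve: CorrelationCurve, fit1: FcsFitResult,
                 fit2: FcsFitResult,
                 window: tuple = (0.5e-3, 50e-3),
                 alpha: float = 0.05) -> ModelSelection:
    """Choose between nested 1C and 2C fits by an F-test on a lag window.

    The two-component model is preferred only when its residual-sum
    improvement exceeds the parameter-count expectation at level
    ``alpha``, evaluated on lags in ``window`` (default 0.5-50 ms, the
    band where the two decays are distinguishable).
    """
    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    n = int(mask.sum())
    if n < 5:
        raise ValueError("selection window must contain >= 5 lags")
    rss1 = float(np.sum(fit1.residuals[mask] ** 2))
    rss2 = float(np.sum(fit2.residuals[mask] ** 2))
    dp = fit2.n_varied - fit1.n_varied
    df2 = n - fit2.n_varied
    if dp <= 0 or df2 <= 0:
        raise ValueError("fits are not properly nested for this window")
    if rss2 <= 0:
        return ModelSelection(2, np.inf, 0.0, window)
    f = ((rss1 - rss2) / dp) / (rss2 / df2)
    p = float(stats.f.sf(max(f, 0.0), dp, df2))
    return ModelSelection(2 if p < alpha else 1, f, p, window)


# ---------------------------------------------------------------------------
# Derived quantities


def concentration(n_particles: float, calibration: CalibrationResult) -> float:
    """Molar concentration in nM: C = N_p / (V_eff N_A)."""
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    v_eff_liters = calibration.v_eff_fl * 1e-15
    return n_particles / (v_eff_liters * AVOGADRO) * 1e9


def count_rate(trace: PhotonTrace, background_khz: float = 0.0) -> float:
    """Background-subtracted mean count rate in kHz (clipped at zero)."""
    if background_khz < 0:
        raise ValueError("background must be non-negative")
    raw = trace.raw_count_rate_khz
    cr = raw - background_khz
    if cr < 0:
        warnings.warn(
            f"background {background_khz:.3g} kHz exceeds raw rate "
            f"{raw:.3g} kHz; clipping to zero")
        cr = 0.0
    return cr
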