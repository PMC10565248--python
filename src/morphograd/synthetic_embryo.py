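"""Synthetic neural-plate datasets with known ground truth.

Generates the spatial structure the profile analysis assumes: a graded
extracellular morphogen curve along the animal-vegetal axis (distance
measured from the embryonic margin), inhomogeneous-Poisson smFISH foci
point sets per target gene, nuclear reporter intensities responding to
the gradient, rendered 3D image stacks, and multiplexed pixel spectra
mixing a target fluorophore with autofluorescence endmembers.

Distances are in micrometres throughout; one cell tier is 14 um (the
10-tier point sits at 140 um from the margin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CELL_TIER_UM",
    "DEFAULT_PEAK_NM",
    "GradientCurve",
    "ExpressionProfileSpec",
    "StripGeometry",
    "EmbryoPhantom",
    "make_gradient",
    "default_gradient",
    "tbxta_spec",
    "etv4_spec",
    "sample_foci",
    "sample_nuclei",
    "hill_response",
    "make_phantom",
    "render_stack",
    "make_spectral_stack",
]

CELL_TIER_UM = 14.0          # 140 um ~ 10 cell tiers
DEFAULT_PEAK_NM = 8.0        # source-domain concentration C0

#: Default relative gradient anchors (um, level).  Levels in the two
#: marginal-most tiers sit below the peak, the peak plateau spans
#: ~40-55 um, and the decay passes through 0.8 at 70 um and 0.4 at
#: 140 um before a smooth tail.
DEFAULT_GRADIENT_ANCHORS = (
    (0.0, 0.60), (14.0, 0.80), (40.0, 1.00), (55.0, 1.00),
    (70.0, 0.80), (140.0, 0.40), (210.0, 0.18), (280.0, 0.08),
    (300.0, 0.06),
)


@dataclass
class GradientCurve:
    """Relative morphogen level vs distance from the margin.

    ``levels`` are normalized to the peak (values in [0, 1]); the single
    scalar ``peak_nm`` anchors the curve to an absolute concentration.
    """

    distance_um: np.ndarray
    levels: np.ndarray
    peak_nm: float = DEFAULT_PEAK_NM
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(self.distance_um) <= 0):
            raise ValueError("distance grid must be increasing")
        if np.any(self.levels < 0) or np.any(self.levels > 1 + 1e-9):
            raise ValueError("levels must lie in [0, 1]")
        if self._interp is None:
            self._interp = PchipInterpolator(self.distance_um, self.levels)

    def __call__(self, x):
        return np.clip(self._interp(x), 0.0, 1.0)

    def absolute_nm(self, x):
        """Absolute concentration (nM) at distance x."""
        return self(x) * self.peak_nm


def make_gradient(anchors=DEFAULT_GRADIENT_ANCHORS,
                  peak_nm: float = DEFAULT_PEAK_NM,
                  grid_step: float = 1.0) -> GradientCurve:
    """Shape-preserving (monotone cubic) curve through relative anchors.

    Anchors must be normalized to the peak (max level 1) and must be
    non-increasing beyond the peak anchor; the marginal-most tiers may
    carry depressed levels (as the measured curve does).
    """
    a = np.asarray(anchors, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or len(a) < 2:
        raise ValueError("anchors must be a sequence of (distance, level)")
    x, y = a[:, 0], a[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("anchor distances must be strictly increasing")
    if np.any(y < 0) or np.any(y > 1 + 1e-12):
        raise ValueError("anchor levels must lie in [0, 1]")
    i_peak = int(np.argmax(y))
    if np.any(np.diff(y[i_peak:]) > 1e-12):
        raise ValueError("anchors beyond the peak must be non-increasing")
    interp = PchipInterpolator(x, y)
    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    # PCHIP is monotone between anchors, so it never overshoots [0, 1]
    return GradientCurve(grid, np.clip(interp(grid), 0.0, 1.0), peak_nm,
                         _interp=interp)


def default_gradient(peak_nm: float = DEFAULT_PEAK_NM) -> GradientCurve:
    return make_gradient(DEFAULT_GRADIENT_ANCHORS, peak_nm)


@dataclass
class ExpressionProfileSpec:
    """Expected smFISH foci rate along the axis for one gene.

    ``rate_anchors`` define, by linear interpolation, the expected
    number of foci per 10-um band across the strip; the absolute scale
    is arbitrary (profiles are normalized downstream).
    """

    gene: str
    rate_anchors: tuple
    domain_um: tuple = (0.0, 300.0)

    def rate(self, x):
        """Expected foci per 10-um band at distance x (vectorized)."""
        a = np.asarray(self.rate_anchors, dtype=float)
        out = np.interp(np.asarray(x, dtype=float), a[:, 0], a[:, 1],
                        left=a[0, 1], right=a[-1, 1])
        lo, hi = self.domain_um
        out = np.where((np.asarray(x) < lo) | (np.asarray(x) > hi), 0.0, out)
        if np.any(out < 0):
            raise ValueError("rate must be non-negative")
        return out


def tbxta_spec(peak_rate: float = 80.0) -> ExpressionProfileSpec:
    """Margin-confined target: maximal over 40-70 um, zero beyond 140 um."""
    return ExpressionProfileSpec("tbxta", (
        (0.0, 0.3 * peak_rate), (40.0, peak_rate), (70.0, peak_rate),
        (140.0, 0.0), (300.0, 0.0),
    ))


def etv4_spec(peak_rate: float = 80.0) -> ExpressionProfileSpec:
    """Broadly expressed target: foci everywhere, peak over 70-140 um."""
    return ExpressionProfileSpec("etv4", (
        (0.0, 0.35 * peak_rate), (60.0, 0.60 * peak_rate),
        (70.0, peak_rate), (140.0, peak_rate),
        (155.0, 0.40 * peak_rate), (300.0, 0.25 * peak_rate),
    ))


@dataclass
class StripGeometry:
    """Analysis strip along the animal-vegetal axis (x from the margin)."""

    length_um: float = 300.0     # x: distance from margin
    width_um: float = 100.0      # y
    depth_um: float = 20.0       # z

    def contains(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        return ((xyz[:, 0] >= 0) & (xyz[:, 0] <= self.length_um)
                & (xyz[:, 1] >= 0) & (xyz[:, 1] <= self.width_um)
                & (xyz[:, 2] >= 0) & (xyz[:, 2] <= self.depth_um))


def sample_foci(spec: ExpressionProfileSpec, geometry: StripGeometry,
                seed: int = 0) -> pd.DataFrame:
    """Inhomogeneous-Poisson smFISH foci along x, uniform in y and z.

    The rate function counts expected foci per 10-um band, so the line
    density is rate/10 per um.  Sampling inverts the cumulative rate on
    a fine grid; output columns: x_um, y_um, z_um, intensity.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, geometry.length_um, 4 * int(geometry.length_um) + 1)
    dens = spec.rate(grid) / 10.0
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    total = cum[-1]
    n = rng.poisson(total) if total > 0 else 0
    u = np.sort(rng.random(n)) * total
    x = np.interp(u, cum, grid)
    y = rng.random(n) * geometry.width_um
    z = rng.random(n) * geometry.depth_um
    # per-focus brightness scatter typical of single-transcript spots
    inten = rng.lognormal(mean=0.0, sigma=0.25, size=n)
    order = rng.permutation(n)
    return pd.DataFrame({"x_um": x[order], "y_um": y[order],
                         "z_um": z[order], "intensity": inten[order]})


def hill_response(level, k: float = 0.2):
    """Saturating (Hill-type, h=1) reporter response to the gradient.

    Shallow by construction: relative output varies much less than the
    input over the gradient's dynamic range, as a stable nuclear
    reporter accumulating downstream of saturable signaling would.
    """
    level = np.asarray(level, dtype=float)
    return level / (level + k)


def sample_nuclei(gradient: GradientCurve, geometry: StripGeometry,
                  seed: int = 0, response=hill_response,
                  spacing_um: float = 9.0, radius_um: float = 2.5,
                  noise_sigma: float = 0.15) -> pd.DataFrame:
    """Nuclei on a jittered (hard-core) lattice with graded reporter levels.

    Reporter intensity = response(gradient(x)) x lognormal noise; the
    response must be monotone non-decreasing in the gradient level.
    Columns: x_um, y_um, z_um, radius_um, intensity.
    """
    rng = np.random.default_rng(seed)
    jitter = max((spacing_um - 2 * radius_um) / 2, 0.0)  # preserves hard core
    xs = np.arange(spacing_um / 2, geometry.length_um, spacing_um)
    ys = np.arange(spacing_um / 2, geometry.width_um, spacing_um)
    zs = np.arange(spacing_um / 2, geometry.depth_um, spacing_um)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    pts = pts[geometry.contains(pts)]
    level = gradient(pts[:, 0])
    inten = response(level) * rng.lognormal(0.0, noise_sigma, size=len(pts))
    return pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1],
                         "z_um": pts[:, 2], "radius_um": radius_um,
                         "intensity": inten})


@dataclass
class EmbryoPhantom:
    """One synthetic embryo strip: foci tables per gene, nuclei, gradient."""

    geometry: StripGeometry
    foci: dict                    # gene -> DataFrame
    nuclei: pd.DataFrame
    gradient: GradientCurve
    seed: int


def make_phantom(seed: int = 0, geometry: StripGeometry | None = None,
                 gradient: GradientCurve | None = None,
                 foci_specs=None) -> EmbryoPhantom:
    """Default phantom: graded curve, tbxta + etv4 foci, reporter nuclei."""
    geometry = geometry or StripGeometry()
    gradient = gradient or default_gradient()
    specs = foci_specs or [tbxta_spec(), etv4_spec()]
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(specs) + 1)
    foci = {s.gene: sample_foci(s, geometry,
                                seed=int(c.generate_state(1)[0] % 2**31))
            for s, c in zip(specs, child)}
    nuclei = sample_nuclei(gradient, geometry,
                           seed=int(child[-1].generate_state(1)[0] % 2**31))
    return EmbryoPhantom(geometry, foci, nuclei, gradient, seed)


# ---------------------------------------------------------------------------
# Rendering


def render_stack(points: pd.DataFrame, geometry: StripGeometry,
                 voxel_um=(0.5, 0.5, 0.5), psf_sigma_um: float = 0.5,
                 spheres: bool = False, background: float = 10.0,
                 read_noise_frac: float = 0.02, amplitude: float = 200.0,
                 seed: int = 0) -> np.ndarray:
    """Render a point table into a (z, y, x) stack with Poisson + read noise.

    Foci become 3D Gaussians of width ``psf_sigma_um``; with
    ``spheres=True`` rows are drawn as filled spheres of their
    ``radius_um`` (soft-edged), for nuclei.  Intensities scale the
    ``amplitude`` (expected photons at a focus center).
    """
    import warnings as _w
    vz, vy, vx = voxel_um  # voxel ordering matches the (z, y, x) stack
    if not spheres and max(voxel_um) > 2 * psf_sigma_um:
        _w.warn("voxel size coarser than 2x spot sigma; spots may alias")
    nx = int(np.ceil(geometry.length_um / vx))
    ny = int(np.ceil(geometry.width_um / vy))
    nz = int(np.ceil(geometry.depth_um / vz))
    img = np.zeros((nz, ny, nx), dtype=float)
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    for row in points.itertuples(index=False):
        x0, y0, z0 = row.x_um, row.y_um, row.z_um
        amp = amplitude * row.intensity
        if spheres:
            r = row.radius_um
            ext = r + 2 * max(voxel_um)
        else:
            r = psf_sigma_um
            ext = 4 * psf_sigma_um
        ix = slice(max(int((x0 - ext) / vx), 0), min(int((x0 + ext) / vx) + 2, nx))
        iy = slice(max(int((y0 - ext) / vy), 0), min(int((y0 + ext) / vy) + 2, ny))
        iz = slice(max(int((z0 - ext) / vz), 0), min(int((z0 + ext) / vz) + 2, nz))
        dz = zc[iz] - z0
        dy = yc[iy] - y0
        dx = xc[ix] - x0
        d2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dx[None, None, :] ** 2)
        if spheres:
            # soft-edged sphere: full amplitude inside, Gaussian skirt
            patch = amp * np.exp(-np.maximum(np.sqrt(d2) - r, 0.0) ** 2
                                 / (2 * (0.25 * r) ** 2))
        else:
            patch = amp * np.exp(-d2 / (2 * r ** 2))
        img[iz, iy, ix] += patch
    rng = np.random.default_rng(seed)
    img = rng.poisson(img + background).astype(float)
    img += rng.normal(0.0, read_noise_frac * max(amplitude, 1.0),
                      size=img.shape)
    return img


def make_spectral_stack(abundance_maps: np.ndarray,
                        endmember_spectra: np.ndarray,
                        noise_sigma: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Mix per-pixel spectra from abundances and endmember spectra.

    abundance_maps: (E, Y, X) non-negative; endmember_spectra: (E, C)
    non-negative emission spectra.  Returns a channel-major (C, Y, X)
    stack; Gaussian noise of sd ``noise_sigma`` is added when requested.
    """
    A = np.asarray(abundance_maps, dtype=float)
    S = np.asarray(endmember_spectra, dtype=float)
    if A.ndim != 3 or S.ndim != 2 or A.shape[0] != S.shape[0]:
        raise ValueError("need (E, Y, X) abundances and (E, C) spectra "
                         "with matching endmember counts")
    if np.any(S < 0) or np.any(A < 0):
        raise ValueError("abundances and spectra must be non-negative")
    stack = np.einsum("eyx,ec->cyx", A, S)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
    return stack
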