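"""Image- and point-set-derived quantification.

Spectral linear unmixing (per-pixel non-negative least squares),
sum-projection strip intensity profiles, Laplacian-of-Gaussian blob
detection, and spatial binning of foci counts and nuclear intensities
along the animal-vegetal axis (10-um bins, left-closed/right-open,
origin at the embryonic margin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from skimage.feature import blob_log

__all__ = [
    "SpatialProfile",
    "BlobSet",
    "linear_unmix",
    "strip_intensity_profile",
    "detect_blobs",
    "bin_foci",
    "bin_nuclear_intensity",
]


@dataclass
class SpatialProfile:
    """A quantity binned along distance from the margin.

    ``per_sample`` is a (samples x bins) matrix (NaN marks empty bins);
    ``mean``/``sd`` aggregate across samples ignoring NaNs.
    """

    bin_edges: np.ndarray          # um, left-closed right-open
    per_sample: np.ndarray         # (n_samples, n_bins)
    normalization: str = "none"    # per-sample-max | control-average-max | none
    n_excluded: int = 0            # points outside the strip/axis range

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.per_sample = np.atleast_2d(np.asarray(self.per_sample,
                                                   dtype=float))
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be increasing")
        if self.per_sample.shape[1] != len(self.bin_edges) - 1:
            raise ValueError("per-sample matrix does not match bin count")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.per_sample, axis=0)

    @property
    def sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.per_sample, axis=0, ddof=1) \
                if len(self.per_sample) > 1 \
                else np.zeros(self.per_sample.shape[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left_um": self.bin_edges[:-1],
            "bin_right_um": self.bin_edges[1:],
            "mean": self.mean,
            "sd": self.sd,
        })


@dataclass
class BlobSet:
    """Detected blobs in physical coordinates (um).

    ``table`` columns: x_um, y_um, z_um, radius_um, intensity (mean
    intensity within the blob radius, arbitrary units).
    """

    table: pd.DataFrame
    voxel_um: tuple | None = None

    def __post_init__(self):
        if len(self.table) and np.any(self.table["radius_um"] <= 0):
            raise ValueError("blob radius must be positive")

    def __len__(self):
        return len(self.table)

    @classmethod
    def from_points(cls, df: pd.DataFrame, radius_um: float = 1.0):
        """Wrap a point table (e.g. phantom ground truth) as a BlobSet."""
        t = df.copy()
        if "radius_um" not in t:
            t["radius_um"] = radius_um
        if "intensity" not in t:
            t["intensity"] = 1.0
        return cls(t)


# ---------------------------------------------------------------------------
# Spectral unmixing


def linear_unmix(stack: np.ndarray, references: np.ndarray,
                 max_condition: float = 1e8):
    """Per-pixel non-negative least-squares spectral decomposition.

    stack: channel-major (C, Y, X); references: (E, C) endmember
    spectra.  Returns (abundances (E, Y, X), residual map (Y, X) of the
    per-pixel euclidean residual norm).
    """
    stack = np.asarray(stack, dtype=float)
    R = np.asarray(references, dtype=float)
    if stack.ndim != 3 or R.ndim != 2:
        raise ValueError("stack must be (C, Y, X), references (E, C)")
    n_ch, ny, nx = stack.shape
    if R.shape[1] != n_ch:
        raise ValueError("reference spectra must have one value per channel")
    if R.shape[0] > n_ch:
        raise ValueError("more endmembers than channels")
    if np.linalg.cond(R @ R.T) > max_condition:
        raise ValueError("reference spectra are (near-)collinear")
    A = R.T  # (C, E) design matrix
    pixels = stack.reshape(n_ch, -1)
    n_end = R.shape[0]
    out = np.empty((n_end, pixels.shape[1]))
    resid = np.empty(pixels.shape[1])
    for j in range(pixels.shape[1]):
        out[:, j], resid[j] = nnls(A, pixels[:, j])
    return out.reshape(n_end, ny, nx), resid.reshape(ny, nx)


# ---------------------------------------------------------------------------
# Strip intensity profile


def strip_intensity_profile(stack: np.ndarray, voxel_um,
                            strip_width_um: float = 100.0,
                            bin_width_um: float = 10.0,
                            normalize: bool = True) -> SpatialProfile:
    """Sum-project a (z, y, x) stack and profile it along x.

    The x axis runs away from the margin; a strip of ``strip_width_um``
    centred in y is averaged transversely, then binned along x.  With
    ``normalize`` the profile is scaled to its own maximum (making it
    invariant to exposure).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (z, y, x)")
    vz, vy, vx = (voxel_um if len(voxel_um) == 3 else
                  (voxel_um[0],) * 3)
    half = strip_width_um / 2.0
    ny = stack.shape[1]
    yc = (np.arange(ny) + 0.5) * vy
    mid = ny * vy / 2.0
    sel = np.abs(yc - mid) <= half
    if not np.any(sel):
        raise ValueError("strip narrower than one voxel row")
    proj = stack.sum(axis=0)            # sum-intensity z projection
    line = proj[sel, :].mean(axis=0)    # transverse average across strip
    xc = (np.arange(stack.shape[2]) + 0.5) * vx
    edges = np.arange(0.0, xc[-1] + bin_width_um, bin_width_um)
    idx = np.digitize(xc, edges) - 1
    prof = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = idx == b
        if np.any(m):
            prof[b] = line[m].mean()
    if normalize:
        peak = np.nanmax(prof)
        if peak > 0:
            prof = prof / peak
    return SpatialProfile(edges, prof[None, :],
                          "per-sample-max" if normalize else "none")


# ---------------------------------------------------------------------------
# Blob detection


def detect_blobs(stack: np.ndarray, voxel_um, radius_um: float = 1.0,
                 threshold_rel: float = 0.2) -> BlobSet:
    """Scale-matched 3D Laplacian-of-Gaussian detection.

    Detects blobs of the stated physical radius (sigma = r/sqrt(3) per
    the LoG scale relation), thresholding the LoG response at
    ``threshold_rel`` of its maximum.  Centroids are refined to
    sub-voxel precision by an intensity-weighted mean over the blob
    neighborhood; per-blob mean intensity is measured within the radius.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (z, y, x)")
    voxel = np.asarray(voxel_um, dtype=float)  # (z, y, x)
    sigma_um = radius_um / np.sqrt(3.0)
    sigma_vox = sigma_um / voxel
    if np.any(radius_um / voxel < 2.0):
        raise ValueError("radius must span >= 2 voxels on every axis; "
                         "use finer sampling")
    if np.all(stack == stack.max()) and stack.max() > 0:
        warnings.warn("stack appears saturated")
    lo = stack - stack.min()
    peaks = blob_log(lo, min_sigma=sigma_vox * 0.8, max_sigma=sigma_vox * 1.3,
                     num_sigma=3, threshold=None,
                     threshold_rel=threshold_rel)
    rows = []
    r_vox = radius_um / voxel
    for z, y, x, *_ in peaks:
        iz, iy, ix = int(round(z)), int(round(y)), int(round(x))
        sl = tuple(slice(max(int(c - r), 0), min(int(c + r) + 1, dim))
                   for c, r, dim in zip((iz, iy, ix),
                                        np.ceil(r_vox).astype(int),
                                        lo.shape))
        patch = lo[sl]
        zz, yy, xx = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl],
                                 indexing="ij")
        w = patch.sum()
        if w <= 0:
            cz, cy, cx = z, y, x
        else:
            cz = (patch * zz).sum() / w
            cy = (patch * yy).sum() / w
            cx = (patch * xx).sum() / w
        rows.append({
            "x_um": (cx + 0.5) * voxel[2],
            "y_um": (cy + 0.5) * voxel[1],
            "z_um": (cz + 0.5) * voxel[0],
            "radius_um": radius_um,
            "intensity": float(patch.mean()),
        })
    table = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "radius_um",
                                        "intensity"])
    return BlobSet(table, tuple(voxel))


# ---------------------------------------------------------------------------
# Binning


def _make_edges(extent_um: float, bin_width_um: float) -> np.ndarray:
    n = int(np.ceil(extent_um / bin_width_um))
    return np.arange(n + 1) * bin_width_um


def _bin_positions(x: np.ndarray, edges: np.ndarray):
    """Left-closed right-open bin index per position; -1 when outside."""
    idx = np.searchsorted(edges, x, side="right") - 1
    idx[(x < edges[0]) | (x >= edges[-1])] = -1
    return idx


def bin_foci(samples, extent_um: float = 300.0, bin_width_um: float = 10.0,
             normalization: str = "per-sample-max") -> SpatialProfile:
    """Foci counts per 10-um bin, per sample, with normalization.

    ``samples`` is a list of BlobSets (one per embryo).  Modes:
    per-sample-max (each sample scaled to its own maximal bin),
    control-average-max (all samples scaled by the mean of per-sample
    maxima — used when comparing a perturbed group against controls),
    or none.  Foci outside [0, extent) are excluded and counted.
    """
    if normalization not in ("per-sample-max", "control-average-max", "none"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    edges = _make_edges(extent_um, bin_width_um)
    mats, excluded = [], 0
    for s in samples:
        x = np.asarray(s.table["x_um"], dtype=float)
        idx = _bin_positions(x, edges)
        excluded += int(np.sum(idx < 0))
        counts = np.bincount(idx[idx >= 0], minlength=len(edges) - 1).astype(float)
        mats.append(counts)
    mat = np.array(mats)
    mat = _normalize(mat, normalization)
    return SpatialProfile(edges, mat, normalization, n_excluded=excluded)


def bin_nuclear_intensity(samples, extent_um: float = 300.0,
                          bin_width_um: float = 10.0,
                          normalization: str = "per-sample-max"
                          ) -> SpatialProfile:
    """Mean nuclear intensity per 10-um bin, per sample.

    Empty bins become NaN and are excluded from the aggregate.
    """
    if normalization not in ("per-sample-max", "control-average-max", "none"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    edges = _make_edges(extent_um, bin_width_um)
    mats, excluded = [], 0
    for s in samples:
        x = np.asarray(s.table["x_um"], dtype=float)
        inten = np.asarray(s.table["intensity"], dtype=float)
        idx = _bin_positions(x, edges)
        excluded += int(np.sum(idx < 0))
        prof = np.full(len(edges) - 1, np.nan)
        for b in range(len(edges) - 1):
            m = idx == b
            if np.any(m):
                prof[b] = inten[m].mean()
        mats.append(prof)
    mat = np.array(mats)
    mat = _normalize(mat, normalization)
    return SpatialProfile(edges, mat, normalization, n_excluded=excluded)


def _normalize(mat: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return mat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maxima = np.nanmax(mat, axis=1)
    maxima[maxima == 0] = np.nan
    if mode == "per-sample-max":
        return mat / maxima[:, None]
    # control-average-max: one shared scale, the average of sample maxima
    return mat / np.nanmean(maxima)
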