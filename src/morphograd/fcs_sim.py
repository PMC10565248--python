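"""Brownian-dynamics synthetic data for the FCS stage.

Simulates mixtures of freely diffusing fluorophores in a periodic box
under a 3D Gaussian detection profile and emits Poisson photon-count
traces together with their ground truth.  The detection profile matches
the analytic fit model exactly, so estimator error can be isolated from
model mismatch.  Optional two-state blinking emulates the triplet state
of a real dye.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .fcs_core import PhotonTrace

__all__ = [
    "SpeciesSpec",
    "BlinkingSpec",
    "SimConfig",
    "MeasurementRecord",
    "simulate_trace",
    "simulate_measurement_series",
    "molecules_per_um3",
]

AVOGADRO = 6.02214076e23


def molecules_per_um3(concentration_nm: float) -> float:
    """Number density (molecules/um^3) of a molar concentration in nM."""
    return concentration_nm * 1e-9 * AVOGADRO * 1e-15


@dataclass
class SpeciesSpec:
    """One freely diffusing fluorescent species.

    brightness is the detected count rate (kHz) of a molecule at the beam
    center; expected_count is the mean number of molecules in the box.
    """

    diffusion_coefficient: float    # um^2/s
    brightness: float = 3.0         # kHz per molecule at beam center
    expected_count: float = 10.0    # mean molecules in the box

    def __post_init__(self):
        if self.diffusion_coefficient <= 0 or self.brightness <= 0 \
                or self.expected_count < 0:
            raise ValueError("species parameters must be positive")


@dataclass
class BlinkingSpec:
    """Two-state (bright/dark) telegraph blinking.

    dark_fraction is the equilibrium dark-state occupancy and
    relaxation_time the telegraph correlation time 1/(k_on + k_off).
    """

    dark_fraction: float = 0.10
    relaxation_time: float = 30e-6

    def __post_init__(self):
        if not 0.0 < self.dark_fraction < 1.0:
            raise ValueError("dark_fraction must lie in (0, 1)")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be positive")


@dataclass
class SimConfig:
    species: list
    box: tuple = (2.4, 2.4, 8.0)    # um, periodic
    omega_o: float = 0.2            # um
    z_o: float = 1.0                # um
    time_step: float = 2e-5         # s; also the photon bin width
    duration: float = 10.0          # s
    background_rate: float = 0.0    # kHz
    seed: int = 0
    blinking: BlinkingSpec | None = None
    # "fixed": N = round(expected_count) per species (the periodic box is a
    # fixed realization of the ambient bath; focal-volume number
    # fluctuations still arise from diffusion).  "poisson": N drawn per
    # trace, adding bath-concentration scatter between realizations.
    number_sampling: str = "fixed"
    # record unwrapped positions of the first species every N steps into
    # the ground-truth record (diagnostics; 0 disables)
    record_stride: int = 0

    def __post_init__(self):
        if not self.species and self.background_rate <= 0:
            raise ValueError("need at least one species or background")
        if self.omega_o <= 0 or self.z_o <= self.omega_o:
            raise ValueError("require 0 < omega_o < z_o")
        bx, by, bz = self.box
        if min(bx, by) < 8 * self.omega_o or bz < 8 * self.z_o:
            raise ValueError(
                "box must be >= 8*omega_o laterally and >= 8*z_o axially")
        if self.species:
            dmax = max(s.diffusion_coefficient for s in self.species)
            dt_max = self.omega_o ** 2 / (20.0 * dmax)
            if self.time_step > dt_max:
                raise ValueError(
                    f"time step {self.time_step:g} s too coarse for "
                    f"D={dmax:g} um^2/s; use dt <= {dt_max:.2g} s")
        if self.duration < self.time_step:
            raise ValueError("duration shorter than one time step")
        if self.number_sampling not in ("fixed", "poisson"):
            raise ValueError("number_sampling must be 'fixed' or 'poisson'")

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def v_eff_fl(self) -> float:
        return np.pi ** 1.5 * self.omega_o ** 2 * self.z_o

    def ground_truth(self) -> dict:
        """Analytic expectations implied by the configuration."""
        total = sum(s.expected_count for s in self.species) or np.nan
        psf_integral = (np.pi / 2) ** 1.5 * self.omega_o ** 2 * self.z_o
        bright = 1.0
        if self.blinking is not None:
            bright = 1.0 - self.blinking.dark_fraction
        cr = self.background_rate + bright * sum(
            s.expected_count * s.brightness * psf_integral / self.box_volume
            for s in self.species)
        return {
            "diffusion_coefficients": [s.diffusion_coefficient
                                       for s in self.species],
            "fractions": [s.expected_count / total for s in self.species],
            "expected_n_in_v_eff": sum(
                s.expected_count * self.v_eff_fl / self.box_volume
                for s in self.species),
            "expected_concentration_nM": sum(
                s.expected_count / self.box_volume for s in self.species
            ) / (AVOGADRO * 1e-15) * 1e9,
            "expected_count_rate_khz": cr,
            "seed": self.seed,
        }


@dataclass
class MeasurementRecord:
    position_um: float
    trace: PhotonTrace
    ground_truth: dict


@njit(cache=True)
def _chunk_kernel(pos, unwrapped, bright, normals, blink_u, step_std,
                  b_hz, bx, by, bz, inv_w2, inv_z2,
                  p_to_dark, p_to_bright, rate,
                  record, stride, phase, rec_out):  # pragma: no cover
    """Advance one species over one chunk of steps (arithmetic only).

    ``normals`` holds pre-generated unit Gaussians (molecule-major), so
    the kernel does pure position updates, periodic wrapping, optional
    telegraph blinking and Gaussian detection weights (skipped beyond
    3 radii where the weight is < e^-18), accumulating into ``rate``.
    """
    n = pos.shape[0]
    nc = normals.shape[1]
    for m in range(n):
        x = pos[m, 0]
        y = pos[m, 1]
        z = pos[m, 2]
        ux = unwrapped[m, 0]
        uy = unwrapped[m, 1]
        uz = unwrapped[m, 2]
        is_bright = bright[m]
        k_rec = 0
        for t in range(nc):
            dx = step_std * normals[m, t, 0]
            dy = step_std * normals[m, t, 1]
            dz = step_std * normals[m, t, 2]
            x += dx
            y += dy
            z += dz
            if x > bx * 0.5:
                x -= bx
            elif x < -bx * 0.5:
                x += bx
            if y > by * 0.5:
                y -= by
            elif y < -by * 0.5:
                y += by
            if z > bz * 0.5:
                z -= bz
            elif z < -bz * 0.5:
                z += bz
            if p_to_dark > 0.0:
                if is_bright:
                    if blink_u[m, t] < p_to_dark:
                        is_bright = False
                elif blink_u[m, t] < p_to_bright:
                    is_bright = True
            if record:
                ux += dx
                uy += dy
                uz += dz
                if (phase + t) % stride == 0:
                    rec_out[k_rec, m, 0] = ux
                    rec_out[k_rec, m, 1] = uy
                    rec_out[k_rec, m, 2] = uz
                    k_rec += 1
            if is_bright:
                arg = (x * x + y * y) * inv_w2 + z * z * inv_z2
                if arg < 18.0:
                    rate[t] += b_hz * np.exp(-arg)
        pos[m, 0] = x
        pos[m, 1] = y
        pos[m, 2] = z
        unwrapped[m, 0] = ux
        unwrapped[m, 1] = uy
        unwrapped[m, 2] = uz
        bright[m] = is_bright
    return k_rec


def simulate_trace(config: SimConfig, chunk_steps: int = 50_000):
    """Simulate one photon-count trace; returns (PhotonTrace, ground truth).

    Molecules are placed uniformly, take isotropic Gaussian steps of std
    sqrt(2 D dt) per axis with periodic wrapping, and emit photons as an
    inhomogeneous Poisson process with per-molecule rate
    brightness * exp(-2(x^2+y^2)/omega_o^2 - 2 z^2/z_o^2).  Random
    numbers come from a seeded SFC64 generator in bulk (float32 unit
    normals; the ~1e-7 relative step granularity is far below any
    physical scale here).
    """
    rng = np.random.Generator(np.random.SFC64(config.seed))
    dt = config.time_step
    n_steps = int(round(config.duration / dt))
    bx, by, bz = (float(v) for v in config.box)

    pops = []
    for s in config.species:
        if config.number_sampling == "poisson":
            n = int(rng.poisson(s.expected_count))
        else:
            n = int(round(s.expected_count))
        pos = (rng.random((n, 3)) - 0.5) * np.array([bx, by, bz])
        pops.append({
            "spec": s, "n": n, "pos": pos, "unwrapped": pos.copy(),
            "std": np.sqrt(2.0 * s.diffusion_coefficient * dt),
            "bright": np.ones(n, dtype=np.bool_),
        })

    p_to_dark = p_to_bright = 0.0
    if config.blinking is not None:
        k_sum = 1.0 / config.blinking.relaxation_time
        k_to_dark = config.blinking.dark_fraction * k_sum
        p_to_dark = -np.expm1(-k_to_dark * dt)
        p_to_bright = -np.expm1(-(k_sum - k_to_dark) * dt)
        for p in pops:
            p["bright"] = rng.random(p["n"]) > config.blinking.dark_fraction

    record = (config.record_stride > 0 and pops and pops[0]["n"] > 0)
    stride = max(config.record_stride, 1)
    recorded = []

    inv_w2 = 2.0 / config.omega_o ** 2
    inv_z2 = 2.0 / config.z_o ** 2
    counts = np.empty(n_steps, dtype=np.int64)
    start = 0
    while start < n_steps:
        nc = min(chunk_steps, n_steps - start)
        rate = np.full(nc, config.background_rate * 1e3)
        for ip, p in enumerate(pops):
            if p["n"] == 0:
                continue
            normals = rng.standard_normal((p["n"], nc, 3),
                                          dtype=np.float32)
            if p_to_dark > 0.0:
                blink_u = rng.random((p["n"], nc), dtype=np.float32)
            else:
                blink_u = np.empty((1, 1), dtype=np.float32)
            rec_this = record and ip == 0
            if rec_this:
                n_rec = len(range((-start) % stride, nc, stride))
                rec_out = np.empty((max(n_rec, 1), p["n"], 3))
            else:
                rec_out = np.empty((1, 1, 3))
            n_rec_done = _chunk_kernel(
                p["pos"], p["unwrapped"], p["bright"], normals, blink_u,
                p["std"], p["spec"].brightness * 1e3, bx, by, bz,
                inv_w2, inv_z2, p_to_dark, p_to_bright, rate,
                rec_this, stride, start, rec_out)
            if rec_this and n_rec_done:
                recorded.append(rec_out[:n_rec_done])
        counts[start:start + nc] = rng.poisson(rate * dt)
        start += nc

    label = "+".join(f"D={s.diffusion_coefficient:g}"
                     for s in config.species)
    trace = PhotonTrace(dt, counts, label=label or "background")
    truth = config.ground_truth()
    truth["realized_counts"] = [p["n"] for p in pops]
    if recorded:
        truth["unwrapped_positions"] = np.concatenate(recorded, axis=0)
    return trace, truth


def simulate_measurement_series(profile, positions, base_config: SimConfig,
                                seed: int | None = None):
    """One trace per position, species density scaled by ``profile(x)``.

    ``profile`` maps distance (um) to a non-negative relative level that
    multiplies every species' expected count of ``base_config``.  Child
    seeds are spawned deterministically from ``seed`` (default: the base
    config's seed).
    """
    positions = list(positions)
    if not positions:
        raise ValueError("positions must be non-empty")
    root = np.random.SeedSequence(
        base_config.seed if seed is None else seed)
    children = root.spawn(len(positions))
    records = []
    for pos, child in zip(positions, children):
        level = float(profile(pos))
        if level < 0:
            raise ValueError("profile must be non-negative")
        species = [replace(s, expected_count=s.expected_count * level)
                   for s in base_config.species]
        cfg = replace(base_config, species=species,
                      seed=int(child.generate_state(1)[0] % (2 ** 31)))
        trace, truth = simulate_trace(cfg)
        trace.label = f"x={pos:g}um"
        truth["position_um"] = pos
        truth["profile_level"] = level
        records.append(MeasurementRecord(pos, trace, truth))
    return records
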