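"""1D hindered-diffusion reaction-diffusion model of gradient formation.

Free morphogen diffuses from a marginal source, binds reversibly to
immobile extracellular sites (HSPGs), and is degraded; the bound pool is
immobile, so binding both retards spreading (effective diffusion
D_eff = D/(1 + k_on B_tot / k_off) in the fast-equilibrium, far-from-
saturation limit) and, when degradation acts predominantly on the bound
pool, shortens the gradient.  The model equations and parameter defaults
are this module's own assumptions: the underlying experiments establish
fast/slow pools and the response to binding-site removal, not rate
constants.

    dc/dt   = D d2c/dx2 - k_on c (B_tot - c_b) + k_off c_b
              - k_deg_free c + s(x)
    dc_b/dt = k_on c (B_tot - c_b) - k_off c_b - k_deg_bound c_b

Explicit finite differences on a uniform grid, zero-flux boundaries by
default (a Dirichlet option at x=0 supports analytic comparisons).
Units: um, s; concentrations in arbitrary (nM-like) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RDParams", "RDState", "step", "solve_to_steady_state",
           "slow_fraction", "scenario", "SCENARIOS"]


@dataclass
class RDParams:
    d_free: float = 55.0            # um^2/s, the measured fast component
    k_on: float = 8.4e-4            # 1/(conc s)
    k_off: float = 1.0              # 1/s
    b_tot: float = 100.0            # binding-site concentration
    k_deg_free: float = 5e-4        # 1/s
    k_deg_bound: float = 0.09       # 1/s: degradation mostly on bound pool
    source_rate: float = 1.0        # conc/s produced within the source strip
    source_width_um: float = 14.0   # one marginal cell tier
    length_um: float = 300.0
    dx_um: float = 2.0
    dt_s: float = 0.02
    left_boundary: str = "no-flux"  # or "dirichlet"
    left_value: float = 1.0         # used by the dirichlet boundary

    def __post_init__(self):
        vals = [self.d_free, self.k_on, self.k_off, self.b_tot,
                self.k_deg_free, self.k_deg_bound, self.source_rate]
        if any(v < 0 for v in vals):
            raise ValueError("rates and concentrations must be non-negative")
        if self.dt_s > self.dx_um ** 2 / (2.0 * max(self.d_free, 1e-12)):
            raise ValueError(
                f"unstable: dt must be <= dx^2/(2 D) = "
                f"{self.dx_um ** 2 / (2 * self.d_free):.3g} s")
        if self.left_boundary not in ("no-flux", "dirichlet"):
            raise ValueError("left_boundary must be 'no-flux' or 'dirichlet'")

    @property
    def n_cells(self) -> int:
        return int(round(self.length_um / self.dx_um))

    @property
    def x_um(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx_um

    def source_profile(self) -> np.ndarray:
        s = np.zeros(self.n_cells)
        s[self.x_um < self.source_width_um] = self.source_rate
        return s


@dataclass
class RDState:
    x_um: np.ndarray
    free: np.ndarray
    bound: np.ndarray
    time_s: float = 0.0
    steady: bool = False

    @property
    def total(self) -> np.ndarray:
        return self.free + self.bound

    def mass(self, dx_um: float) -> float:
        return float(self.total.sum() * dx_um)


def _laplacian(c: np.ndarray, dx: float, left: str, left_value: float):
    """Conservative Laplacian; ghost cells reflect (no-flux) or pin the
    first cell's face value (dirichlet at x=0)."""
    lap = np.empty_like(c)
    lap[1:-1] = c[:-2] - 2 * c[1:-1] + c[2:]
    lap[-1] = c[-2] - c[-1]
    if left == "no-flux":
        lap[0] = c[1] - c[0]
    else:
        lap[0] = (2 * left_value - 3 * c[0] + c[1])
    return lap / dx ** 2


def step(state: RDState, params: RDParams, n_steps: int = 1) -> RDState:
    """Advance the explicit scheme by ``n_steps`` (in place on copies)."""
    c = state.free.copy()
    cb = state.bound.copy()
    dx, dt = params.dx_um, params.dt_s
    src = params.source_profile()
    for _ in range(n_steps):
        bind = params.k_on * c * (params.b_tot - cb)
        unbind = params.k_off * cb
        dc = (params.d_free * _laplacian(c, dx, params.left_boundary,
                                         params.left_value)
              - bind + unbind - params.k_deg_free * c + src)
        dcb = bind - unbind - params.k_deg_bound * cb
        c = c + dt * dc
        cb = cb + dt * dcb
        if np.any(c < -1e-9) or np.any(cb < -1e-9):
            raise RuntimeError(
                "negative concentrations: reduce dt below "
                f"{dx ** 2 / (2 * params.d_free):.3g} s")
    return RDState(state.x_um, c, cb, state.time_s + n_steps * dt)


def solve_to_steady_state(params: RDParams, max_time_s: float = 2e4,
                          rel_tol: float = 1e-8,
                          init: RDState | None = None) -> RDState:
    """Integrate until the relative change per characteristic time drops
    below ``rel_tol``.

    The characteristic time is the slower of transport across the
    domain's decay scale and the binding relaxation; convergence is
    measured as max |dc| / (max c) over one such interval.
    """
    if init is None:
        x = params.x_um
        state = RDState(x, np.zeros(params.n_cells), np.zeros(params.n_cells))
    else:
        state = init
    t_bind = 1.0 / max(params.k_on * params.b_tot + params.k_off, 1e-9)
    t_transport = (params.length_um / 4) ** 2 / max(params.d_free, 1e-9)
    t_char = max(t_bind, t_transport, 1.0)
    interval = min(t_char, max_time_s / 20.0)
    n_check = max(int(interval / params.dt_s), 1)
    # tolerance scaled to the check interval so slow-transport regimes
    # are still judged per characteristic time
    tol = rel_tol * (n_check * params.dt_s) / t_char
    while state.time_s < max_time_s:
        new = step(state, params, n_check)
        scale = max(new.total.max(), 1e-300)
        change = np.max(np.abs(new.total - state.total)) / scale
        state = new
        if change < tol:
            state.steady = True
            return state
    state.steady = False
    return state


def slow_fraction(state: RDState, window_um: tuple = (0.0, 28.0)) -> float:
    """Bound fraction integral(c_b)/integral(c + c_b) over a window."""
    lo, hi = window_um
    m = (state.x_um >= lo) & (state.x_um <= hi)
    if not np.any(m):
        raise ValueError("window contains no grid cells")
    tot = np.sum(state.free[m] + state.bound[m])
    if tot <= 0:
        return 0.0
    return float(np.sum(state.bound[m]) / tot)


def _hepi(base: RDParams) -> RDParams:
    # heparinase removes most binding sites; with degradation acting
    # mainly on the bound pool the gradient becomes shallower (longer)
    return replace(base, b_tot=base.b_tot * 0.3)


def _tethered_clone(base: RDParams) -> RDParams:
    # membrane tethering abolishes extracellular diffusion; ligand stays
    # within the producing clone (residual mobility kept tiny but nonzero
    # for numerical regularity)
    d = 0.1
    return replace(base, d_free=d,
                   dt_s=min(base.dt_s, base.dx_um ** 2 / (2 * d) * 0.4))


def _morpho_trap(base: RDParams) -> RDParams:
    # uniform high-affinity, effectively irreversible immobile binder
    return replace(base, b_tot=base.b_tot * 10.0, k_off=1e-3,
                   k_deg_bound=base.k_deg_bound)


SCENARIOS = {
    "control": lambda base: base,
    "hepI": _hepi,
    "tethered_clone": _tethered_clone,
    "morpho_trap": _morpho_trap,
}


def scenario(name: str, base: RDParams | None = None) -> RDParams:
    """Preset parameter sets for the perturbation experiments."""
    base = base or RDParams()
    try:
        return SCENARIOS[name](base)
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {sorted(SCENARIOS)}") from None
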