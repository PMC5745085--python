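"""Deterministic integration of the dimerization networks.

The production schedule is discontinuous at ``t_on`` and ``t_off``, so the
ODE systems are integrated piecewise on ``[0, t_on]``, ``[t_on, t_off]`` and
``[t_off, t_end]`` with the state handed across segment boundaries; inside a
segment the synthesis rate is constant and the right-hand side smooth.
Segments are solved with the high-order explicit Runge-Kutta pair DOP853
(the systems are non-stiff at the published rates, and the 8th-order dense
output keeps interpolation error at the recorded grid points well below the
step-controller tolerance).

Alongside the concentrations, three cumulative integrals are co-integrated
(production inflow and the two degradation outflows), so that exact
conservation identities of the schemes can be checked per time point:

* Nodal ledger: ``cum_production = N + D + cum_deg_N`` (both models; the
  cold-start scheme converts one N per D, so the same identity applies).
* Vg1 ledger (primed only): ``V0 = V + D + cum_deg_V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import KineticParameters, ModelKind, M_PER_NM, S_PER_HPF

__all__ = [
    "Trajectory",
    "MassLedger",
    "IntegrationError",
    "default_grid",
    "integrate",
    "mass_ledger",
]

#: Default solver tolerances: rel_tol well below the percent scale of any
#: reported quantity, abs_tol well below the nM signal scale.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-15

#: Concentrations more negative than this (M) are treated as solver failure
#: rather than round-off; no clipping is ever applied.
NEGATIVE_TOL = 1e-12

#: Default output spacing (s): one row per minute.
DEFAULT_DT = 60.0

#: Cap on the solver step (s).  The step controller would otherwise take
#: very large steps in the flat post-window phase, where dense-output
#: interpolation error can exceed the endpoint error and put visible
#: wiggles on the nearly-constant dimer curve.
DEFAULT_MAX_STEP = 120.0


class IntegrationError(RuntimeError):
    """Raised when a segment fails to converge or produces negative mass."""


@dataclass
class Trajectory:
    """Solution of one model on a time grid, with conservation ledgers.

    Concentrations are molar, times are seconds.  ``cum_*`` arrays are the
    co-integrated inflow/outflow totals; they are ``None`` for trajectories
    reconstructed from CSV, which only stores the concentrations.
    """

    model: ModelKind
    params: KineticParameters
    times: np.ndarray
    N: np.ndarray
    V: np.ndarray
    D: np.ndarray
    cum_production: np.ndarray | None = None
    cum_deg_N: np.ndarray | None = None
    cum_deg_V: np.ndarray | None = None
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be a 1-D grid with >= 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("N", "V", "D"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must align with times")
            setattr(self, name, arr)

    def species(self, name: str) -> np.ndarray:
        """Concentration array for species ``'N'``, ``'V'`` or ``'D'``."""
        if name not in ("N", "V", "D"):
            raise KeyError(f"unknown species {name!r}")
        return getattr(self, name)

    @property
    def times_hpf(self) -> np.ndarray:
        return self.times / S_PER_HPF

    @property
    def N_nM(self) -> np.ndarray:
        return self.N / M_PER_NM

    @property
    def V_nM(self) -> np.ndarray:
        return self.V / M_PER_NM

    @property
    def D_nM(self) -> np.ndarray:
        return self.D / M_PER_NM


@dataclass
class MassLedger:
    """Per-time conservation residuals (M); ``r_vg1`` is primed-only."""

    times: np.ndarray
    r_nodal: np.ndarray
    r_vg1: np.ndarray | None = None

    def max_abs(self) -> float:
        worst = float(np.max(np.abs(self.r_nodal)))
        if self.r_vg1 is not None:
            worst = max(worst, float(np.max(np.abs(self.r_vg1))))
        return worst


def default_grid(params: KineticParameters, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform grid 0..t_end with spacing ``dt`` (s), endpoint included."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    grid = np.arange(0.0, params.t_end, dt)
    return np.append(grid, params.t_end)


def _segment_rhs(model: ModelKind, params: KineticParameters, prod: float):
    """RHS of the augmented system for one time-homogeneous segment.

    State layout: [N, V, D, cum_production, cum_deg_N, cum_deg_V].
    """
    beta_N, beta_V, lam_D = params.beta_N, params.beta_V, params.lambda_D
    primed = model is ModelKind.PRIMED_HETERODIMER

    def rhs(t, y):
        N, V = y[0], y[1]
        flux = lam_D * N * V if primed else lam_D * N * N
        deg_N = beta_N * N
        deg_V = beta_V * V if primed else 0.0
        dV = -deg_V - flux if primed else 0.0
        return (prod - deg_N - flux, dV, flux, prod, deg_N, deg_V)

    return rhs


def integrate(
    model: ModelKind,
    params: KineticParameters,
    grid: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = DEFAULT_MAX_STEP,
) -> Trajectory:
    """Integrate one model over ``grid`` (s), piecewise across the window.

    Initial conditions are (N, V, D) = (0, V0, 0) for the primed model —
    the system starts with the maternal Vg1 excess — and (N, D) = (0, 0)
    for cold-start.

    Raises
    ------
    IntegrationError
        If any segment fails to converge or a concentration goes negative
        beyond round-off tolerance.
    ValueError
        If the grid leaves [0, t_end] or tolerances are not positive.
    """
    model = ModelKind(model)
    if grid is None:
        grid = default_grid(params)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] != 0.0 or grid[-1] > params.t_end:
        raise ValueError("grid must start at 0 and lie within [0, t_end]")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")

    primed = model is ModelKind.PRIMED_HETERODIMER
    y = np.zeros(6)
    if primed:
        y[1] = params.V0

    out = np.empty((6, grid.size))
    boundaries = [grid[0]]
    for b in (params.t_on, params.t_off, min(params.t_end, grid[-1])):
        if grid[0] < b <= grid[-1] and b > boundaries[-1]:
            boundaries.append(b)
    if boundaries[-1] < grid[-1]:
        boundaries.append(grid[-1])

    out[:, 0] = y
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        prod = params.lambda_N_on if params.t_on <= t0 and t1 <= params.t_off else 0.0
        mask = (grid > t0) & (grid <= t1)
        t_eval = grid[mask]
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(
            _segment_rhs(model, params, prod),
            (t0, t1),
            y,
            method="DOP853",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{t0}, {t1}] s: {sol.message}"
            )
        if sol.y[:3].min() < -NEGATIVE_TOL:
            raise IntegrationError(
                f"negative concentration beyond tolerance on segment [{t0}, {t1}] s"
            )
        n_grid = int(mask.sum())
        out[:, mask] = sol.y[:, :n_grid]
        y = sol.y[:, -1]

    return Trajectory(
        model=model,
        params=params,
        times=grid,
        N=out[0],
        V=out[1],
        D=out[2],
        cum_production=out[3],
        cum_deg_N=out[4],
        cum_deg_V=out[5] if primed else np.zeros_like(out[5]),
        rtol=rtol,
        atol=atol,
    )


def mass_ledger(traj: Trajectory) -> MassLedger:
    """Conservation residuals of a trajectory (should be ~solver tolerance).

    Nodal ledger (both models): every molar of produced N is either still
    monomeric, bound in a dimer, or degraded.  Vg1 ledger (primed): the
    initial pool is partitioned among free V, dimer, and degraded V.
    """
    if traj.cum_production is None or traj.cum_deg_N is None:
        raise ValueError("trajectory carries no ledger fields (CSV round-trip?)")
    r_nodal = traj.cum_production - (traj.N + traj.D + traj.cum_deg_N)
    if traj.model is ModelKind.PRIMED_HETERODIMER:
        if traj.cum_deg_V is None:
            raise ValueError("primed trajectory missing cum_deg_V ledger")
        r_vg1 = traj.params.V0 - (traj.V + traj.D + traj.cum_deg_V)
        return MassLedger(times=traj.times, r_nodal=r_nodal, r_vg1=r_vg1)
    return MassLedger(times=traj.times, r_nodal=r_nodal)
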