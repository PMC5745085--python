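"""Closed-form solutions in degenerate limits, used as integrator oracles.

None of the full nonlinear systems admits an elementary solution, but three
limits do, and they pin down the integrator independently:

* with dimerization switched off (``lambda_D = 0``) the Nodal monomer obeys a
  linear birth-death equation with a piecewise-constant source;
* in the same limit Vg1 is pure exponential decay from the maternal pool;
* the cold-start monomer has a quasi-steady state where windowed synthesis
  balances degradation plus the homodimerization sink.
"""

from __future__ import annotations

import numpy as np

from .model import KineticParameters

__all__ = [
    "monomer_closed_form",
    "vg1_decay_closed_form",
    "cold_start_qss_monomer",
]


def monomer_closed_form(t, params: KineticParameters):
    """Nodal monomer N(t) in M for the lambda_D = 0 limit.

    Zero before the production window; saturating rise toward the
    steady state lambda_N/beta_N inside it; exponential decay after.
    Accepts a scalar or array of times (s).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    lam, beta = params.lambda_N_on, params.beta_N
    n_plateau = lam / beta if beta > 0 else np.inf
    rise = n_plateau * -np.expm1(-beta * np.clip(t - params.t_on, 0.0, None))
    n_off = n_plateau * -np.expm1(-beta * (params.t_off - params.t_on))
    decay = n_off * np.exp(-beta * np.clip(t - params.t_off, 0.0, None))
    out = np.where(t <= params.t_on, 0.0, np.where(t <= params.t_off, rise, decay))
    return out if out.ndim else float(out)


def vg1_decay_closed_form(t, params: KineticParameters):
    """Vg1 monomer V(t) = V0 * exp(-beta_V * t) in M (lambda_D*N*V = 0 limit)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = params.V0 * np.exp(-params.beta_V * t)
    return out if out.ndim else float(out)


def cold_start_qss_monomer(params: KineticParameters) -> float:
    """Quasi-steady-state monomer N* (M) of the cold-start model.

    Positive root of ``lambda_D*N**2 + beta_N*N - lambda_N_on = 0``, the
    level at which in-window synthesis balances degradation plus the
    homodimer sink.  Returns 0 when synthesis is off.
    """
    if params.lambda_D <= 0:
        raise ValueError("requires lambda_D > 0")
    lam, beta, lam_d = params.lambda_N_on, params.beta_N, params.lambda_D
    if lam == 0:
        return 0.0
    # Numerically stable quadratic root: avoids cancellation when beta
    # dominates (the lambda_D -> 0 limit must degenerate to lam/beta).
    disc = np.sqrt(beta * beta + 4.0 * lam_d * lam)
    return 2.0 * lam / (beta + disc)
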