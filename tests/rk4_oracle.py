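"""Independent fixed-step RK4 re-implementation of both models.

Deliberately minimal and written without reference to the package's
integrator: classical Runge-Kutta with a fixed step, integrated piecewise
across the production-window boundaries.  Used only as a cross-check oracle
in tests.
"""

import numpy as np


def rk4_dimer_curves(params, dt_out=300.0, h=1.0):
    """Return (times, D_primed, D_cold) arrays via fixed-step RK4."""

    def step(f, t, y, h):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    def run(rhs, y0):
        times = [0.0]
        out = [y0.copy()]
        y = y0.copy()
        bounds = [0.0, params.t_on, params.t_off, params.t_end]
        for t0, t1 in zip(bounds[:-1], bounds[1:]):
            lam = params.lambda_N_on if t0 >= params.t_on and t1 <= params.t_off else 0.0

            def f(t, y, lam=lam):
                return rhs(lam, y)

            n = int(round((t1 - t0) / h))
            t = t0
            for i in range(n):
                y = step(f, t, y, h)
                t = t0 + (i + 1) * h
                times.append(t)
                out.append(y.copy())
        return np.array(times), np.array(out)

    def rhs_primed(lam, y):
        N, V, D = y
        flux = params.lambda_D * N * V
        return np.array(
            [lam - params.beta_N * N - flux, -params.beta_V * V - flux, flux]
        )

    def rhs_cold(lam, y):
        N, D = y
        flux = params.lambda_D * N * N
        return np.array([lam - params.beta_N * N - flux, flux])

    t_p, y_p = run(rhs_primed, np.array([0.0, params.V0, 0.0]))
    t_c, y_c = run(rhs_cold, np.array([0.0, 0.0]))
    times = np.append(np.arange(0.0, params.t_end, dt_out), params.t_end)
    return (
        times,
        np.interp(times, t_p, y_p[:, 2]),
        np.interp(times, t_c, y_c[:, 1]),
    )
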