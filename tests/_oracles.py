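"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form code paths: kinetics are
checked against stiff ODE integration of the compartmental mass-balance
equations, and the marginal likelihood against adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration(ind, doses, ts):
    """Central concentration by ODE integration (non-steady-state doses).

    States: central amount, peripheral amount, depot amount.  Infusions are
    zero-order inputs; enteral doses are boluses into the depot scaled by F.
    """
    k10, k12, k21 = ind.cl / ind.vc, ind.q / ind.vc, ind.q / ind.vp
    ka = ind.ka

    def rhs(t, yv):
        a1, a2, ad = yv
        r = sum(d.amount / d.duration for d in doses
                if d.route == "iv_infusion" and d.time <= t < d.time + d.duration)
        return [r + ka * ad - (k10 + k12) * a1 + k21 * a2,
                k12 * a1 - k21 * a2,
                -ka * ad]

    ts = np.asarray(ts, dtype=float)
    tend = float(ts.max())
    bounds = sorted({0.0, tend}
                    | {d.time for d in doses if d.time < tend}
                    | {d.time + d.duration for d in doses
                       if d.route == "iv_infusion" and d.time + d.duration < tend})
    y = np.zeros(3)
    out = np.zeros_like(ts)
    if (ts == 0).any():
        out[ts == 0] = 0.0
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        for d in doses:
            if d.route != "iv_infusion" and abs(d.time - t0) < 1e-12:
                y[2] += ind.f * d.amount
        sol = solve_ivp(rhs, (t0, t1), y, dense_output=True,
                        rtol=1e-11, atol=1e-13, method="LSODA")
        m = (ts > t0) & (ts <= t1)
        if m.any():
            out[m] = sol.sol(ts[m])[0] / ind.vc
        y = sol.y[:, -1]
    return out


def quadrature_ofv(y, times, doses, make_individual, omega_cl, add_sd):
    """-2 log marginal likelihood by adaptive quadrature over a single
    clearance eta (additive-only residual error)."""
    from scipy.integrate import quad

    from voripk.kinetics import concentration

    y = np.asarray(y, dtype=float)
    v = add_sd ** 2
    n = len(y)

    def integrand(eta):
        c = np.array([concentration(make_individual(eta), doses, t)
                      for t in times])
        return float(np.exp(-np.sum((y - c) ** 2) / (2 * v)
                            - eta * eta / (2 * omega_cl ** 2)))

    val, _ = quad(integrand, -8 * omega_cl, 8 * omega_cl,
                  epsabs=1e-300, epsrel=1e-13, limit=500)
    norm = (2 * np.pi * v) ** (n / 2) * np.sqrt(2 * np.pi * omega_cl ** 2)
    return float(-2 * np.log(val / norm))
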