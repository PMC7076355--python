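"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form/grid machinery: the
two-compartment system is integrated directly as ODEs so that the production
code can be checked against an implementation that shares nothing with it
beyond the model definition.
"""

import numpy as np


def ode_concentration(pk, regimen, times):
    """Plasma concentration by direct stiff integration of the mass ODEs."""
    from scipy.integrate import solve_ivp

    ke, k12, k21 = (x * 24.0 for x in (pk.ke, pk.k12, pk.k21))
    times = np.asarray(times, dtype=float)
    events = sorted(regimen.events, key=lambda e: e.time)
    y = np.zeros(2)  # drug amounts per kg in central, peripheral
    out = np.zeros_like(times)
    bounds = [0.0] + [e.time for e in events] + [float(times[-1])]
    bounds = sorted(set(b for b in bounds if b <= times[-1]))
    for e in events:
        if e.time == 0.0:
            y[0] += e.amount

    def rhs(_t, yy):
        a, b = yy
        return [-(ke + k12) * a + k21 * b, k12 * a - k21 * b]

    if times[0] == 0.0:
        out[0] = y[0] / pk.V
    for t0, t1 in zip(bounds, bounds[1:]):
        sel = times[(times > t0) & (times <= t1)]
        t_eval = np.unique(np.concatenate((sel, [t1])))
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=1e-10,
                        atol=1e-12, method="LSODA")
        for tt, col in zip(sol.t, sol.y.T):
            if np.any(np.isclose(tt, sel)):
                out[np.isclose(times, tt)] = col[0] / pk.V
        y = sol.y[:, -1]
        for e in events:
            if np.isclose(e.time, t1):
                y[0] += e.amount
    return out
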