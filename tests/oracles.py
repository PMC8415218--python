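"""Independent numerical oracles used by the tests.

The closed-form concentration code is checked against adaptive-step
integration of the two-state system (gut amount, central amount) with dose
boluses added to the gut compartment; nothing here shares code with the
package's closed-form path.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def ode_profile(params, events, times, c_ini: float = 0.0) -> np.ndarray:
    """Concentrations (nmol/L) at `times` by stiff-safe ODE integration."""
    times = np.asarray(times, dtype=float)
    boluses = sorted(
        ((ev.time_h, ev.amount_mg / 558.64e-6 * params.f) for ev in events if ev.amount_mg > 0),
    )
    t_start = min([b[0] for b in boluses] + [0.0, float(times.min(initial=0.0))])
    t_end = float(times.max(initial=0.0))

    def rhs(_t, y):
        gut, central = y
        return [-params.ka * gut, params.ka * gut - params.ke * central]

    y = np.array([0.0, c_ini * params.v])
    out = np.full(times.shape, np.nan)
    bounds = [b[0] for b in boluses] + [t_end + 1e-9]
    t_cur = t_start
    bolus_idx = 0
    # integrate segment by segment, applying boluses at their event times
    while t_cur <= t_end:
        while bolus_idx < len(boluses) and abs(boluses[bolus_idx][0] - t_cur) < 1e-12:
            y[0] += boluses[bolus_idx][1]
            bolus_idx += 1
        t_next = bounds[bolus_idx] if bolus_idx < len(boluses) else t_end
        if t_next <= t_cur:
            t_next = t_end
        mask = (times >= t_cur) & (times <= t_next)
        t_eval = np.unique(times[mask])
        sol = solve_ivp(
            rhs, (t_cur, max(t_next, t_cur + 1e-12)), y,
            t_eval=t_eval if t_eval.size else None,
            rtol=1e-11, atol=1e-14, method="DOP853", dense_output=True,
        )
        for t in np.atleast_1d(t_eval):
            out[np.isclose(times, t)] = sol.sol(t)[1] / params.v
        y = sol.sol(max(t_next, t_cur + 1e-12))  # state at the segment end
        if t_next >= t_end:
            break
        t_cur = t_next
    out[times < t_start] = 0.0
    return out


def bruteforce_two_point_weights(L: np.ndarray, step: float = 1e-4):
    """Grid search of the 2-point mixture weight maximizing the objective."""
    assert L.shape[1] == 2
    w1 = np.arange(0.0, 1.0 + step / 2, step)
    rowmax = L.max(axis=1, keepdims=True)
    a = np.exp(L - rowmax)
    mix = np.outer(a[:, 0], w1) + np.outer(a[:, 1], 1.0 - w1)
    obj = np.log(mix).sum(axis=0) + rowmax.sum()
    i = int(np.argmax(obj))
    return np.array([w1[i], 1.0 - w1[i]]), float(obj[i])
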