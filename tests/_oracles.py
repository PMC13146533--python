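"""Independent numeric oracles, kept separate from the implementation.

The forward model is solved in closed form by the package; here the same
initial-value problem is integrated numerically with a generic ODE
solver, segment by constant-power segment, so agreement is a genuine
cross-check rather than a tautology.
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_simulate(system, protocol, sample_times, initial_temp=None):
    """Integrate dT/dt = (Q(t) - hA (T - Tsurr)) / C with solve_ivp."""
    sample_times = np.asarray(sample_times, dtype=float)
    T = system.ambient_temp if initial_temp is None else float(initial_temp)
    knots = sorted(
        {float(sample_times[0]), float(sample_times[-1])}
        | {s.start_s for s in protocol.segments
           if sample_times[0] < s.start_s < sample_times[-1]}
        | {s.end_s for s in protocol.segments
           if sample_times[0] < s.end_s < sample_times[-1]}
    )
    out = np.empty_like(sample_times)
    for a, b in zip(knots, knots[1:]):
        power = protocol.power_at(0.5 * (a + b))
        if power > 0:
            q = power * (1 - 10 ** (-system.absorbance)) * system.eta + system.solvent_heat
        else:
            q = 0.0

        def rhs(_t, y, q=q):
            return [(q - system.hA * (y[0] - system.ambient_temp))
                    / system.heat_capacity_total]

        inside = (sample_times >= a) & (sample_times <= b)
        t_eval = np.unique(np.concatenate([sample_times[inside], [a, b]]))
        sol = solve_ivp(rhs, (a, b), [T], t_eval=t_eval, rtol=1e-11, atol=1e-12,
                        method="LSODA")
        for t, y in zip(sol.t, sol.y[0]):
            hit = np.isclose(sample_times, t) & inside
            out[hit] = y
        T = float(sol.y[0][-1])
    return out
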