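"""Exact stochastic simulation (Gillespie) of the solution switch scheme.

Independent of the package's ODE path: used as a cross-check oracle that
the deterministic equations transcribe the reaction scheme correctly.
"""

import numpy as np


def gillespie_solution(params, init, t_grid, omega, rng):
    """Simulate A + B <-> AB, B -> B', B' -> B at copy-number scale.

    ``omega`` converts concentration (uM) to copy number.  Returns an array
    (4, len(t_grid)) of concentrations (A, B, AB, Bp) sampled on the grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    nA = int(round(init.A * omega))
    nB = int(round(init.B * omega))
    nAB = int(round(init.AB * omega))
    nBp = int(round(init.Bp * omega))
    c_bind = params.kon / omega
    c_unbind = params.koff
    c_phos = params.kp * params.kinase_scale
    c_dephos = params.kdp * params.phosphatase_scale

    out = np.empty((4, t_grid.size))
    t = t_grid[0]
    i = 0
    while True:
        a = np.array([
            c_bind * nA * nB,
            c_unbind * nAB,
            c_phos * nB,
            c_dephos * nBp,
        ])
        a_tot = a.sum()
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf
        while i < t_grid.size and t_grid[i] < t_next:
            out[:, i] = (nA, nB, nAB, nBp)
            i += 1
        if i >= t_grid.size:
            break
        t = t_next
        r = rng.random() * a_tot
        if r < a[0]:
            nA -= 1; nB -= 1; nAB += 1
        elif r < a[0] + a[1]:
            nA += 1; nB += 1; nAB -= 1
        elif r < a[0] + a[1] + a[2]:
            nB -= 1; nBp += 1
        else:
            nB += 1; nBp -= 1
    return out / omega
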