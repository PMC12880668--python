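"""Brute-force fixed-step RK4 oracles for the forcing chains.

Pure-python state propagation at a fine step (default 0.01 min), recording
values on a 1-min grid.  Deliberately independent of the package's
closed-form machinery.
"""

from __future__ import annotations

import numpy as np


def rk4_chain(derivs, y0, t_end=1440.0, dt=0.01, record_every=1.0, impulses=()):
    """Integrate y' = derivs(t, y) with impulses [(t, index, amount)].

    Returns dict time -> state list, for times on the record grid.
    """
    n = len(y0)
    y = [float(v) for v in y0]
    imps = sorted(impulses)
    rec = {0.0: list(y)}
    steps = int(round(t_end / dt))
    rec_stride = int(round(record_every / dt))
    t = 0.0
    ptr = 0
    while ptr < len(imps) and abs(imps[ptr][0]) < dt / 2:
        y[imps[ptr][1]] += imps[ptr][2]
        ptr += 1
    rec[0.0] = list(y)
    for k in range(steps):
        k1 = derivs(t, y)
        y2 = [y[i] + 0.5 * dt * k1[i] for i in range(n)]
        k2 = derivs(t + 0.5 * dt, y2)
        y3 = [y[i] + 0.5 * dt * k2[i] for i in range(n)]
        k3 = derivs(t + 0.5 * dt, y3)
        y4 = [y[i] + dt * k3[i] for i in range(n)]
        k4 = derivs(t + dt, y4)
        y = [y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(n)]
        t = (k + 1) * dt
        while ptr < len(imps) and abs(imps[ptr][0] - t) < dt / 2:
            y[imps[ptr][1]] += imps[ptr][2]
            ptr += 1
        if (k + 1) % rec_stride == 0:
            rec[round(t, 6)] = list(y)
    return rec


def rel_err(got: np.ndarray, want: np.ndarray) -> float:
    """Max abs difference normalised by the oracle's peak magnitude."""
    scale = np.abs(want).max()
    return float(np.abs(got - want).max() / scale) if scale > 0 else float(np.abs(got).max())
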