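"""Compiled inner loops (numba) with pure-numpy fallbacks.

The time-stepping recursions (RK4 of the glucose pair, first-order-hold and
zero-order-hold filters) are short vector operations repeated hundreds of
times per window; at the batch sizes the fitter uses they are dominated by
interpreter overhead, so they are JIT-compiled when numba is available.
The numpy fallbacks compute identical results.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _rk4_glucose_nb(Xh, Eh, RAh, G0, SG0, EGP, GEZI, SE, H, Gth, tauG, dt, floor,
                    outG, outSG):  # pragma: no cover - compiled
    B = Xh.shape[0]
    T = outG.shape[1] - 1
    bad_step = -1
    for b in range(B):
        G = G0[b]
        SG = SG0[b]
        outG[b, 0] = G
        outSG[b, 0] = SG
        for k in range(T):
            gk = G
            sk = SG
            accG = 0.0
            accS = 0.0
            for stage in range(4):
                if stage == 0:
                    i = 2 * k
                    wt = 1.0
                elif stage == 3:
                    i = 2 * k + 2
                    wt = 1.0
                else:
                    i = 2 * k + 1
                    wt = 2.0
                h = H[b] if gk < Gth[b] else 0.0
                fr = 0.003 * (gk - 162.0) if gk > 162.0 else 0.0
                dG = -(GEZI[b] + (1.0 + h) * Xh[b, i]) * gk + EGP[b] - SE[b] * Eh[b, i] + RAh[b, i] - fr
                dS = (gk - sk) / tauG[b]
                accG += wt * dG
                accS += wt * dS
                if stage == 0 or stage == 1:
                    gk = G + 0.5 * dt * dG
                    sk = SG + 0.5 * dt * dS
                elif stage == 2:
                    gk = G + dt * dG
                    sk = SG + dt * dS
            G = G + dt / 6.0 * accG
            SG = SG + dt / 6.0 * accS
            if floor > 0.0:
                if not (G > floor):
                    G = floor
                if not (SG > floor):
                    SG = floor
            elif not (G > 0.0) or not (SG > 0.0):
                bad_step = k + 1
                return bad_step
            outG[b, k + 1] = G
            outSG[b, k + 1] = SG
    return bad_step


@njit(cache=True)
def _foh_nb(u, a, b0, b1, y0, out):  # pragma: no cover - compiled
    B, T = u.shape
    for b in range(B):
        y = y0[b]
        out[b, 0] = y
        for k in range(T - 1):
            y = a[b] * y + b0[b] * u[b, k] + b1[b] * u[b, k + 1]
            out[b, k + 1] = y


@njit(cache=True)
def _zoh2_nb(u, a, r, e1_0, e_0, out):  # pragma: no cover - compiled
    B, T = u.shape
    for b in range(B):
        e1 = e1_0[b]
        e = e_0[b]
        out[b, 0] = e
        for k in range(T - 1):
            uk = u[b, k]
            d1 = e1 - uk
            e = uk + (e - uk) * a[b] + d1 * r[b]
            e1 = uk + d1 * a[b]
            out[b, k + 1] = e


def rk4_glucose(Xh, Eh, RAh, G0, SG0, EGP, GEZI, SE, H, Gth, tauG, dt, floor):
    """Batched RK4 of the glucose pair; returns (G, SG, bad_step)."""
    B = Xh.shape[0]
    T = (Xh.shape[1] - 1) // 2
    outG = np.empty((B, T + 1))
    outSG = np.empty((B, T + 1))
    if HAVE_NUMBA:
        args = [np.ascontiguousarray(x) for x in (Xh, Eh, RAh)]
        scal = [np.ascontiguousarray(np.broadcast_to(np.asarray(v, dtype=float), (B,)))
                for v in (G0, SG0, EGP, GEZI, SE, H, Gth, tauG)]
        bad = _rk4_glucose_nb(*args, *scal, float(dt), float(floor), outG, outSG)
        return outG, outSG, int(bad)
    return None  # caller falls back to the numpy path


def foh_filter(u, a, b0, b1, y0):
    B, T = u.shape
    out = np.empty((B, T))
    if HAVE_NUMBA:
        _foh_nb(np.ascontiguousarray(u), *(np.ascontiguousarray(np.broadcast_to(v, (B,)))
                                           for v in (a, b0, b1, y0)), out)
        return out
    out[:, 0] = y0
    for k in range(T - 1):
        out[:, k + 1] = a * out[:, k] + b0 * u[:, k] + b1 * u[:, k + 1]
    return out


def zoh_two_stage(u, a, r, e1_0, e_0):
    B, T = u.shape
    out = np.empty((B, T))
    if HAVE_NUMBA:
        _zoh2_nb(np.ascontiguousarray(u), *(np.ascontiguousarray(np.broadcast_to(v, (B,)))
                                            for v in (a, r, e1_0, e_0)), out)
        return out
    e1 = np.broadcast_to(e1_0, (B,)).copy()
    e = np.broadcast_to(e_0, (B,)).copy()
    out[:, 0] = e
    for k in range(T - 1):
        uk = u[:, k]
        d1 = e1 - uk
        e = uk + (e - uk) * a + d1 * r
        e1 = uk + d1 * a
        out[:, k + 1] = e
    return out
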