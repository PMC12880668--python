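"""Closed-form responses of first-order compartment cascades.

Every compartment chain in the model (meal absorption, subcutaneous insulin,
physical activity, heart-rate driven metabolic rate) is a cascade of
first-order stages with unit DC gain, ``tau * ydot = u - y``.  The Laplace
transfer function of an ``n``-stage cascade is ``prod_i 1/(1 + tau_i s)``,
i.e. ``gain / prod_i (s + a_i)`` with rates ``a_i = 1/tau_i`` and
``gain = prod_i a_i``.  This module evaluates the exact impulse and step
responses of such cascades on a time grid, including the repeated-pole
(confluent) cases such as the meal chain's double ``tau_D2`` stage, without
numerical blow-up when two rates approach each other.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["chain_response", "cascade_impulse", "cascade_step", "foh_lowpass"]

# Relative pole separation below which a pair is treated as confluent.  The
# pairwise-distinct partial-fraction formula stays accurate (error ~ eps/sep)
# well below this, and the clustered formula's O(sep * t) error is negligible
# above machine-level separations, so the two branches overlap safely.
_CLUSTER_RTOL = 1e-7


def _distinct_response(alphas: np.ndarray, t: np.ndarray, gain: np.ndarray) -> np.ndarray:
    """Partial-fraction response for pairwise-distinct rates.

    alphas: (B, n) decay rates, t: (T,) times, gain: (B,).
    Returns (B, T) = gain * sum_i exp(-a_i t) / prod_{j!=i} (a_j - a_i).
    """
    diff = alphas[:, None, :] - alphas[:, :, None]  # (B, i, j): a_j - a_i
    np.einsum("bii->bi", diff)[...] = 1.0
    denom = diff.prod(axis=2)  # (B, n): prod_{j != i}(a_j - a_i)
    coef = gain[:, None] / denom
    out = np.einsum("bi,bit->bt", coef, np.exp(-alphas[:, :, None] * t[None, None, :]))
    return out


def _clustered_coeffs(alphas: np.ndarray, gain: float) -> list[tuple[float, np.ndarray]]:
    """Partial-fraction coefficients with pole multiplicities for one row.

    Returns [(beta_j, c_j)] where c_j[k-1] multiplies t^(k-1) e^(-beta_j t)/(k-1)!.
    """
    order = np.argsort(alphas)
    a = alphas[order]
    scale = max(abs(a).max(), 1e-300)
    clusters: list[list[float]] = [[a[0]]]
    for v in a[1:]:
        if abs(v - clusters[-1][0]) <= _CLUSTER_RTOL * scale:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    betas = [float(np.mean(c)) for c in clusters]
    mults = [len(c) for c in clusters]
    result = []
    for j, (bj, mj) in enumerate(zip(betas, mults)):
        # F_j(s) = gain * prod_{l != j} (s + b_l)^(-m_l); need F_j^{(r)}(-b_j).
        others = [(bl, ml) for l, (bl, ml) in enumerate(zip(betas, mults)) if l != j]
        F = [gain * math.prod((bl - bj) ** (-ml) for bl, ml in others)]
        # g^{(p)}(-b_j) = -sum_l m_l (-1)^p p! (b_l - b_j)^(-(p+1))
        gders = []
        for p in range(mj - 1):
            gders.append(
                -sum(ml * (-1) ** p * math.factorial(p) * (bl - bj) ** (-(p + 1)) for bl, ml in others)
            )
        for r in range(1, mj):
            F.append(sum(math.comb(r - 1, q) * F[q] * gders[r - 1 - q] for q in range(r)))
        # c_{j,k} = F^{(m_j - k)}(-b_j) / (m_j - k)!, inverse transform of
        # 1/(s+b)^k is t^{k-1} e^{-bt}/(k-1)!
        c = np.array([F[mj - k] / math.factorial(mj - k) for k in range(1, mj + 1)])
        result.append((bj, c))
    return result


def _clustered_response(alphas: np.ndarray, t: np.ndarray, gain: float) -> np.ndarray:
    out = np.zeros_like(t)
    for beta, c in _clustered_coeffs(alphas, gain):
        decay = np.exp(-beta * t)
        poly = np.zeros_like(t)
        tpow = np.ones_like(t)
        for k in range(1, len(c) + 1):
            poly += c[k - 1] * tpow / math.factorial(k - 1)
            tpow = tpow * t
        out += poly * decay
    return out


def chain_response(alphas: np.ndarray, t: np.ndarray, gain: np.ndarray | None = None) -> np.ndarray:
    """Inverse Laplace transform of ``gain / prod_i (s + alpha_i)`` at times t.

    ``alphas`` has shape (..., n); a zero entry integrates the chain (used for
    step responses).  Times t < 0 return 0.  Output shape is (..., T).
    """
    alphas = np.asarray(alphas, dtype=float)
    t = np.asarray(t, dtype=float)
    batch_shape = alphas.shape[:-1]
    n = alphas.shape[-1]
    A = alphas.reshape(-1, n)
    B = A.shape[0]
    if gain is None:
        g = np.ones(B)
    else:
        g = np.broadcast_to(np.asarray(gain, dtype=float), batch_shape).reshape(-1).copy()
    tpos = np.where(t > 0, t, 0.0)
    scale = np.maximum(np.abs(A).max(axis=1), 1e-300)
    mindiff = np.full(B, np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            mindiff = np.minimum(mindiff, np.abs(A[:, i] - A[:, j]))
    degenerate = mindiff <= _CLUSTER_RTOL * scale
    out = np.empty((B, t.size))
    ok = ~degenerate
    if ok.any():
        out[ok] = _distinct_response(A[ok], tpos, g[ok])
    for b in np.nonzero(degenerate)[0]:
        out[b] = _clustered_response(A[b], tpos, float(g[b]))
    out[:, t <= 0] = 0.0
    return out.reshape(batch_shape + (t.size,))


def cascade_impulse(taus: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Impulse response of a unit-DC-gain first-order cascade.

    ``taus``: (..., n) stage time constants (min). Total mass (DC gain) is 1.
    """
    taus = np.asarray(taus, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("cascade time constants must be positive")
    alphas = 1.0 / taus
    gain = alphas.prod(axis=-1)
    return chain_response(alphas, t, gain)


def cascade_step(taus: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit-step response of a unit-DC-gain cascade (tends to 1)."""
    taus = np.asarray(taus, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("cascade time constants must be positive")
    alphas = 1.0 / taus
    gain = alphas.prod(axis=-1)
    zero = np.zeros(alphas.shape[:-1] + (1,))
    return chain_response(np.concatenate([alphas, zero], axis=-1), t, gain)


def foh_lowpass(u: np.ndarray, dt: float, tau: np.ndarray, y0: np.ndarray | float = 0.0) -> np.ndarray:
    """Integrate ``tau ydot = u - y`` exactly for piecewise-linear input.

    ``u``: (..., T) input samples on a uniform grid of step ``dt``; ``tau``
    broadcasts over the batch dims.  First-order-hold discretisation: exact
    when u is linear between samples, third-order accurate otherwise.
    """
    u = np.asarray(u, dtype=float)
    tau = np.asarray(tau, dtype=float)
    a = np.exp(-dt / tau)
    c = tau / dt
    b0 = c * (1.0 - a) - a
    b1 = 1.0 - c * (1.0 - a)
    y = np.empty_like(u)
    y[..., 0] = y0
    for k in range(u.shape[-1] - 1):
        y[..., k + 1] = a * y[..., k] + b0 * u[..., k] + b1 * u[..., k + 1]
    return y
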