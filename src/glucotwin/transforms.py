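"""Bijections between constrained latents and the unconstrained guide space.

Each scalar latent gets a transform chosen from its support: a scaled logit
for two-sided intervals, a shifted log for half-lines, identity for the real
line.  All maps are vectorised over a (B, D) matrix given per-site bounds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SupportTransform"]

# Exp/logit argument guard.  50 keeps every transformed value finite with
# huge headroom over the physical scales (e^50 ~ 5e21) while preventing the
# overflow cascades a 700-style cap allows in downstream gradient algebra.
_CLIP_Z = 50.0
_EDGE = 1e-12        # relative margin kept from interval endpoints


class SupportTransform:
    """Vectorised site-wise bijection defined by per-site (lo, hi) bounds."""

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.kind = np.zeros(self.lo.shape, dtype=int)  # 0 identity, 1 log, 2 logit
        self.kind[np.isfinite(self.lo) & ~np.isfinite(self.hi)] = 1
        both = np.isfinite(self.lo) & np.isfinite(self.hi)
        self.kind[both] = 2
        if np.any(~np.isfinite(self.lo) & np.isfinite(self.hi)):
            raise ValueError("upper-bounded-only supports are not used by this model")
        self.width = np.where(both, self.hi - self.lo, 1.0)

    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = x.copy()
        m = self.kind == 1
        if m.any():
            z[..., m] = np.log(np.maximum(x[..., m] - self.lo[m], 1e-300))
        m = self.kind == 2
        if m.any():
            u = (x[..., m] - self.lo[m]) / self.width[m]
            u = np.clip(u, _EDGE, 1.0 - _EDGE)
            z[..., m] = np.log(u) - np.log1p(-u)
        return z

    def to_constrained(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = z.copy()
        m = self.kind == 1
        if m.any():
            x[..., m] = self.lo[m] + np.exp(np.minimum(z[..., m], _CLIP_Z))
        m = self.kind == 2
        if m.any():
            zm = np.clip(z[..., m], -_CLIP_Z, _CLIP_Z)
            x[..., m] = self.lo[m] + self.width[m] / (1.0 + np.exp(-zm))
        return x

    def log_abs_det_jacobian(self, z: np.ndarray) -> np.ndarray:
        """log |d constrained / d unconstrained|, summed over sites."""
        z = np.asarray(z, dtype=float)
        out = np.zeros(z.shape[:-1])
        m = self.kind == 1
        if m.any():
            out = out + np.minimum(z[..., m], _CLIP_Z).sum(axis=-1)
        m = self.kind == 2
        if m.any():
            zm = np.clip(z[..., m], -_CLIP_Z, _CLIP_Z)
            # log(width) + log sigmoid(z) + log sigmoid(-z)
            out = out + (np.log(self.width[m]) - np.logaddexp(0.0, -zm) - np.logaddexp(0.0, zm)).sum(axis=-1)
        return out
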