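"""Batched simulation engine for 24 h glucose-dynamics windows.

All forcing chains (meal absorption, subcutaneous insulin, physical activity,
metabolic rate) are evaluated through their closed-form responses; only the
nonlinear glucose/subcutaneous-glucose pair is integrated numerically (RK4 on
the window grid, with forcing evaluated on a half-step grid so the midpoint
stages of RK4 see exact forcing values).

Every parameter may be a scalar or a batch vector of shape (B,), so a single
call evaluates the same window under B different latent draws — this is what
makes the finite-difference ELBO gradients and the posterior-predictive
ensembles affordable.  Events are passed as dicts whose values are scalars or
(B,) arrays (see :func:`meal_dict` etc. for the expected keys).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .linresp import chain_response, foh_lowpass
from .params import BIOAVAILABILITY, RENAL_SLOPE, RENAL_THRESHOLD

__all__ = [
    "IntegrationError",
    "half_grid",
    "hr_to_grid",
    "ra_signal",
    "ip_signal",
    "pa_signal",
    "si_signal",
    "e_signal",
    "x_signal",
    "renal_excretion",
    "glucose_rhs_arrays",
    "integrate_glucose",
]


class IntegrationError(RuntimeError):
    """Raised when the glucose integration produces NaN or non-positive G."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


def half_grid(t_grid: np.ndarray) -> np.ndarray:
    """Uniform grid refined with midpoints: (2T+1,) for a (T+1,) grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    dt = t_grid[1] - t_grid[0]
    return t_grid[0] + 0.5 * dt * np.arange(2 * (t_grid.size - 1) + 1)


def _delayed(th: np.ndarray, onset) -> np.ndarray:
    """Time since onset, (B, Th); negative values map to 0 in the cascades."""
    onset = np.atleast_1d(np.asarray(onset, dtype=float))
    return th[None, :] - onset[:, None]


def _one_double_response(singles: np.ndarray, double: np.ndarray, gain: np.ndarray,
                         tpos: np.ndarray) -> np.ndarray:
    """Response with one double pole b and k simple poles s_i (vectorised).

    h(t) = sum_i A_i e^{-s_i t} + (C1 + C2 t) e^{-b t} with
    A_i = gain / (prod_{j!=i}(s_j - s_i) (b - s_i)^2),
    C2 = gain / prod_i (s_i - b), C1 = -C2 sum_i 1/(s_i - b).
    singles: (B, k) with k possibly 0; double, gain: (B,); tpos: (B, T).
    """
    B, k = singles.shape
    db = double[:, None]
    out = np.zeros_like(tpos)
    C2 = gain.copy()
    C1sum = np.zeros(B)
    for i in range(k):
        d = singles[:, i] - double
        C2 = C2 / d
        C1sum += 1.0 / d
        denom = np.ones(B)
        for j in range(k):
            if j != i:
                denom *= singles[:, j] - singles[:, i]
        denom *= (double - singles[:, i]) ** 2
        out += (gain / denom)[:, None] * np.exp(-singles[:, i][:, None] * tpos)
    C1 = -C2 * C1sum
    out += (C1[:, None] + C2[:, None] * tpos) * np.exp(-db * tpos)
    return out


def _resp_batch(taus_cols: list[np.ndarray], delay: np.ndarray) -> np.ndarray:
    """Vectorised cascade response with batch-dependent taus and delays.

    taus_cols: list of n arrays each (B,); delay: (B, Th).  Rows are routed
    by pole pattern: all-distinct (partial fractions), exactly one coincident
    pair (confluent closed form, e.g. the meal chain's double tauD2), and a
    generic per-row fallback for higher multiplicities.
    """
    taus = np.stack([np.broadcast_to(c, delay.shape[:1]) for c in taus_cols], axis=-1)
    alphas = 1.0 / taus
    gain = alphas.prod(axis=-1)
    B, n = alphas.shape
    dpos = np.where(delay > 0, delay, 0.0)
    out = np.zeros_like(delay)
    if n == 1:
        out = gain[:, None] * np.exp(-alphas * dpos)
        out[delay <= 0] = 0.0
        return out
    scale = np.maximum(np.abs(alphas).max(axis=1), 1e-300)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    close = np.stack([np.abs(alphas[:, i] - alphas[:, j]) <= 1e-7 * scale for i, j in pairs], axis=1)
    n_close = close.sum(axis=1)
    distinct = n_close == 0
    if distinct.any():
        a = alphas[distinct]
        diff = a[:, None, :] - a[:, :, None]
        np.einsum("bii->bi", diff)[...] = 1.0
        coef = gain[distinct, None] / diff.prod(axis=2)
        out[distinct] = np.einsum("bi,bit->bt", coef, np.exp(-a[:, :, None] * dpos[distinct, None, :]))
    if (n_close == 1).any():
        for pi, (i, j) in enumerate(pairs):
            rows = (n_close == 1) & close[:, pi]
            if not rows.any():
                continue
            rest = [k for k in range(n) if k not in (i, j)]
            singles = alphas[rows][:, rest] if rest else np.empty((int(rows.sum()), 0))
            double = 0.5 * (alphas[rows, i] + alphas[rows, j])
            out[rows] = _one_double_response(singles, double, gain[rows], dpos[rows])
    fallback = n_close > 1
    for b in np.nonzero(fallback)[0]:
        out[b] = chain_response(alphas[b], dpos[b], gain[b])
    out[delay <= 0] = 0.0
    return out


def ra_signal(th: np.ndarray, meals: list[dict], VG) -> np.ndarray:
    """Rate of glucose appearance (mg/dL/min) on grid th, summed over meals.

    Each meal dict: t_report, carbs (g), TD, tauD1, tauD2, MA (scalar or (B,)).
    The chain is three cascaded unit-DC stages (tauD1, tauD2, tauD2); the
    injected mass is BIOAVAILABILITY * MA * carbs * 1000 / VG, so the plasma
    glucose mass VG * integral(RA) equals 0.8 * MA * carbs.
    """
    VG = np.atleast_1d(np.asarray(VG, dtype=float))
    B = max(VG.size, max((np.size(m[k]) for m in meals for k in ("TD", "tauD1", "tauD2", "MA")), default=1))
    out = np.zeros((B, th.size))
    for m in meals:
        carbs = float(np.asarray(m["carbs"]))
        if carbs < 0:
            raise ValueError("carbs must be non-negative")
        if carbs == 0:
            continue
        onset = float(np.asarray(m["t_report"])) + np.broadcast_to(np.asarray(m["TD"], dtype=float), (B,))
        delay = _delayed(th, onset)
        tau1 = np.broadcast_to(np.asarray(m["tauD1"], dtype=float), (B,))
        tau2 = np.broadcast_to(np.asarray(m["tauD2"], dtype=float), (B,))
        if np.any(tau1 <= 0) or np.any(tau2 <= 0):
            raise ValueError("meal time constants must be positive")
        mass = BIOAVAILABILITY * np.broadcast_to(np.asarray(m["MA"], dtype=float), (B,)) * carbs * 1000.0 / np.broadcast_to(VG, (B,))
        out += mass[:, None] * _resp_batch([tau1, tau2, tau2], delay)
    return out


def ip_signal(
    th: np.ndarray,
    boluses: list[dict],
    basal_rate,
    tauI1_basal,
    tauI2,
    tauI3,
    S1_0=0.0,
    S2_0=0.0,
    Ip_0=0.0,
) -> np.ndarray:
    """Plasma-acting insulin rate Ip (U/min) on grid th.

    Boluses are impulses of mass IA*dose into the three-stage LTI part of the
    insulin chain (tauI1 per bolus, then tauI2, tauI3); basal is a constant
    infusion basal_rate into the first compartment from t=0; initial
    compartment contents relax through the remaining stages (an initial value
    s in a stage with constant tau is equivalent to an impulse of mass s*tau
    into that stage).
    """
    tauI2 = np.atleast_1d(np.asarray(tauI2, dtype=float))
    tauI3 = np.atleast_1d(np.asarray(tauI3, dtype=float))
    sizes = [tauI2.size, tauI3.size, np.size(basal_rate), np.size(tauI1_basal), np.size(S1_0), np.size(S2_0), np.size(Ip_0)]
    sizes += [np.size(b[k]) for b in boluses for k in ("TI", "tauI1", "IA")]
    B = max(sizes)
    t2 = np.broadcast_to(tauI2, (B,))
    t3 = np.broadcast_to(tauI3, (B,))
    out = np.zeros((B, th.size))
    for b in boluses:
        dose = float(np.asarray(b["dose"]))
        if dose < 0:
            raise ValueError("dose must be non-negative")
        if dose == 0:
            continue
        onset = float(np.asarray(b["t_report"])) + np.broadcast_to(np.asarray(b["TI"], dtype=float), (B,))
        tau1 = np.broadcast_to(np.asarray(b["tauI1"], dtype=float), (B,))
        mass = np.broadcast_to(np.asarray(b["IA"], dtype=float), (B,)) * dose
        out += mass[:, None] * _resp_batch([tau1, t2, t3], _delayed(th, onset))
    basal = np.broadcast_to(np.asarray(basal_rate, dtype=float), (B,))
    if np.any(basal > 0):
        tau1b = np.broadcast_to(np.asarray(tauI1_basal, dtype=float), (B,))
        # step response = integral of the impulse response: add a zero rate
        alphas = np.stack([1.0 / tau1b, 1.0 / t2, 1.0 / t3, np.zeros(B)], axis=-1)
        gain = 1.0 / (tau1b * t2 * t3)
        step = chain_response(alphas, th, gain)
        out += basal[:, None] * step
    # free responses of the initial compartment contents
    s1 = np.broadcast_to(np.asarray(S1_0, dtype=float), (B,))
    s2 = np.broadcast_to(np.asarray(S2_0, dtype=float), (B,))
    ip0 = np.broadcast_to(np.asarray(Ip_0, dtype=float), (B,))
    delay0 = np.broadcast_to(th[None, :], (B, th.size))
    if np.any(s1 != 0):
        tau1b = np.broadcast_to(np.asarray(tauI1_basal, dtype=float), (B,))
        out += (s1 * tau1b)[:, None] * _resp_batch([tau1b, t2, t3], delay0)
    if np.any(s2 != 0):
        out += (s2 * t2)[:, None] * _resp_batch([t2, t3], delay0)
    if np.any(ip0 != 0):
        # free decay of the last stage itself: Ip(t) = Ip0 exp(-t/tau3), t >= 0
        out += np.where(delay0 >= 0, ip0[:, None] * np.exp(-np.maximum(delay0, 0.0) / t3[:, None]), 0.0)
    return out


def pa_signal(th: np.ndarray, exercises: list[dict]) -> np.ndarray:
    """Physical-activity modulation of insulin sensitivity (dimensionless).

    PA(t) = sum over events of P_long*exp(-d/tauP_long) + P_short*exp(-d/tauP_short)
    for d = t - (t_report + TP) >= 0; overlapping events superpose.
    """
    sizes = [np.size(e[k]) for e in exercises for k in ("TP", "tauP_long", "tauP_short", "P_long", "P_short")]
    B = max(sizes, default=1)
    out = np.zeros((B, th.size))
    for e in exercises:
        onset = float(np.asarray(e["t_report"])) + np.broadcast_to(np.asarray(e["TP"], dtype=float), (B,))
        d = _delayed(th, onset)
        tl = np.broadcast_to(np.asarray(e["tauP_long"], dtype=float), (B,))[:, None]
        ts = np.broadcast_to(np.asarray(e["tauP_short"], dtype=float), (B,))[:, None]
        if np.any(~(tl > ts)) or np.any(ts <= 0):
            raise ValueError("require tauP_long > tauP_short > 0")
        pl = np.broadcast_to(np.asarray(e["P_long"], dtype=float), (B,))[:, None]
        ps = np.broadcast_to(np.asarray(e["P_short"], dtype=float), (B,))[:, None]
        active = d >= 0
        dpos = np.where(active, d, 0.0)
        out += np.where(active, pl * np.exp(-dpos / tl) + ps * np.exp(-dpos / ts), 0.0)
    return out


def si_signal(th: np.ndarray, SIE, SIA, SIphi, pa: np.ndarray, day_frac0=0.0) -> np.ndarray:
    """Insulin sensitivity SI(t) = SIE (1+PA) (1 + SIA sin(2 pi (t + SIphi))).

    t is in days measured from local midnight of the window's calendar day;
    th is in minutes from the window start and day_frac0 is the start's time
    of day as a fraction of a day.
    """
    SIE = np.atleast_1d(np.asarray(SIE, dtype=float))[:, None]
    SIA = np.atleast_1d(np.asarray(SIA, dtype=float))[:, None]
    SIphi = np.atleast_1d(np.asarray(SIphi, dtype=float))[:, None]
    day_frac0 = np.atleast_1d(np.asarray(day_frac0, dtype=float))[:, None]
    tday = day_frac0 + th[None, :] / 1440.0
    return SIE * (1.0 + pa) * (1.0 + SIA * np.sin(2.0 * np.pi * (tday + SIphi)))


def hr_to_grid(hr_t, hr_bpm, th: np.ndarray, hr_rest: float, max_age: float = 15.0) -> np.ndarray:
    """Heart rate held from the most recent reading; stale/missing -> hr_rest.

    A grid point uses the last reading at or before it if that reading is at
    most ``max_age`` minutes old, otherwise the resting value.
    """
    hr_t = np.asarray(hr_t, dtype=float)
    hr_bpm = np.asarray(hr_bpm, dtype=float)
    if hr_t.size == 0:
        return np.full(th.size, float(hr_rest))
    idx = np.searchsorted(hr_t, th, side="right") - 1
    valid = idx >= 0
    idxc = np.clip(idx, 0, hr_t.size - 1)
    age = th - hr_t[idxc]
    out = np.where(valid & (age <= max_age), hr_bpm[idxc], float(hr_rest))
    return out


def e_signal(hr_on_grid: np.ndarray, dt: float, tauE, hr_rest, E1_0=0.0, E_0=0.0) -> np.ndarray:
    """Metabolic rate E: excess heart rate through two equal-tau stages.

    hr_on_grid: (Th,) heart rate held piecewise-constant on the grid bins;
    exact zero-order-hold propagation of the repeated-pole pair, unit DC gain.
    """
    if np.any(np.asarray(hr_rest, dtype=float) <= 0):
        raise ValueError("hr_rest must be positive")
    tauE = np.atleast_1d(np.asarray(tauE, dtype=float))
    if np.any(tauE <= 0):
        raise ValueError("tauE must be positive")
    u_all = np.maximum(np.asarray(hr_on_grid, dtype=float) - np.asarray(hr_rest, dtype=float), 0.0)
    u_all = np.atleast_2d(u_all)
    B = max(tauE.size, u_all.shape[0])
    u_all = np.broadcast_to(u_all, (B, u_all.shape[1]))
    tau = np.broadcast_to(tauE, (B,))
    a = np.exp(-dt / tau)
    r = (dt / tau) * a
    return _kernels.zoh_two_stage(u_all, a, r, np.full(B, float(E1_0)), np.full(B, float(E_0)))


def x_signal(si: np.ndarray, ip: np.ndarray, dt: float, tauI4, X0=0.0) -> np.ndarray:
    """Insulin effect X: final chain stage driven by SI(t) * Ip(t).

    First-order-hold exponential integrator on the forcing grid; exact for
    piecewise-linear SI*Ip, third-order accurate for the smooth closed-form
    drive actually supplied.
    """
    tauI4 = np.atleast_1d(np.asarray(tauI4, dtype=float))
    if np.any(tauI4 <= 0):
        raise ValueError("tauI4 must be positive")
    u = np.atleast_2d(si * ip)
    B = u.shape[0]
    tau = np.broadcast_to(tauI4, (B,))
    a = np.exp(-dt / tau)
    c = tau / dt
    b0 = c * (1.0 - a) - a
    b1 = 1.0 - c * (1.0 - a)
    return _kernels.foh_filter(u, a, b0, b1, np.broadcast_to(np.asarray(X0, dtype=float), (B,)))


def renal_excretion(G):
    """Hovorka-type renal excretion: 0.003 (G - 162) above 162 mg/dL, else 0."""
    G = np.asarray(G, dtype=float)
    return RENAL_SLOPE * np.maximum(G - RENAL_THRESHOLD, 0.0)


def glucose_rhs_arrays(G, X, E, RA, EGP, GEZI, SE, H, Gth):
    """dG/dt with hypoglycemia-amplified insulin action.

    dG/dt = -(GEZI + (1+h) X) G + EGP - SE*E + RA - FR, h = H when G < Gth.
    The (1+h) factor keeps insulin acting above the threshold and amplifies
    it below; H -> 0 removes the amplification entirely.
    """
    h = np.where(G < Gth, H, 0.0)
    return -(GEZI + (1.0 + h) * X) * G + EGP - SE * E + RA - renal_excretion(G)


def integrate_glucose(
    t_grid: np.ndarray,
    X_h: np.ndarray,
    E_h: np.ndarray,
    RA_h: np.ndarray,
    G0,
    SG0,
    EGP,
    GEZI,
    SE,
    H,
    Gth,
    tauG,
    floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 integration of the (G, SG) pair with forcing on the half grid.

    X_h, E_h, RA_h: (B, 2T+1) forcing on the half grid of t_grid (T+1,).
    Returns (G, SG) each (B, T+1).  With ``floor=None`` a NaN or non-positive
    glucose aborts with :class:`IntegrationError`; a positive floor clamps
    instead (used inside the likelihood where extreme latent draws must give
    a finite, if terrible, density).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(t_grid[1] - t_grid[0])
    B = X_h.shape[0]
    T = t_grid.size - 1
    if _kernels.HAVE_NUMBA:
        res = _kernels.rk4_glucose(X_h, E_h, RA_h, G0, SG0, EGP, GEZI, SE, H, Gth, tauG,
                                   dt, 0.0 if floor is None else float(floor))
        outG, outSG, bad = res
        if floor is None and bad >= 0:
            raise IntegrationError(
                f"glucose integration failed at t={t_grid[bad]:.1f} min", t=float(t_grid[bad]))
        return outG, outSG
    EGP, GEZI, SE, H, Gth, tauG = (np.broadcast_to(np.asarray(v, dtype=float), (B,)) for v in (EGP, GEZI, SE, H, Gth, tauG))
    G = np.broadcast_to(np.asarray(G0, dtype=float), (B,)).astype(float).copy()
    SG = np.broadcast_to(np.asarray(SG0, dtype=float), (B,)).astype(float).copy()
    outG = np.empty((B, T + 1))
    outSG = np.empty((B, T + 1))
    outG[:, 0] = G
    outSG[:, 0] = SG

    def rhs(Gv, SGv, i):
        dG = glucose_rhs_arrays(Gv, X_h[:, i], E_h[:, i], RA_h[:, i], EGP, GEZI, SE, H, Gth)
        dSG = (Gv - SGv) / tauG
        return dG, dSG

    for k in range(T):
        i0, i1, i2 = 2 * k, 2 * k + 1, 2 * k + 2
        k1G, k1S = rhs(G, SG, i0)
        k2G, k2S = rhs(G + 0.5 * dt * k1G, SG + 0.5 * dt * k1S, i1)
        k3G, k3S = rhs(G + 0.5 * dt * k2G, SG + 0.5 * dt * k2S, i1)
        k4G, k4S = rhs(G + dt * k3G, SG + dt * k3S, i2)
        G = G + (dt / 6.0) * (k1G + 2 * k2G + 2 * k3G + k4G)
        SG = SG + (dt / 6.0) * (k1S + 2 * k2S + 2 * k3S + k4S)
        if floor is not None:
            G = np.maximum(G, floor)
            SG = np.maximum(SG, floor)
        else:
            bad = ~np.isfinite(G) | (G <= 0) | ~np.isfinite(SG)
            if bad.any():
                raise IntegrationError(
                    f"glucose integration failed at t={t_grid[k + 1]:.1f} min "
                    f"({int(bad.sum())}/{B} batch rows non-finite or non-positive)",
                    t=float(t_grid[k + 1]),
                )
        outG[:, k + 1] = G
        outSG[:, k + 1] = SG
    return outG, outSG
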