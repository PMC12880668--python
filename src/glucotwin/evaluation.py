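"""Posterior-predictive analytics: fit quality, glycemic metrics under
variability replay, circadian peak-sensitivity periods, next-hour prediction
scenarios and post-hoc meal regressions."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm_api

from .hierarchy import HierModel
from .svi import FitResult, posterior_predictive, sample_posterior

__all__ = [
    "GlycemicMetrics",
    "PredictionScenario",
    "SCENARIOS",
    "rmse_posterior_mean",
    "glycemic_metrics",
    "replay_variability",
    "peak_si_fractions",
    "prediction_eval",
    "posthoc_meal_regression",
]

log = logging.getLogger(__name__)


@dataclass
class GlycemicMetrics:
    """Mean glucose and time in/below/above range, in percent of the window."""

    mean_bg: float
    tir: float
    tbr: float
    tar: float
    lo: float = 70.0
    hi: float = 180.0

    def __post_init__(self) -> None:
        if abs(self.tir + self.tbr + self.tar - 100.0) > 1e-9:
            raise ValueError("TIR + TBR + TAR must equal 100")


@dataclass
class PredictionScenario:
    """Blanking windows (min) for meal / insulin / activity effects before an
    origin, and the prediction horizons."""

    scenario_id: int
    meal_blank: float
    insulin_blank: float
    activity_blank: float
    horizons: tuple = (30.0, 60.0)
    require_absent: bool = False   # scenario 3: origins must be disturbance-free

    def __post_init__(self) -> None:
        if min(self.meal_blank, self.insulin_blank, self.activity_blank) < 0:
            raise ValueError("blanking windows must be non-negative")


SCENARIOS = {
    1: PredictionScenario(1, 45.0, 120.0, 1440.0),
    2: PredictionScenario(2, 30.0, 45.0, 45.0),
    3: PredictionScenario(3, 45.0, 120.0, 1440.0, require_absent=True),
}


def glycemic_metrics(traces, lo: float = 70.0, hi: float = 180.0) -> GlycemicMetrics:
    """Time-fraction metrics of one or many uniformly sampled glucose traces."""
    x = np.asarray(traces, dtype=float).ravel()
    tbr = 100.0 * np.mean(x < lo)
    tar = 100.0 * np.mean(x > hi)
    return GlycemicMetrics(mean_bg=float(x.mean()), tir=100.0 - tbr - tar,
                           tbr=float(tbr), tar=float(tar), lo=lo, hi=hi)


def rmse_posterior_mean(fit: FitResult, model: HierModel, n_draws: int = 200, seed: int = 0,
                        n_boot: int = 10_000) -> pd.DataFrame:
    """Per-patient RMSE between CGM and the posterior-predictive mean SG.

    The per-patient value is the mean over that patient's 24 h samples with
    a 95% nonparametric bootstrap CI over samples.
    """
    pp = posterior_predictive(fit, model, n_draws, seed=seed, resample="none")
    per_patient: dict[int, list[float]] = {}
    for w in pp:
        if w["cgm"].size == 0:
            log.warning("window patient %d sample %d has no CGM; excluded", w["patient"], w["sample"])
            continue
        mean_sg = w["SG"].mean(axis=0)
        pred = np.interp(w["cgm_t"], w["t_grid"], mean_sg)
        rmse = float(np.sqrt(np.mean((pred - w["cgm"]) ** 2)))
        per_patient.setdefault(w["patient"], []).append(rmse)
    rng = np.random.default_rng(seed)
    rows = []
    for p, vals in sorted(per_patient.items()):
        v = np.asarray(vals)
        boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        lo_, hi_ = np.percentile(boots, [2.5, 97.5])
        rows.append({"patient": p, "rmse": v.mean(), "ci_lo": lo_, "ci_hi": hi_,
                     "n_samples": v.size})
    return pd.DataFrame(rows)


def replay_variability(fit: FitResult, model: HierModel, mode: str = "interday",
                       n: int = 200, seed: int = 0, lo: float = 70.0,
                       hi: float = 180.0) -> dict:
    """Glycemic metrics of CGM vs resampled posterior-predictive ensembles.

    Returns a per-patient metrics table (CGM, intraday and — for
    mode='interday' — interday columns) and per-window 10-90 percentile
    bands with their mean widths.
    """
    if mode not in ("intraday", "interday"):
        raise ValueError("mode must be intraday or interday")
    modes = ["intraday"] + (["interday"] if mode == "interday" else [])
    ensembles = {m: posterior_predictive(fit, model, n, seed=seed, resample=m) for m in modes}
    rows = []
    pids = sorted({w["p"] for w in model.windows})
    bands = []
    for p in pids:
        cgm_all = np.concatenate([w["sample"].cgm for w in model.windows if w["p"] == p])
        row = {"patient": p}
        for name, metric in zip(("mean_bg", "tir", "tbr", "tar"), _metric_tuple(cgm_all, lo, hi)):
            row[f"cgm_{name}"] = metric
        for m in modes:
            sg = np.concatenate([e["SG"].ravel() for e in ensembles[m] if e["patient"] == p])
            for name, metric in zip(("mean_bg", "tir", "tbr", "tar"), _metric_tuple(sg, lo, hi)):
                row[f"{m}_{name}"] = metric
        rows.append(row)
    for wi, w in enumerate(model.windows):
        entry = {"patient": w["p"], "sample": w["s"], "t_grid": ensembles[modes[0]][wi]["t_grid"]}
        for m in modes:
            band = np.percentile(ensembles[m][wi]["SG"], [10, 90], axis=0)
            entry[f"{m}_band"] = band
            entry[f"{m}_width"] = float((band[1] - band[0]).mean())
        bands.append(entry)
    return {"metrics": pd.DataFrame(rows), "bands": bands}


def _metric_tuple(x, lo, hi):
    g = glycemic_metrics(x, lo, hi)
    return g.mean_bg, g.tir, g.tbr, g.tar


def peak_si_fractions(fit: FitResult, model: HierModel, n_draws: int = 500,
                      seed: int = 0) -> pd.DataFrame:
    """Share of posterior draws whose intraday insulin-sensitivity peak falls
    in the breakfast (2-10 h), lunch (10-18 h) or dinner (18-2 h) period.

    The sinusoid SIA sin(2 pi (t + phi)) peaks at time-of-day
    (0.25 - phi) mod 1; draws with SIA = 0 have no peak and are excluded
    (their count is reported).
    """
    draws = sample_posterior(fit, model, n_draws, seed=seed)
    rows = []
    for p in range(model.shape.n_patients):
        counts = {"B": 0, "L": 0, "D": 0}
        degenerate = 0
        for s in range(model.shape.n_samples[p]):
            sia = draws.value("SIA", p, s)
            phi = draws.value("SIphi", p, s)
            good = sia > 0
            degenerate += int((~good).sum())
            peak_h = 24.0 * ((0.25 - phi[good]) % 1.0)
            counts["B"] += int(((peak_h > 2) & (peak_h <= 10)).sum())
            counts["L"] += int(((peak_h > 10) & (peak_h <= 18)).sum())
            counts["D"] += int(((peak_h > 18) | (peak_h <= 2)).sum())
        total = sum(counts.values())
        rows.append({"patient": p,
                     "B": 100.0 * counts["B"] / total if total else np.nan,
                     "L": 100.0 * counts["L"] / total if total else np.nan,
                     "D": 100.0 * counts["D"] / total if total else np.nan,
                     "n_degenerate": degenerate})
    return pd.DataFrame(rows)


def _patient_level_redraw(model: HierModel, Z: np.ndarray, p: int, s: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Redraw sample-level SIE/EGP from the patient-level posterior structure
    (new-day parameters, per the prediction procedure)."""
    from .svi import _redraw_sample_sites

    Z = _redraw_sample_sites(model, Z, ["SIE"], p, s, rng)
    return _redraw_sample_sites(model, Z, ["EGP"], p, s, rng)


def prediction_eval(fit: FitResult, model: HierModel, scenario: PredictionScenario,
                    n_draws: int = 50, seed: int = 0, origin_stride: float = 30.0) -> pd.DataFrame:
    """Next-hour prediction RMSE under a disturbance-knowledge scenario.

    At each origin the forward simulation uses only events whose effects are
    knowable under the scenario (reported longer ago than the blanking
    window; future events are never used), EGP and SI redrawn from the
    patient-level posterior, and the prediction is re-anchored to the CGM
    value at the origin.  Scenario 3 instead requires the origin's blanking
    windows — and the prediction horizon — to be disturbance-free.
    """
    rng = np.random.default_rng(seed)
    draws = sample_posterior(fit, model, n_draws, seed=seed)
    hmax = max(scenario.horizons)
    err = {h: [] for h in scenario.horizons}
    n_origins = 0
    for wi, w in enumerate(model.windows):
        sm = w["sample"]
        p, s = w["p"], w["s"]
        Z = _patient_level_redraw(model, draws.Z.copy(), p, s, rng)
        ev_times = {"meal": [m["t_report"] for m in sm.meals],
                    "bolus": [b["t_report"] for b in sm.boluses],
                    "exercise": [e["t_report"] for e in sm.exercises]}
        blank = {"meal": scenario.meal_blank, "bolus": scenario.insulin_blank,
                 "exercise": scenario.activity_blank}
        origins = np.arange(60.0, 1440.0 - hmax + 1e-9, origin_stride)
        for t0 in origins:
            if scenario.require_absent:
                bad = False
                for kind, times in ev_times.items():
                    for t in times:
                        if t0 - blank[kind] < t <= t0 + hmax:
                            bad = True
                if bad:
                    continue
                keep = {k: [] for k in ev_times}
            else:
                keep = {k: [t for t in ts if t <= t0 - blank[k]] for k, ts in ev_times.items()}
            sub = _subset_window(model, w, keep)
            full = model._sim_window(Z, sub, full=True)
            tg = full["t_grid"]
            sg0 = _interp_rows(tg, full["SG"], t0)
            cgm0 = np.interp(t0, sm.cgm_t, sm.cgm)
            n_origins += 1
            for h in scenario.horizons:
                pred = cgm0 + (_interp_rows(tg, full["SG"], t0 + h) - sg0).mean()
                actual = np.interp(t0 + h, sm.cgm_t, sm.cgm)
                err[h].append(pred - actual)
    rows = []
    for h in scenario.horizons:
        e = np.asarray(err[h])
        rows.append({"scenario": scenario.scenario_id, "horizon_min": h,
                     "rmse": float(np.sqrt(np.mean(e ** 2))) if e.size else np.nan,
                     "n_origins": e.size})
    return pd.DataFrame(rows)


def _interp_rows(tg: np.ndarray, Y: np.ndarray, t: float) -> np.ndarray:
    i = int(np.clip(np.searchsorted(tg, t) - 1, 0, tg.size - 2))
    w = (t - tg[i]) / (tg[i + 1] - tg[i])
    return Y[:, i] * (1 - w) + Y[:, i + 1] * w


def _subset_window(model: HierModel, w: dict, keep: dict) -> dict:
    """A window dict whose event lists are restricted to the kept report times."""
    sub = dict(w)
    sub["meals"] = [m for m in w["meals"] if m["t_report"] in set(keep["meal"])]
    sub["boluses"] = [b for b in w["boluses"] if b["t_report"] in set(keep["bolus"])]
    sub["exercises"] = [e for e in w["exercises"] if e["t_report"] in set(keep["exercise"])]
    return sub


def posthoc_meal_regression(fit: FitResult, model: HierModel, n_draws: int = 500,
                            seed: int = 0) -> dict[str, pd.DataFrame]:
    """OLS of meal-parameter posterior means on macronutrients and glucose.

    For every reported meal, the posterior means of its absorption time
    constant (tauD2), start offset (TD) and carb coefficient (MA) are
    regressed on carbohydrate, fat and protein grams plus dCGM, the measured
    glucose at the self-reported time minus 40 mg/dL, with an intercept.
    """
    draws = sample_posterior(fit, model, n_draws, seed=seed)
    rows = []
    for w in model.windows:
        sm = w["sample"]
        p, s = w["p"], w["s"]
        for j, m in enumerate(sm.meals):
            suffix = f"m{j}"
            cgm_at = float(np.interp(m["t_report"], sm.cgm_t, sm.cgm))
            rows.append({
                "tauD2": float(draws.value("tauD2", p, s, suffix).mean()),
                "TD": float(draws.value("TD", p, s, suffix).mean()),
                "MA": float(draws.value("MA", p, s, suffix).mean()),
                "carbs": m["carbs"], "fat": m.get("fat", 0.0),
                "protein": m.get("protein", 0.0), "dCGM": cgm_at - 40.0,
            })
    df = pd.DataFrame(rows)
    if len(df) < 10:
        raise ValueError(f"post-hoc regression needs >= 10 meals, got {len(df)}")
    X = sm_api.add_constant(df[["carbs", "fat", "protein", "dCGM"]])
    out = {}
    for target in ("tauD2", "TD", "MA"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm_api.OLS(df[target], X).fit()
        ci = res.conf_int()
        out[target] = pd.DataFrame({
            "variable": ["Intercept", "Carbs", "Fat", "Protein", "dCGM"],
            "coeff": res.params.to_numpy(),
            "p_value": res.pvalues.to_numpy(),
            "ci_lo": ci[0].to_numpy(),
            "ci_hi": ci[1].to_numpy(),
        })
    return out
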