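"""Virtual cohort generation with known ground truth.

Emulates the composition of a free-living MDI study: per 24 h sample 2-4
meals in breakfast / lunch / dinner windows (mean ~2.7 per day), fast-acting
boluses paired with most meals (~0.7 each, so ~1.9 per day), occasional
exercise (~0.33 per day) with a heart-rate elevation, one long-acting
injection per day converted to a constant basal rate, and CGM at 5-minute
cadence with additive Gaussian noise at the sample's own latent noise level.
Latents are drawn from the hierarchical prior, so every generated cohort is
a fair draw from the model with the truth recorded for recovery checks.

The CGM noise of a clean window is redrawn (bounded retries) if white noise
at the drawn sigma happens to fabricate a >= 45 mg/dL consecutive-reading
jump; real sensor noise is autocorrelated and does not produce such
artefacts, and this keeps clean windows passing the discontinuity filter by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import CohortShape, HierModel, LatentDraws, sample_latents
from .pipeline import RawRecords, PatientRecords, Sample24h
from .priors import PriorTable, build_priors
from .simulate import simulate_sample

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "inject_defects", "exemplary_day"]

log = logging.getLogger(__name__)

_MEAL_WINDOWS = {"breakfast": (7 * 60, 9 * 60), "lunch": (12 * 60, 14 * 60),
                 "dinner": (18 * 60, 21 * 60), "snack": (15 * 60, 17 * 60)}


@dataclass
class CohortConfig:
    """Study-condition knobs of the generator (defaults mirror the emulated
    free-living cohort composition)."""

    n_patients: int = 10
    samples_per_patient: int = 50
    meal_count_probs: dict = field(default_factory=lambda: {2: 0.4, 3: 0.5, 4: 0.1})
    carbs_mean: float = 55.0        # g
    carbs_sd: float = 25.0
    carbs_range: tuple = (10.0, 150.0)
    bolus_prob: float = 0.7         # per meal
    units_per_10g: float = 1.0
    bolus_noise: float = 0.2        # relative sd of the dose rule
    exercise_prob: float = 0.33     # per day
    exercise_duration: tuple = (20.0, 60.0)   # min
    hr_elevation: tuple = (40.0, 80.0)        # bpm
    hr_baseline: tuple = (60.0, 75.0)         # per-patient, bpm
    basal_units_per_day: tuple = (22.0, 34.0)  # per-patient
    g0_mean: float = 140.0
    g0_sd: float = 25.0
    sigma_range: tuple | None = None   # override CGM noise sd (mg/dL); None -> latent draw
    cgm_cadence_min: float = 5.0
    start_date: str = "2024-03-01"
    max_retries: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.samples_per_patient < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.bolus_prob <= 1 or not 0 <= self.exercise_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything used to generate the cohort, for recovery checks."""

    draws: LatentDraws                # n_draws = 1, consistent across levels
    params: list                      # [patient][sample] SimulationParams
    events: list                      # [patient][sample] EventSet
    g0: list                          # [patient][sample] true initial glucose
    manifest: dict                    # designed pass/fail bookkeeping
    config: CohortConfig

    def value(self, name, patient=None, sample=None, event=None) -> float:
        return float(self.draws.value(name, patient, sample, event)[0])

    def to_json(self, path) -> None:
        latents = {n: float(self.draws.Z[0, i]) for n, i in self.draws.sites.index.items()}
        payload = {"latents": latents, "manifest": self.manifest,
                   "config": {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in asdict(self.config).items()}}
        Path(path).write_text(json.dumps(payload, indent=1))


def _schedule_day(rng: np.random.Generator, cfg: CohortConfig) -> tuple[list, list, list]:
    counts = sorted(cfg.meal_count_probs)
    probs = np.array([cfg.meal_count_probs[c] for c in counts], dtype=float)
    n_meals = int(rng.choice(counts, p=probs / probs.sum()))
    slots = {2: ["breakfast", "dinner"], 3: ["breakfast", "lunch", "dinner"],
             4: ["breakfast", "lunch", "snack", "dinner"]}[n_meals]
    meals, boluses = [], []
    for slot in slots:
        lo, hi = _MEAL_WINDOWS[slot]
        t = float(rng.uniform(lo, hi))
        carbs = float(np.clip(rng.normal(cfg.carbs_mean, cfg.carbs_sd), *cfg.carbs_range))
        fat = float(np.clip(rng.normal(0.35 * carbs, 10.0), 0.0, 100.0))
        protein = float(np.clip(rng.normal(0.4 * carbs, 12.0), 0.0, 120.0))
        meals.append({"t_report": round(t), "carbs": round(carbs, 1), "fat": round(fat, 1),
                      "protein": round(protein, 1)})
        if rng.uniform() < cfg.bolus_prob or not boluses and slot == slots[-1]:
            dose = cfg.units_per_10g * carbs / 10.0 * float(rng.normal(1.0, cfg.bolus_noise))
            dose = float(np.clip(dose, 0.5, 25.0))
            boluses.append({"t_report": round(t - float(rng.uniform(0, 15))), "dose": round(dose, 1)})
    meals.sort(key=lambda m: m["t_report"])
    boluses.sort(key=lambda b: b["t_report"])
    exercises = []
    if rng.uniform() < cfg.exercise_prob:
        t = float(rng.uniform(6 * 60, 21 * 60))
        exercises.append({"t_report": round(t), "duration": round(float(rng.uniform(*cfg.exercise_duration)))})
    return meals, boluses, exercises


def _resample_subtree(sites, Z: np.ndarray, prefix: str, rng: np.random.Generator) -> None:
    """Redraw (in ancestral order) every site whose name starts with prefix."""
    from scipy.special import ndtr, ndtri

    for i, name in enumerate(sites.names):
        if not name.startswith(prefix):
            continue
        if sites.loc_kind[i] == 2:
            k = int(np.nonzero(sites.egp_sites == i)[0][0])
            t = sites.egp_triples[k]
            loc = Z[0, t[0]] + Z[0, t[1]] * Z[0, t[2]]
        elif sites.loc_kind[i] == 1:
            loc = Z[0, sites.parent_idx[i]]
        else:
            loc = sites.loc_const[i]
        scale = max(Z[0, sites.scale_idx[i]] if sites.scale_kind[i] == 1 else sites.scale_const[i], 1e-12)
        if sites.family[i] == 1:
            Z[0, i] = rng.uniform(sites.lo[i], sites.hi[i])
        elif sites.family[i] == 2:
            Z[0, i] = rng.exponential(scale)
        else:
            a = ndtr((sites.lo[i] - loc) / scale) if np.isfinite(sites.lo[i]) else 0.0
            b = ndtr((sites.hi[i] - loc) / scale) if np.isfinite(sites.hi[i]) else 1.0
            q = np.clip(a + rng.uniform() * (b - a), 1e-15, 1 - 1e-15)
            Z[0, i] = float(np.clip(loc + scale * ndtri(q), sites.lo[i], sites.hi[i]))


def generate_cohort(config: CohortConfig | None = None, priors: PriorTable | None = None,
                    out_dir=None) -> tuple[GroundTruth, RawRecords]:
    """Generate a cohort: latents from the prior, schedules, traces, CSVs."""
    cfg = config if config is not None else CohortConfig()
    priors = priors if priors is not None else build_priors()
    rng = np.random.default_rng(cfg.seed)
    start0 = pd.Timestamp(cfg.start_date)

    # schedules first (they fix the hierarchy shape)
    schedules = []
    for p in range(cfg.n_patients):
        days = [_schedule_day(rng, cfg) for _ in range(cfg.samples_per_patient)]
        schedules.append(days)
    skeletons = []
    cadence = cfg.cgm_cadence_min
    cgm_t = np.arange(0.0, 1440.0, cadence)
    for p in range(cfg.n_patients):
        hr_base = float(rng.uniform(*cfg.hr_baseline))
        basal_dose = float(np.round(rng.uniform(*cfg.basal_units_per_day)))
        rows = []
        for s, (meals, boluses, exercises) in enumerate(schedules[p]):
            rows.append(Sample24h(
                patient_id=f"p{p:02d}", start=start0 + pd.Timedelta(days=s),
                cgm_t=cgm_t.copy(), cgm=np.zeros(cgm_t.size), hr_t=cgm_t.copy(),
                hr_bpm=np.zeros(cgm_t.size), meals=meals, boluses=boluses,
                exercises=exercises, basal_rate=basal_dose / 1440.0, g0=0.0,
                day_frac0=0.0, hr_rest=hr_base))
        skeletons.append(rows)

    model = HierModel([row for row in skeletons], priors=priors, dt=5.0)
    draws = sample_latents(priors, model.shape, seed=int(rng.integers(2 ** 31)), n_draws=1)

    truth_params, truth_events, truth_g0 = [], [], []
    designed: dict[str, list[bool]] = {}
    patients: dict[str, PatientRecords] = {}
    for p in range(cfg.n_patients):
        hr_base = skeletons[p][0].hr_rest
        t_par, e_par, g_par = [], [], []
        cgm_rows, hr_rows, ev_rows = [], [], []
        for s in range(cfg.samples_per_patient):
            sm = skeletons[p][s]
            start = sm.start
            # heart rate: baseline + noise + exercise elevation
            hr = hr_base + 4.0 + rng.normal(0.0, 3.0, size=cgm_t.size)
            for e in sm.exercises:
                lift = float(rng.uniform(*cfg.hr_elevation))
                on = (cgm_t >= e["t_report"]) & (cgm_t < e["t_report"] + e["duration"])
                hr[on] += lift
            sm.hr_bpm = np.round(np.maximum(hr, 40.0), 1)
            if cfg.sigma_range is not None:
                sig = float(rng.uniform(*cfg.sigma_range))
                draws.Z[0, model.sites.index[f"log_sigma.p{p}.s{s}"]] = np.log(sig)
            ok = False
            for attempt in range(cfg.max_retries):
                g0 = float(np.clip(rng.normal(cfg.g0_mean, cfg.g0_sd), 80.0, 240.0))
                sm.g0 = g0
                params, events = model.assemble_sample_params(draws, p, s)
                try:
                    tb = simulate_sample(params, events, sm.hr_t, sm.hr_bpm)
                except Exception:
                    tb = None
                if tb is not None and tb.G.min() > 25.0 and tb.G.max() < 550.0:
                    ok = True
                    break
                # redraw this sample's latent subtree and try again
                for name in ("EGP", "SIE", "SIA", "SIphi", "X0", "S0", "Ip0"):
                    _resample_subtree(model.sites, draws.Z, f"{name}.p{p}.s{s}", rng)
            if not ok:
                log.warning("patient %d sample %d kept after %d retries (glucose near bounds)",
                            p, s, cfg.max_retries)
                params, events = model.assemble_sample_params(draws, p, s)
                tb = simulate_sample(params, events, sm.hr_t, sm.hr_bpm)
            sigma = params.sigma
            sg5 = tb.sg_at(cgm_t)
            for _ in range(cfg.max_retries):
                noise = rng.normal(0.0, sigma, size=cgm_t.size)
                cgm = np.clip(sg5 + noise, 25.0, 590.0)
                if np.abs(np.diff(cgm)).max() < 45.0:
                    break
            sm.cgm = np.round(cgm, 1)
            designed.setdefault(f"p{p:02d}", []).append(
                bool(np.abs(np.diff(sm.cgm)).max() < 45.0))
            t_par.append(params)
            e_par.append(events)
            g_par.append(sm.g0)
            ts = start + pd.to_timedelta(cgm_t, unit="m")
            cgm_df = pd.DataFrame({"timestamp": ts, "glucose_mgdl": sm.cgm})
            if s == cfg.samples_per_patient - 1:
                # tail reading at the closing midnight so the last day's
                # window lies fully inside the CGM span
                tail = float(np.round(np.clip(tb.sg_at(1440.0) + rng.normal(0.0, sigma),
                                              25.0, 590.0), 1))
                cgm_df = pd.concat([cgm_df, pd.DataFrame(
                    {"timestamp": [start + pd.Timedelta(minutes=1440)],
                     "glucose_mgdl": [tail]})], ignore_index=True)
            cgm_rows.append(cgm_df)
            hr_rows.append(pd.DataFrame({"timestamp": ts, "bpm": sm.hr_bpm}))
            evs = [{"timestamp": start + pd.Timedelta(minutes=m["t_report"]), "type": "meal",
                    "value": m["carbs"], "fat_g": m["fat"], "protein_g": m["protein"]}
                   for m in sm.meals]
            evs += [{"timestamp": start + pd.Timedelta(minutes=b["t_report"]), "type": "bolus",
                     "value": b["dose"], "fat_g": np.nan, "protein_g": np.nan} for b in sm.boluses]
            evs += [{"timestamp": start + pd.Timedelta(minutes=e["t_report"]), "type": "exercise",
                     "value": e["duration"], "fat_g": np.nan, "protein_g": np.nan}
                    for e in sm.exercises]
            evs.append({"timestamp": start + pd.Timedelta(minutes=7 * 60), "type": "basal",
                        "value": round(sm.basal_rate * 1440.0, 1), "fat_g": np.nan, "protein_g": np.nan})
            if s == 0:
                # dose the evening before the first day so its window has a
                # long-acting injection in the preceding 24 h
                evs.append({"timestamp": start - pd.Timedelta(hours=17), "type": "basal",
                            "value": round(sm.basal_rate * 1440.0, 1), "fat_g": np.nan,
                            "protein_g": np.nan})
            ev_rows.append(pd.DataFrame(evs))
        truth_params.append(t_par)
        truth_events.append(e_par)
        truth_g0.append(g_par)
        events_df = pd.concat(ev_rows, ignore_index=True).sort_values("timestamp", kind="stable")
        patients[f"p{p:02d}"] = PatientRecords(
            cgm=pd.concat(cgm_rows, ignore_index=True),
            events=events_df.reset_index(drop=True),
            hr=pd.concat(hr_rows, ignore_index=True))

    manifest = {"n_patients": cfg.n_patients, "samples_per_patient": cfg.samples_per_patient,
                "designed_pass": designed,
                "designed_pass_count": int(sum(sum(v) for v in designed.values())),
                "defects": []}
    truth = GroundTruth(draws=draws, params=truth_params, events=truth_events, g0=truth_g0,
                        manifest=manifest, config=cfg)
    raw = RawRecords(patients)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw.write_dir(out)
        truth.to_json(out / "truth.json")
        Path(out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return truth, raw


def inject_defects(raw: RawRecords, defect_spec: list[dict],
                   manifest: dict | None = None) -> tuple[RawRecords, list[dict]]:
    """Deterministically corrupt selected day-windows of a generated cohort.

    Each spec entry: {"patient": "p00", "day": 3, "kind": one of
    gap | jump | no_meals | no_bolus | hr_sparse}.  Returns the corrupted
    records plus a manifest of the expected filter outcome per defect.
    A defect outside the data span raises.
    """
    out = {}
    for pid, pr in raw.patients.items():
        out[pid] = PatientRecords(cgm=pr.cgm.copy(), events=pr.events.copy(), hr=pr.hr.copy())
    expected = []
    for spec in defect_spec:
        pid, day, kind = spec["patient"], int(spec["day"]), spec["kind"]
        pr = out[pid]
        day0 = pr.cgm["timestamp"].iloc[0].normalize() + pd.Timedelta(days=day)
        day1 = day0 + pd.Timedelta(days=1)
        if day0 > pr.cgm["timestamp"].iloc[-1]:
            raise ValueError(f"defect day {day} outside data span for {pid}")
        in_day_cgm = (pr.cgm.timestamp >= day0) & (pr.cgm.timestamp < day1)
        in_day_ev = (pr.events.timestamp >= day0) & (pr.events.timestamp < day1)
        in_day_hr = (pr.hr.timestamp >= day0) & (pr.hr.timestamp < day1)
        if kind == "gap":
            t0 = day0 + pd.Timedelta(minutes=360)
            drop = in_day_cgm & (pr.cgm.timestamp > t0) & (pr.cgm.timestamp <= t0 + pd.Timedelta(minutes=13))
            pr.cgm = pr.cgm[~drop].reset_index(drop=True)
            fails = "cgm_gap"
        elif kind == "jump":
            idx = pr.cgm.index[in_day_cgm][len(pr.cgm.index[in_day_cgm]) // 2]
            prev = pr.cgm.loc[idx - 1, "glucose_mgdl"]
            pr.cgm.loc[idx, "glucose_mgdl"] = min(prev + 50.0, 590.0)
            fails = "cgm_jump"
        elif kind == "no_meals":
            drop = in_day_ev & (pr.events["type"] == "meal")
            pr.events = pr.events[~drop].reset_index(drop=True)
            fails = "meal_count"
        elif kind == "no_bolus":
            drop = in_day_ev & (pr.events["type"] == "bolus")
            pr.events = pr.events[~drop].reset_index(drop=True)
            fails = "bolus_count"
        elif kind == "hr_sparse":
            idx = pr.hr.index[in_day_hr]
            keep = idx[: max(1, int(0.25 * len(idx)))]
            pr.hr = pr.hr.drop(index=[i for i in idx if i not in set(keep)]).reset_index(drop=True)
            fails = "hr_coverage"
        else:
            raise ValueError(f"unknown defect kind {kind!r}")
        expected.append({**spec, "fails_rule": fails, "window_start": day0.isoformat()})
    if manifest is not None:
        manifest["defects"] = expected
        designed = manifest.get("designed_pass", {})
        hit = {(e["patient"], e["day"]) for e in expected}
        removed = sum(1 for pid, day in hit if designed.get(pid, [])[day])
        manifest["designed_pass_count"] = manifest.get("designed_pass_count", 0) - removed
    return RawRecords(out), expected


def exemplary_day(seed: int = 0) -> Sample24h:
    """A canonical 24 h input day (events + heart rate) for worked examples
    and prior-predictive checks; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    cgm_t = np.arange(0.0, 1440.0, 5.0)
    hr = 66.0 + rng.normal(0, 2.5, cgm_t.size)
    hr[(cgm_t >= 1000) & (cgm_t < 1045)] += 55.0
    return Sample24h(
        patient_id="example", start=pd.Timestamp("2024-03-01"), cgm_t=cgm_t,
        cgm=np.full(cgm_t.size, 140.0), hr_t=cgm_t.copy(), hr_bpm=np.round(hr, 1),
        meals=[{"t_report": 460.0, "carbs": 45.0, "fat": 15.0, "protein": 20.0},
               {"t_report": 770.0, "carbs": 70.0, "fat": 25.0, "protein": 30.0},
               {"t_report": 1160.0, "carbs": 60.0, "fat": 20.0, "protein": 25.0}],
        boluses=[{"t_report": 455.0, "dose": 4.5}, {"t_report": 765.0, "dose": 7.0},
                 {"t_report": 1155.0, "dose": 6.0}],
        exercises=[{"t_report": 1000.0, "duration": 45.0}],
        basal_rate=26.0 / 1440.0, g0=132.0, day_frac0=0.0, hr_rest=62.0)
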