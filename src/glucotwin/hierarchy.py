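"""The hierarchical Bayesian generative model over 24 h glucose samples.

Latents live on four levels — cohort, patient, sample (one 24 h window) and
event (meal / bolus / exercise).  A latent estimated on several levels forms
a chain of truncated-normal conditionals centred on the level above; spread
parameters are fixed table values or estimated sd hyper-latents.  Endogenous
glucose production is linked to insulin sensitivity through a linear
conditional mean EGP ~ TN(EGPi + EGPm * SIE, sd), reflecting the observed
correlation between the two across days.

The module provides site enumeration for a cohort shape, vectorised prior
sampling, the batched joint log-density (prior + CGM likelihood driven by
the simulation engine), parameter assembly for single-sample simulation and
prior-predictive checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from . import engine
from .events import BolusEvent, EventSet, ExerciseEvent, MealEvent
from .params import ModelState, SimulationParams
from .pipeline import Sample24h
from .priors import PriorTable, build_priors
from .transforms import SupportTransform

__all__ = [
    "CohortShape",
    "HierarchySpec",
    "SiteTable",
    "LatentDraws",
    "build_sites",
    "sample_latents",
    "egp_for_sample",
    "HierModel",
    "prior_predictive",
]

log = logging.getLogger(__name__)

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)
_EVENT_LEVELS = ("meal", "bolus", "exercise")
_G_FLOOR = 1.0  # mg/dL clamp inside the likelihood; extreme draws stay finite


@dataclass
class CohortShape:
    """Counts defining the hierarchy: patients, samples, events per sample."""

    n_samples: list[int]                      # per patient
    n_events: list[list[tuple[int, int, int]]]  # per (patient, sample): (meals, boluses, exercises)

    @property
    def n_patients(self) -> int:
        return len(self.n_samples)

    @classmethod
    def from_dataset(cls, dataset: list[list[Sample24h]]) -> "CohortShape":
        return cls(
            n_samples=[len(samples) for samples in dataset],
            n_events=[[(len(s.meals), len(s.boluses), len(s.exercises)) for s in samples]
                      for samples in dataset],
        )


@dataclass
class HierarchySpec:
    """Level map (latent name -> levels) plus the cohort counts."""

    levels: dict[str, tuple[str, ...]]
    shape: CohortShape

    @classmethod
    def from_priors(cls, priors: PriorTable, shape: CohortShape) -> "HierarchySpec":
        return cls({name: priors[name].levels for name in priors.names()}, shape)


class SiteTable:
    """Flat enumeration of every scalar latent site for one cohort shape."""

    def __init__(self, priors: PriorTable, shape: CohortShape):
        self.priors = priors
        self.shape = shape
        self.names: list[str] = []
        self._rows: list[dict] = []
        self._build()
        D = len(self.names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.lo = np.array([r["lo"] for r in self._rows])
        self.hi = np.array([r["hi"] for r in self._rows])
        self.family = np.array([r["family"] for r in self._rows], dtype=int)
        self.loc_kind = np.array([r["loc_kind"] for r in self._rows], dtype=int)
        self.loc_const = np.array([r["loc_const"] for r in self._rows])
        self.parent_idx = np.array([r["parent_idx"] for r in self._rows], dtype=int)
        self.scale_kind = np.array([r["scale_kind"] for r in self._rows], dtype=int)
        self.scale_const = np.array([r["scale_const"] for r in self._rows])
        self.scale_idx = np.array([r["scale_idx"] for r in self._rows], dtype=int)
        egp = [(i, r["egp"]) for i, r in enumerate(self._rows) if r["egp"] is not None]
        self.egp_sites = np.array([i for i, _ in egp], dtype=int)
        self.egp_triples = np.array([t for _, t in egp], dtype=int).reshape(-1, 3)
        self.transform = SupportTransform(self.lo, self.hi)
        self.D = D

    # -- construction -------------------------------------------------------
    def _add(self, name: str, spec, level: str, parent: str | None, patient: int | None) -> None:
        row = {"lo": spec.lo, "hi": spec.hi, "family": 0, "loc_kind": 0, "loc_const": 0.0,
               "parent_idx": 0, "scale_kind": 0, "scale_const": 1.0, "scale_idx": 0, "egp": None}
        root = spec.root
        is_root_level = level == spec.levels[0]
        if is_root_level and spec.linkage != "egp":
            if root.family == "uniform":
                row["family"] = 1
                row["lo"], row["hi"] = root.lower, root.upper
            elif root.family == "exponential":
                row["family"] = 2
                row["scale_const"] = root.scale
                row["lo"], row["hi"] = 0.0, np.inf
            elif root.family == "half_normal":
                row["loc_const"] = 0.0
                row["scale_const"] = root.scale
                row["lo"], row["hi"] = 0.0, np.inf
            else:  # truncated normal / normal
                row["loc_const"] = root.loc
                row["scale_const"] = root.scale
            # a root whose spread is itself estimated (e.g. tauD1 across patients)
            sd = spec.sds.get(level)
            if isinstance(sd, str):
                row["scale_kind"], row["scale_idx"] = 1, self._sd_index(sd, patient)
        elif spec.linkage == "egp":
            p = patient
            row["loc_kind"] = 2
            row["egp"] = (self.index_of(f"EGPi.p{p}"), self.index_of(f"EGPm.p{p}"),
                          self.index_of(parent))  # parent carries the SIE sample site name
            sd = spec.sds.get("sample")
            if isinstance(sd, str):
                row["scale_kind"], row["scale_idx"] = 1, self._sd_index(sd, patient)
            else:
                row["scale_const"] = float(sd)
        else:
            row["loc_kind"] = 1
            row["parent_idx"] = self.index_of(parent)
            sd = spec.sds.get(level)
            if sd is None:
                raise KeyError(f"latent {spec.name!r} lacks a spread for level {level!r}")
            if isinstance(sd, str):
                row["scale_kind"], row["scale_idx"] = 1, self._sd_index(sd, patient)
            else:
                row["scale_const"] = float(sd)
            if spec.circular:
                row["lo"], row["hi"] = -np.inf, np.inf
        self.names.append(name)
        self._rows.append(row)
        self.index = None  # invalidated during build; index_of uses _tmp_index
        self._tmp_index[name] = len(self.names) - 1

    def index_of(self, name: str) -> int:
        return self._tmp_index[name]

    def _sd_index(self, sd_name: str, patient: int | None) -> int:
        levels = self.priors[sd_name].levels
        if levels[0] == "cohort":
            return self.index_of(f"{sd_name}.c")
        return self.index_of(f"{sd_name}.p{patient}")

    def _build(self) -> None:
        self._tmp_index: dict[str, int] = {}
        priors, shape = self.priors, self.shape
        order = priors.names()
        # cohort sites (sd hypers first so roots may reference them)
        for name in sorted(order, key=lambda n: not n.startswith("sd_")):
            if priors[name].levels[0] == "cohort":
                self._add(f"{name}.c", priors[name], "cohort", None, None)
        for p in range(shape.n_patients):
            for name in sorted(order, key=lambda n: not n.startswith("sd_")):
                spec = priors[name]
                if "patient" in spec.levels:
                    parent = f"{name}.c" if spec.levels[0] == "cohort" else None
                    self._add(f"{name}.p{p}", spec, "patient", parent, p)
            for s in range(shape.n_samples[p]):
                for name in order:
                    spec = priors[name]
                    if "sample" in spec.levels:
                        if spec.linkage == "egp":
                            parent = f"SIE.p{p}.s{s}"
                        else:
                            parent = f"{name}.p{p}"
                        self._add(f"{name}.p{p}.s{s}", spec, "sample", parent, p)
                nm, nb, nx = shape.n_events[p][s]
                for kind, count, tag in (("meal", nm, "m"), ("bolus", nb, "b"), ("exercise", nx, "x")):
                    for j in range(count):
                        for name in order:
                            spec = priors[name]
                            if kind in spec.levels:
                                parent = f"{name}.p{p}" if "patient" in spec.levels else None
                                self._add(f"{name}.p{p}.s{s}.{tag}{j}", spec, kind, parent, p)

    # -- densities ----------------------------------------------------------
    def _cond_loc_scale(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        loc = np.broadcast_to(self.loc_const, Z.shape).copy()
        m = self.loc_kind == 1
        loc[:, m] = Z[:, self.parent_idx[m]]
        if self.egp_sites.size:
            t = self.egp_triples
            loc[:, self.egp_sites] = Z[:, t[:, 0]] + Z[:, t[:, 1]] * Z[:, t[:, 2]]
        scale = np.broadcast_to(self.scale_const, Z.shape).copy()
        m = self.scale_kind == 1
        scale[:, m] = np.maximum(Z[:, self.scale_idx[m]], 1e-12)
        return loc, scale

    def log_prior(self, Z: np.ndarray) -> np.ndarray:
        """Sum of all conditional prior log-densities; out-of-support -> -inf."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        ok = np.all((Z >= self.lo) & (Z <= self.hi), axis=1)
        loc, scale = self._cond_loc_scale(Z)
        out = np.zeros(Z.shape[0])
        tn = self.family == 0
        if tn.any():
            z = (Z[:, tn] - loc[:, tn]) / scale[:, tn]
            lp = -0.5 * z * z - np.log(scale[:, tn]) - _LOG_SQRT2PI
            lp -= _log_tn_norm_vec((self.lo[tn] - loc[:, tn]) / scale[:, tn],
                                   (self.hi[tn] - loc[:, tn]) / scale[:, tn])
            out += lp.sum(axis=1)
        un = self.family == 1
        if un.any():
            out += -np.log(self.hi[un] - self.lo[un]).sum()
        ex = self.family == 2
        if ex.any():
            out += (-np.log(scale[:, ex]) - Z[:, ex] / scale[:, ex]).sum(axis=1)
        return np.where(ok, out, -np.inf)

    def median_draw(self) -> np.ndarray:
        """Deterministic ancestral draw at the conditional medians, (D,)."""
        return self.sample(None, 1, median=True)[0]

    def sample(self, rng: np.random.Generator | None, n_draws: int = 1,
               median: bool = False) -> np.ndarray:
        """Ancestral sampling of all sites; returns (n_draws, D)."""
        Z = np.empty((n_draws, self.D))
        loc_const = self.loc_const
        for i in range(self.D):
            if self.loc_kind[i] == 1:
                loc = Z[:, self.parent_idx[i]]
            elif self.loc_kind[i] == 2:
                k = int(np.nonzero(self.egp_sites == i)[0][0])
                t = self.egp_triples[k]
                loc = Z[:, t[0]] + Z[:, t[1]] * Z[:, t[2]]
            else:
                loc = np.full(n_draws, loc_const[i])
            scale = Z[:, self.scale_idx[i]] if self.scale_kind[i] == 1 else np.full(n_draws, self.scale_const[i])
            scale = np.maximum(scale, 1e-12)
            u = np.full(n_draws, 0.5) if median else rng.uniform(size=n_draws)
            if self.family[i] == 1:
                Z[:, i] = self.lo[i] + u * (self.hi[i] - self.lo[i])
            elif self.family[i] == 2:
                Z[:, i] = -scale * np.log1p(-u)
            else:
                a = ndtr((self.lo[i] - loc) / scale) if np.isfinite(self.lo[i]) else 0.0
                b = ndtr((self.hi[i] - loc) / scale) if np.isfinite(self.hi[i]) else 1.0
                q = np.clip(a + u * (b - a), 1e-15, 1.0 - 1e-15)
                Z[:, i] = np.clip(loc + scale * ndtri(q), self.lo[i], self.hi[i])
        return Z


def _log_tn_norm_vec(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """log(Phi(beta) - Phi(alpha)) elementwise, tolerant of infinite bounds."""
    out = np.zeros(np.broadcast_shapes(alpha.shape, beta.shape))
    a_f, b_f = np.isfinite(alpha), np.isfinite(beta)
    only_b = ~a_f & b_f
    if only_b.any():
        out[only_b] = log_ndtr(beta[only_b])
    only_a = a_f & ~b_f
    if only_a.any():
        out[only_a] = log_ndtr(-alpha[only_a])
    both = a_f & b_f
    if both.any():
        hi = log_ndtr(beta[both])
        lo = log_ndtr(alpha[both])
        out[both] = hi + np.log1p(-np.exp(np.minimum(lo - hi, -1e-16)))
    return out


@dataclass
class LatentDraws:
    """Constrained latent values: (n_draws, D) matrix plus site metadata."""

    Z: np.ndarray
    sites: SiteTable

    @property
    def n_draws(self) -> int:
        return self.Z.shape[0]

    def col(self, name: str) -> np.ndarray:
        return self.Z[:, self.sites.index[name]]

    def value(self, name: str, patient: int | None = None, sample: int | None = None,
              event: str | None = None) -> np.ndarray:
        key = name
        if patient is not None:
            key += f".p{patient}"
            if sample is not None:
                key += f".s{sample}"
                if event is not None:
                    key += f".{event}"
        elif sample is None and event is None and f"{name}.c" in self.sites.index:
            key += ".c"
        return self.col(key)


def build_sites(priors: PriorTable, shape: CohortShape) -> SiteTable:
    return SiteTable(priors, shape)


def sample_latents(priors: PriorTable, hier: HierarchySpec | CohortShape,
                   seed: int, n_draws: int = 1) -> LatentDraws:
    """Ancestral prior draws for a cohort shape; reproducible given seed."""
    shape = hier.shape if isinstance(hier, HierarchySpec) else hier
    sites = build_sites(priors, shape)
    rng = np.random.default_rng(seed)
    return LatentDraws(Z=sites.sample(rng, n_draws), sites=sites)


def egp_for_sample(EGPi: float, EGPm: float, SIE_sample, sd_EGP: float,
                   seed: int | np.random.Generator = 0, size=None) -> np.ndarray:
    """Draw sample-level EGP ~ TN(EGPi + EGPm * SIE, sd, lower=0)."""
    if EGPi < 0:
        raise ValueError("EGPi must be non-negative")
    if sd_EGP <= 0:
        raise ValueError("sd_EGP must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loc = EGPi + EGPm * np.asarray(SIE_sample, dtype=float)
    a = ndtr((0.0 - loc) / sd_EGP)
    u = rng.uniform(size=size if size is not None else np.shape(loc))
    return loc + sd_EGP * ndtri(np.clip(a + u * (1.0 - a), 1e-15, 1 - 1e-15))


# ---------------------------------------------------------------------------
# the full model over a dataset


class HierModel:
    """Joint density over latents and CGM observations for a fixed dataset.

    ``dt`` is the likelihood simulation step in minutes (the published-scale
    configuration uses 1 min; the scaled-down test configuration 5 min).
    """

    def __init__(self, dataset: list[list[Sample24h]], priors: PriorTable | None = None,
                 dt: float = 1.0):
        self.dataset = dataset
        self.priors = priors if priors is not None else build_priors()
        self.shape = CohortShape.from_dataset(dataset)
        self.sites = build_sites(self.priors, self.shape)
        self.dt = float(dt)
        self.windows = []
        for p, samples in enumerate(dataset):
            for s, sm in enumerate(samples):
                self.windows.append(self._prep_window(p, s, sm))

    # -- window precomputation ---------------------------------------------
    def _prep_window(self, p: int, s: int, sm: Sample24h) -> dict:
        t_grid = np.arange(0.0, 1440.0 + 0.5 * self.dt, self.dt)
        th = engine.half_grid(t_grid)
        hr_th = engine.hr_to_grid(sm.hr_t, sm.hr_bpm, th, sm.hr_rest)
        cgm_t = np.clip(sm.cgm_t, 0.0, 1440.0)
        i0 = np.clip((cgm_t // self.dt).astype(int), 0, t_grid.size - 2)
        w = (cgm_t - t_grid[i0]) / self.dt
        ix = self.sites.index
        pref_p, pref_s = f".p{p}", f".p{p}.s{s}"
        cols = {k: ix[f"{k}{pref_p}"] for k in
                ("VG", "GEZI", "tauG", "tauI2", "tauI3", "tauI4", "H", "Gth", "SE", "tauE", "tauD1", "tauI1")}
        cols.update({k: ix[f"{k}{pref_s}"] for k in
                     ("EGP", "SIE", "SIA", "SIphi", "X0", "S0", "Ip0", "log_sigma")})
        meals = [{"t_report": m["t_report"], "carbs": m["carbs"],
                  "TD": ix[f"TD{pref_s}.m{j}"], "tauD2": ix[f"tauD2{pref_s}.m{j}"],
                  "MA": ix[f"MA{pref_s}.m{j}"], "tauD1": cols["tauD1"]}
                 for j, m in enumerate(sm.meals)]
        boluses = [{"t_report": b["t_report"], "dose": b["dose"],
                    "TI": ix[f"TI{pref_s}.b{j}"], "tauI1": ix[f"tauI1{pref_s}.b{j}"],
                    "IA": ix[f"IA{pref_s}.b{j}"]} for j, b in enumerate(sm.boluses)]
        exercises = [{"t_report": e["t_report"], "TP": ix[f"TP{pref_s}.x{j}"],
                      "tauP_long": ix[f"tauP_long{pref_s}.x{j}"],
                      "tauP_short": ix[f"tauP_short{pref_s}.x{j}"],
                      "P_long": ix[f"P_long{pref_s}.x{j}"], "P_short": ix[f"P_short{pref_s}.x{j}"]}
                     for j, e in enumerate(sm.exercises)]
        site_set = set(cols.values())
        for group in (meals, boluses, exercises):
            for ev in group:
                site_set.update(v for k, v in ev.items() if k not in ("t_report", "carbs", "dose"))
        return {"p": p, "s": s, "sample": sm, "t_grid": t_grid, "th": th, "hr_th": hr_th,
                "cgm_i0": i0, "cgm_w": w, "cols": cols, "meals": meals, "boluses": boluses,
                "exercises": exercises, "sites": np.array(sorted(site_set), dtype=int)}

    @property
    def D(self) -> int:
        return self.sites.D

    # -- simulation ---------------------------------------------------------
    def _sim_window(self, Z: np.ndarray, w: dict, full: bool = False):
        """Simulate one window under B latent rows; returns SG at CGM times.

        With ``full=True`` returns the (G, SG, X, RA, PA, SI, E) grid signals.
        """
        cols = w["cols"]
        c = lambda k: Z[:, cols[k]]
        th, dth = w["th"], w["th"][1] - w["th"][0]
        sm = w["sample"]
        meals = [{**m, "TD": Z[:, m["TD"]], "tauD1": Z[:, m["tauD1"]],
                  "tauD2": Z[:, m["tauD2"]], "MA": Z[:, m["MA"]]} for m in w["meals"]]
        boluses = [{**b, "TI": Z[:, b["TI"]], "tauI1": Z[:, b["tauI1"]], "IA": Z[:, b["IA"]]}
                   for b in w["boluses"]]
        exercises = [{**e, "TP": Z[:, e["TP"]], "tauP_long": Z[:, e["tauP_long"]],
                      "tauP_short": Z[:, e["tauP_short"]], "P_long": Z[:, e["P_long"]],
                      "P_short": Z[:, e["P_short"]]} for e in w["exercises"]]
        RA_h = engine.ra_signal(th, meals, c("VG"))
        PA_h = engine.pa_signal(th, exercises)
        if PA_h.shape[0] == 1 and Z.shape[0] > 1:
            PA_h = np.broadcast_to(PA_h, (Z.shape[0], th.size))
        SI_h = engine.si_signal(th, c("SIE"), c("SIA"), c("SIphi"), PA_h, sm.day_frac0)
        Ip_h = engine.ip_signal(th, boluses, sm.basal_rate, c("tauI1"), c("tauI2"), c("tauI3"),
                                S1_0=c("S0"), S2_0=c("S0"), Ip_0=c("Ip0"))
        X_h = engine.x_signal(SI_h, Ip_h, dth, c("tauI4"), X0=c("X0"))
        E_h = engine.e_signal(w["hr_th"], dth, c("tauE"), sm.hr_rest)
        if E_h.shape[0] == 1 and Z.shape[0] > 1:
            E_h = np.broadcast_to(E_h, (Z.shape[0], th.size))
        G, SG = engine.integrate_glucose(w["t_grid"], X_h, E_h, RA_h, sm.g0, sm.g0,
                                         c("EGP"), c("GEZI"), c("SE"), c("H"), c("Gth"),
                                         c("tauG"), floor=_G_FLOOR)
        if full:
            ev = slice(0, th.size, 2)
            return {"t_grid": w["t_grid"], "G": G, "SG": SG, "X": X_h[:, ev], "RA": RA_h[:, ev],
                    "PA": PA_h[:, ev], "SI": SI_h[:, ev], "E": E_h[:, ev]}
        sg_at = SG[:, w["cgm_i0"]] * (1.0 - w["cgm_w"]) + SG[:, w["cgm_i0"] + 1] * w["cgm_w"]
        return sg_at

    def window_loglik(self, Z: np.ndarray, wi: int) -> np.ndarray:
        w = self.windows[wi]
        sm = w["sample"]
        sg = self._sim_window(Z, w)
        sigma = np.exp(Z[:, w["cols"]["log_sigma"]])[:, None]
        r = (sm.cgm[None, :] - sg) / sigma
        return (-0.5 * r * r - np.log(sigma) - _LOG_SQRT2PI).sum(axis=1)

    def log_lik(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(Z)
        out = np.zeros(Z.shape[0])
        for wi in range(len(self.windows)):
            out += self.window_loglik(Z, wi)
        return out

    def log_prior(self, Z: np.ndarray) -> np.ndarray:
        return self.sites.log_prior(Z)

    def log_joint(self, Z: np.ndarray) -> np.ndarray:
        """Batched joint log density; out-of-support rows return -inf."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        lp = self.sites.log_prior(Z)
        ok = np.isfinite(lp)
        out = np.full(Z.shape[0], -np.inf)
        if ok.any():
            out[ok] = lp[ok] + self.log_lik(Z[ok])
        return out

    # -- assembly ------------------------------------------------------------
    def assemble_sample_params(self, draws: LatentDraws, patient: int, sample: int,
                               draw: int = 0) -> tuple[SimulationParams, EventSet]:
        """Flatten one latent draw into SimulationParams + EventSet."""
        if not (0 <= patient < self.shape.n_patients and 0 <= sample < self.shape.n_samples[patient]):
            raise IndexError("patient/sample index out of range")
        Z = draws.Z[draw]
        ix = draws.sites.index
        sm = self.dataset[patient][sample]
        g = lambda k: float(Z[ix[f"{k}.p{patient}"]])
        gs = lambda k: float(Z[ix[f"{k}.p{patient}.s{sample}"]])
        params = SimulationParams(
            VG=g("VG"), GEZI=g("GEZI"), EGP=gs("EGP"), SIE=gs("SIE"), SIA=gs("SIA"),
            SIphi=gs("SIphi") % 1.0, tauG=g("tauG"), tauI2=g("tauI2"), tauI3=g("tauI3"),
            tauI4=g("tauI4"), tauE=g("tauE"), SE=g("SE"), H=g("H"), Gth=g("Gth"),
            sigma=float(np.exp(gs("log_sigma"))), hr_rest=sm.hr_rest, day_frac0=sm.day_frac0,
            state0=ModelState(G=sm.g0, SG=sm.g0, S1=gs("S0"), S2=gs("S0"), Ip=gs("Ip0"),
                              X=gs("X0")),
        )
        pref = f".p{patient}.s{sample}"
        ev = EventSet(basal_rate=sm.basal_rate, tauI1_basal=g("tauI1"))
        for j, m in enumerate(sm.meals):
            ev.meals.append(MealEvent(t_report=m["t_report"], carbs=m["carbs"],
                                      fat=m.get("fat", 0.0), protein=m.get("protein", 0.0),
                                      TD=float(Z[ix[f"TD{pref}.m{j}"]]),
                                      tauD1=g("tauD1"), tauD2=float(Z[ix[f"tauD2{pref}.m{j}"]]),
                                      MA=float(Z[ix[f"MA{pref}.m{j}"]])))
        for j, b in enumerate(sm.boluses):
            ev.boluses.append(BolusEvent(t_report=b["t_report"], dose=b["dose"],
                                         TI=float(Z[ix[f"TI{pref}.b{j}"]]),
                                         tauI1=float(Z[ix[f"tauI1{pref}.b{j}"]]),
                                         IA=float(Z[ix[f"IA{pref}.b{j}"]])))
        for j, e in enumerate(sm.exercises):
            ev.exercises.append(ExerciseEvent(t_report=e["t_report"],
                                              TP=float(Z[ix[f"TP{pref}.x{j}"]]),
                                              tauP_long=float(Z[ix[f"tauP_long{pref}.x{j}"]]),
                                              tauP_short=float(Z[ix[f"tauP_short{pref}.x{j}"]]),
                                              P_long=float(Z[ix[f"P_long{pref}.x{j}"]]),
                                              P_short=float(Z[ix[f"P_short{pref}.x{j}"]])))
        return params, ev

    def scatter_sample_params(self, draws: LatentDraws, patient: int, sample: int,
                              params: SimulationParams, events: EventSet, draw: int = 0) -> None:
        """Inverse of assemble: write the bundle's values back into the draws."""
        Z = draws.Z[draw]
        ix = draws.sites.index
        for k, v in (("VG", params.VG), ("GEZI", params.GEZI), ("tauG", params.tauG),
                     ("tauI2", params.tauI2), ("tauI3", params.tauI3), ("tauI4", params.tauI4),
                     ("tauE", params.tauE), ("SE", params.SE), ("H", params.H), ("Gth", params.Gth)):
            Z[ix[f"{k}.p{patient}"]] = v
        pref = f".p{patient}.s{sample}"
        for k, v in (("EGP", params.EGP), ("SIE", params.SIE), ("SIA", params.SIA),
                     ("SIphi", params.SIphi), ("log_sigma", np.log(params.sigma)),
                     ("X0", params.state0.X), ("S0", params.state0.S1), ("Ip0", params.state0.Ip)):
            Z[ix[f"{k}{pref}"]] = v
        for j, m in enumerate(events.meals):
            Z[ix[f"TD{pref}.m{j}"]] = m.TD
            Z[ix[f"tauD2{pref}.m{j}"]] = m.tauD2
            Z[ix[f"MA{pref}.m{j}"]] = m.MA
        for j, b in enumerate(events.boluses):
            Z[ix[f"TI{pref}.b{j}"]] = b.TI
            Z[ix[f"tauI1{pref}.b{j}"]] = b.tauI1
            Z[ix[f"IA{pref}.b{j}"]] = b.IA
        for j, e in enumerate(events.exercises):
            Z[ix[f"TP{pref}.x{j}"]] = e.TP
            Z[ix[f"tauP_long{pref}.x{j}"]] = e.tauP_long
            Z[ix[f"tauP_short{pref}.x{j}"]] = e.tauP_short
            Z[ix[f"P_long{pref}.x{j}"]] = e.P_long
            Z[ix[f"P_short{pref}.x{j}"]] = e.P_short


def prior_predictive(priors: PriorTable, inputs: Sample24h, n: int = 200, seed: int = 0,
                     dt: float = 1.0) -> dict:
    """Prior-predictive ensemble for one day of inputs, plus range summaries.

    Simulates ``n`` prior draws of the full hierarchy (one patient, one
    sample shaped like ``inputs``) against the given events and heart rate,
    and additionally a zero-insulin / zero-meal conditioning run whose
    terminal glucose distribution diagnoses the endogenous production /
    clearance balance of the priors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = HierModel([[inputs]], priors=priors, dt=dt)
    draws = sample_latents(priors, model.shape, seed=seed, n_draws=n)
    full = model._sim_window(draws.Z, model.windows[0], full=True)
    frac = float(np.mean((full["G"] >= 0.0) & (full["G"] <= 400.0)))

    stripped = Sample24h(patient_id=inputs.patient_id, start=inputs.start, cgm_t=inputs.cgm_t,
                         cgm=inputs.cgm, hr_t=inputs.hr_t, hr_bpm=inputs.hr_bpm,
                         meals=[], boluses=[], exercises=[], basal_rate=0.0, g0=inputs.g0,
                         day_frac0=inputs.day_frac0, hr_rest=inputs.hr_rest)
    model0 = HierModel([[stripped]], priors=priors, dt=dt)
    draws0 = sample_latents(priors, model0.shape, seed=seed, n_draws=n)
    # zero-insulin conditioning: no boluses/basal and no initial insulin on board
    ix0 = draws0.sites.index
    for k in ("X0", "S0", "Ip0"):
        draws0.Z[:, ix0[f"{k}.p0.s0"]] = 0.0
    full0 = model0._sim_window(draws0.Z, model0.windows[0], full=True)
    terminal = full0["G"][:, -1]
    return {"t_grid": full["t_grid"], "G": full["G"], "SG": full["SG"],
            "frac_in_range": frac, "terminal_zero_insulin": terminal,
            "median_terminal_zero_insulin": float(np.median(terminal))}
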