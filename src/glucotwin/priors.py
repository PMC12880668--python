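"""Prior families and the default prior table of the hierarchical model.

The table assigns every latent its support, its root prior (applied at the
highest level the latent is estimated on) and the spread of each lower-level
conditional, which is either a fixed value or the name of an estimated
standard-deviation hyper-latent.  Entries whose numbers are physiological
defaults (chosen by prior-predictive calibration so that simulated glucose
spans the 0-400 mg/dL range) are marked ``source="default"``; entries pinned
by published estimates carry ``source="printed"``.

Units: minutes, mg/dL, grams; insulin sensitivity in 1/U (the microU-per-mL
to units conversion is folded into SI's effective gain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = ["PriorSpec", "LatentSpec", "PriorTable", "build_priors", "default_latent_specs"]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class PriorSpec:
    """A univariate prior: one of the five families used by the model."""

    family: str                    # truncated_normal | half_normal | exponential | uniform | log_normal
    loc: float = 0.0
    scale: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf
    source: str = "default"        # "printed" (published value) or "default"

    def __post_init__(self) -> None:
        allowed = {"truncated_normal", "half_normal", "exponential", "uniform", "log_normal"}
        if self.family not in allowed:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "half_normal":
            self.lower = 0.0
        if self.family == "exponential":
            self.lower = 0.0
        if not self.lower < self.upper:
            raise ValueError("prior requires lower < upper")
        if self.family == "uniform" and not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("uniform prior requires finite bounds")

    # -- numerics -----------------------------------------------------------
    def median(self) -> float:
        if self.family == "uniform":
            return 0.5 * (self.lower + self.upper)
        if self.family == "exponential":
            return self.scale * math.log(2.0)
        if self.family == "half_normal":
            return self.scale * 0.6744897501960817
        if self.family == "log_normal":
            return math.exp(self.loc)
        a = ndtr((self.lower - self.loc) / self.scale)
        b = ndtr((self.upper - self.loc) / self.scale)
        return self.loc + self.scale * ndtri(0.5 * (a + b))

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        u = rng.uniform(size=size)
        if self.family == "uniform":
            return self.lower + u * (self.upper - self.lower)
        if self.family == "exponential":
            return -self.scale * np.log1p(-u)
        if self.family == "log_normal":
            return np.exp(self.loc + self.scale * ndtri(u))
        loc, scale = self.loc, self.scale
        if self.family == "half_normal":
            loc, scale = 0.0, self.scale
        a = ndtr((self.lower - loc) / scale)
        b = ndtr((self.upper - loc) / scale)
        return loc + scale * ndtri(a + u * (b - a))

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        inside = (x >= self.lower) & (x <= self.upper)
        if self.family == "uniform":
            out[inside] = -math.log(self.upper - self.lower)
            return out
        if self.family == "exponential":
            out[inside] = -math.log(self.scale) - x[inside] / self.scale
            return out
        if self.family == "log_normal":
            z = (np.log(x[inside]) - self.loc) / self.scale
            out[inside] = -0.5 * z * z - np.log(x[inside] * self.scale * _SQRT2PI)
            return out
        loc, scale = (0.0, self.scale) if self.family == "half_normal" else (self.loc, self.scale)
        z = (x[inside] - loc) / scale
        lognorm = _log_tn_norm((self.lower - loc) / scale, (self.upper - loc) / scale)
        out[inside] = -0.5 * z * z - math.log(scale * _SQRT2PI) - lognorm
        return out

    def to_dict(self) -> dict:
        d = {"family": self.family, "loc": self.loc, "scale": self.scale, "source": self.source}
        if math.isfinite(self.lower):
            d["lower"] = self.lower
        if math.isfinite(self.upper):
            d["upper"] = self.upper
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(family=d["family"], loc=d.get("loc", 0.0), scale=d.get("scale", 1.0),
                   lower=d.get("lower", -math.inf), upper=d.get("upper", math.inf),
                   source=d.get("source", "default"))


def _log_tn_norm(alpha: float, beta: float) -> float:
    """log(Phi(beta) - Phi(alpha)), stable for one-sided truncation."""
    if alpha == -math.inf and beta == math.inf:
        return 0.0
    if alpha == -math.inf:
        return float(log_ndtr(beta))
    if beta == math.inf:
        return float(log_ndtr(-alpha))
    hi, lo = float(log_ndtr(beta)), float(log_ndtr(alpha))
    return hi + math.log1p(-math.exp(min(lo - hi, -1e-300)))


@dataclass
class LatentSpec:
    """One latent of the hierarchy: support, levels, root prior, spreads.

    ``levels`` runs from the highest estimation level downward, e.g.
    ("cohort", "patient", "sample") or ("patient", "meal").  ``root`` is the
    prior of the top-level value; each subsequent level is a truncated-normal
    conditional centred on its parent with the spread given in ``sds`` (a
    float, or the name of an estimated sd hyper-latent).  ``circular`` marks
    phase-like latents whose conditionals are plain normals (period folded in
    at use).  ``linkage="egp"`` marks the endogenous-glucose-production
    latent whose conditional mean is EGPi + EGPm * SIE of its sample.
    """

    name: str
    levels: tuple[str, ...]
    lo: float
    hi: float
    root: PriorSpec
    sds: dict = field(default_factory=dict)
    circular: bool = False
    linkage: str | None = None

    def to_dict(self) -> dict:
        return {"name": self.name, "levels": list(self.levels), "lo": self.lo, "hi": self.hi,
                "root": self.root.to_dict(),
                "sds": {k: (v if isinstance(v, (int, float, str)) else v) for k, v in self.sds.items()},
                "circular": self.circular, "linkage": self.linkage}

    @classmethod
    def from_dict(cls, d: dict) -> "LatentSpec":
        return cls(name=d["name"], levels=tuple(d["levels"]), lo=d["lo"], hi=d["hi"],
                   root=PriorSpec.from_dict(d["root"]), sds=dict(d.get("sds", {})),
                   circular=d.get("circular", False), linkage=d.get("linkage"))


def _tn(loc, scale, lo=-math.inf, hi=math.inf, source="default") -> PriorSpec:
    return PriorSpec("truncated_normal", loc=loc, scale=scale, lower=lo, upper=hi, source=source)


INF = math.inf


def default_latent_specs() -> list[LatentSpec]:
    """The packaged default table (see module docstring for provenance)."""
    L = LatentSpec
    specs = [
        # -- two-level physiology (cohort location, patient value) ----------
        L("VG", ("cohort", "patient"), 50.0, 250.0, _tn(120.0, 30.0, 50.0, 250.0), {"patient": 15.0}),
        L("GEZI", ("cohort", "patient"), 1e-3, 1e-2, _tn(2.5e-3, 1.5e-3, 1e-3, 1e-2, source="printed"),
          {"patient": 5e-4}),
        L("EGPi", ("cohort", "patient"), 0.0, 4.0, _tn(1.0, 0.4, 0.0, 4.0), {"patient": 0.25}),
        L("tauG", ("cohort", "patient"), 5.0, 30.0, _tn(15.0, 6.0, 5.0, 30.0, source="printed"),
          {"patient": 4.0}),
        L("tauI2", ("cohort", "patient"), 20.0, 120.0, _tn(60.0, 20.0, 20.0, 120.0), {"patient": 10.0}),
        L("tauI3", ("cohort", "patient"), 20.0, 120.0, _tn(60.0, 20.0, 20.0, 120.0), {"patient": 10.0}),
        L("tauI4", ("cohort", "patient"), 10.0, 60.0, _tn(25.0, 10.0, 10.0, 60.0), {"patient": 6.0}),
        L("H", ("cohort", "patient"), 0.0, 2.0, _tn(0.0, 0.25, 0.0, 2.0), {"patient": 0.15}),
        L("Gth", ("cohort", "patient"), 50.0, 80.0, _tn(65.0, 6.0, 50.0, 80.0), {"patient": 4.0}),
        L("SE", ("cohort", "patient"), 0.0, 0.05, _tn(0.01, 0.008, 0.0, 0.05), {"patient": 0.004}),
        L("tauE", ("cohort", "patient"), 5.0, 120.0, _tn(30.0, 15.0, 5.0, 120.0), {"patient": 8.0}),
        # -- patient-only ----------------------------------------------------
        L("EGPm", ("patient",), 0.0, 4.0, _tn(1.2, 0.6, 0.0, 4.0)),
        L("tauD1", ("patient",), 1.0, 10.0, _tn(6.0, 2.0, 1.0, 10.0, source="printed"),
          {"patient": "sd_tauD1"}),
        # -- three-level (cohort, patient, sample) ---------------------------
        L("SIE", ("cohort", "patient", "sample"), 0.02, 2.0, _tn(0.4, 0.2, 0.02, 2.0),
          {"patient": 0.12, "sample": "sd_SIE"}),
        L("SIA", ("cohort", "patient", "sample"), 0.0, 0.5, _tn(0.2, 0.12, 0.0, 0.5, source="printed"),
          {"patient": 0.08, "sample": "sd_SIA"}),
        L("SIphi", ("cohort", "patient", "sample"), -INF, INF,
          PriorSpec("uniform", lower=0.0, upper=1.0, source="printed"),
          {"patient": 0.15, "sample": "sd_SIphi"}, circular=True),
        L("X0", ("cohort", "patient", "sample"), 0.0, 0.05, _tn(0.008, 0.005, 0.0, 0.05),
          {"patient": 0.003, "sample": "sd_X0"}),
        L("S0", ("cohort", "patient", "sample"), 0.0, 0.2, _tn(0.02, 0.012, 0.0, 0.2),
          {"patient": 0.008, "sample": 0.006}),
        L("Ip0", ("cohort", "patient", "sample"), 0.0, 0.2, _tn(0.02, 0.012, 0.0, 0.2),
          {"patient": 0.008, "sample": 0.006}),
        L("log_sigma", ("cohort", "patient", "sample"), -INF, INF, _tn(math.log(10.0), 0.4),
          {"patient": 0.25, "sample": 0.2}),
        # -- sample-only: EGP via the EGP-SI linkage -------------------------
        L("EGP", ("sample",), 0.0, 8.0, _tn(1.5, 0.5, 0.0, 8.0), {"sample": "sd_EGP"}, linkage="egp"),
        # -- meal-level ------------------------------------------------------
        L("TD", ("meal",), -30.0, 90.0, _tn(15.0, 20.0, -30.0, 90.0)),
        L("tauD2", ("patient", "meal"), 20.0, 120.0, _tn(55.0, 15.0, 20.0, 120.0), {"meal": 15.0}),
        L("MA", ("meal",), 0.2, 3.0, _tn(1.0, 0.2, 0.2, 3.0, source="printed")),
        # -- bolus-level -----------------------------------------------------
        L("TI", ("bolus",), -30.0, 60.0, _tn(10.0, 12.0, -30.0, 60.0)),
        L("tauI1", ("patient", "bolus"), 5.0, 40.0, _tn(16.0, 6.0, 5.0, 40.0, source="printed"),
          {"bolus": "sd_tauI1"}),
        L("IA", ("bolus",), 0.2, 3.0, _tn(1.0, 0.2, 0.2, 3.0)),
        # -- exercise-level --------------------------------------------------
        L("TP", ("exercise",), -30.0, 60.0, _tn(10.0, 12.0, -30.0, 60.0, source="printed")),
        L("tauP_long", ("patient", "exercise"), 240.0, 4320.0, _tn(1040.0, 400.0, 240.0, 4320.0,
          source="printed"), {"exercise": "sd_tauP_long"}),
        L("tauP_short", ("patient", "exercise"), 5.0, 120.0, _tn(60.0, 30.0, 5.0, 120.0,
          source="printed"), {"exercise": 25.0}),
        L("P_long", ("exercise",), 0.0, 2.0, _tn(0.4, 0.3, 0.0, 2.0, source="printed")),
        L("P_short", ("exercise",), -1.0, 1.0, _tn(0.0, 0.3, -1.0, 1.0)),
        # -- estimated spread hypers ----------------------------------------
        L("sd_tauD1", ("cohort",), 0.0, INF, PriorSpec("exponential", scale=2.0)),
        L("sd_EGP", ("patient",), 0.0, INF, PriorSpec("exponential", scale=0.3)),
        L("sd_SIE", ("patient",), 0.0, INF, PriorSpec("exponential", scale=0.1)),
        L("sd_SIA", ("patient",), 0.0, INF, PriorSpec("exponential", scale=0.08)),
        L("sd_SIphi", ("patient",), 0.0, INF, PriorSpec("exponential", scale=0.1)),
        L("sd_tauP_long", ("patient",), 0.0, INF, PriorSpec("exponential", scale=300.0)),
        L("sd_X0", ("patient",), 0.0, INF, PriorSpec("half_normal", scale=0.004)),
        L("sd_tauI1", ("patient",), 0.0, INF, PriorSpec("half_normal", scale=5.0)),
    ]
    return specs


@dataclass
class PriorTable:
    """The effective prior table: latent specs keyed by name."""

    specs: dict[str, LatentSpec]

    def __getitem__(self, name: str) -> LatentSpec:
        return self.specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def names(self) -> list[str]:
        return list(self.specs)

    def levels_of(self, name: str) -> tuple[str, ...]:
        return self.specs[name].levels

    def to_dict(self) -> dict:
        return {"latents": [s.to_dict() for s in self.specs.values()]}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorTable":
        specs = [LatentSpec.from_dict(x) for x in d["latents"]]
        return cls({s.name: s for s in specs})

    @classmethod
    def from_yaml(cls, path) -> "PriorTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_priors(config: dict | None = None) -> PriorTable:
    """Assemble the effective prior table: packaged defaults plus overrides.

    ``config`` maps latent name to override dicts, e.g.
    ``{"SIE": {"root": {"loc": 0.5}, "sds": {"sample": 0.1}}}``.  Unknown
    names or malformed entries raise a configuration error.
    """
    table = {s.name: s for s in default_latent_specs()}
    for name, over in (config or {}).items():
        if name not in table:
            raise KeyError(f"unknown latent {name!r} in prior config")
        spec = table[name]
        root = spec.root
        if "root" in over:
            root = PriorSpec.from_dict({**root.to_dict(), **over["root"]})
        sds = {**spec.sds, **over.get("sds", {})}
        table[name] = replace(spec, root=root, sds=sds,
                              lo=over.get("lo", spec.lo), hi=over.get("hi", spec.hi))
    # sanity: every named sd hyper exists
    for spec in table.values():
        for v in spec.sds.values():
            if isinstance(v, str) and v not in table:
                raise KeyError(f"latent {spec.name!r} references unknown sd hyper {v!r}")
    return PriorTable(table)
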