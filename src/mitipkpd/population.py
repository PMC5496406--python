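"""Inter-individual variability and forward simulation of a full study.

Each structural parameter P with a random effect follows a log-normal
law across subjects, ``P_i = tvP * exp(eta_i)`` with
``eta_i ~ N(0, omega_P)``.  Three parameters — the peripheral volume,
the elimination clearance and the IC50 — carry no random effect: they
are typical-value-only in the final model (their inter-individual
variability shrank out during model building).

Published variabilities are quoted as CV%, which maps to the log-scale
variance through the exact log-normal relation ``omega = ln(1 + CV^2)``.

Residual (within-subject) error is proportional for the drug
concentration (assay error scales with the signal over the ~3 decades a
single-dose profile spans) and additive for glucose (narrow physiologic
range).  Neither magnitude is a structural constant of the model; both
are estimable and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import (
    StructuralPDParams,
    StructuralPKParams,
    central_concentration,
    effect_site_concentration,
    inhibitory_effect,
)

__all__ = [
    "PARAM_NAMES",
    "RANDOM_EFFECT_PARAMS",
    "FIXED_EFFECT_ONLY",
    "PopulationSpec",
    "DoseEvent",
    "Observation",
    "StudyDataset",
    "cv_to_omega",
    "omega_to_cv",
    "realize_individual",
    "sample_population",
    "simulate_study",
]

#: canonical parameter order used throughout the package
PARAM_NAMES = ("ka", "v", "v2", "cl", "cl2", "tlag", "ke0", "ic50", "gamma", "e0")

#: parameters that may carry a log-normal random effect
RANDOM_EFFECT_PARAMS = ("ka", "v", "tlag", "cl2", "ke0", "gamma", "e0")

#: parameters fixed at their typical value for every subject
FIXED_EFFECT_ONLY = ("v2", "cl", "ic50")

PK_PARAMS = ("ka", "v", "v2", "cl", "cl2", "tlag")
PD_PARAMS = ("ke0", "ic50", "gamma", "e0")


def cv_to_omega(cv_percent: float) -> float:
    """Log-normal variance omega from a coefficient of variation in percent."""
    cv = cv_percent / 100.0
    return math.log1p(cv * cv)


def omega_to_cv(omega: float) -> float:
    """Coefficient of variation (percent) of a log-normal with log-variance omega."""
    return 100.0 * math.sqrt(math.expm1(omega))


@dataclass(frozen=True)
class PopulationSpec:
    """Typical values, random-effect variances and residual error — the estimand.

    tv : typical value per structural parameter (units as in the
        structural parameter classes).
    omega : variance of the log-scale random effect, per parameter;
        only members of :data:`RANDOM_EFFECT_PARAMS` may appear.
    sigma_pk : proportional residual SD for drug concentration
        (dimensionless fraction).
    sigma_pd : additive residual SD for glucose (mmol/L).
    """

    tv: Mapping[str, float]
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_pk: float = 0.10
    sigma_pd: float = 0.15

    def __post_init__(self) -> None:
        tv = dict(self.tv)
        omega = dict(self.omega)
        object.__setattr__(self, "tv", tv)
        object.__setattr__(self, "omega", omega)
        missing = set(PARAM_NAMES) - set(tv)
        extra = set(tv) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(f"tv must name exactly {PARAM_NAMES}; missing {sorted(missing)}, extra {sorted(extra)}")
        for name, value in tv.items():
            lo_ok = value >= 0 if name == "tlag" else value > 0
            if not (math.isfinite(value) and lo_ok):
                raise ValueError(f"typical value {name}={value!r} out of range")
        bad = set(omega) - set(RANDOM_EFFECT_PARAMS)
        if bad:
            raise ValueError(
                f"random effects not permitted on {sorted(bad)}; "
                f"{FIXED_EFFECT_ONLY} are typical-value-only"
            )
        for name, value in omega.items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"omega[{name}]={value!r} must be >= 0")
        if not (self.sigma_pk > 0 and self.sigma_pd > 0):
            raise ValueError("residual SDs must be > 0")

    @classmethod
    def from_cv(
        cls,
        tv: Mapping[str, float],
        cv_percent: Mapping[str, float],
        sigma_pk: float = 0.10,
        sigma_pd: float = 0.15,
    ) -> "PopulationSpec":
        """Build a spec from CV% variabilities (omega = ln(1 + CV^2))."""
        omega = {k: cv_to_omega(v) for k, v in cv_percent.items()}
        return cls(tv=tv, omega=omega, sigma_pk=sigma_pk, sigma_pd=sigma_pd)

    def cv_percent(self, name: str) -> float:
        return omega_to_cv(self.omega.get(name, 0.0))

    def random_effect_names(self, subset: Iterable[str] | None = None) -> tuple[str, ...]:
        """Parameters with a strictly positive omega, in canonical order."""
        pool = RANDOM_EFFECT_PARAMS if subset is None else tuple(subset)
        return tuple(p for p in pool if self.omega.get(p, 0.0) > 0.0)

    def evolve(self, *, tv=None, omega=None, sigma_pk=None, sigma_pd=None) -> "PopulationSpec":
        """Copy with selected entries updated (dicts are merged)."""
        new_tv = dict(self.tv)
        new_tv.update(tv or {})
        new_om = dict(self.omega)
        new_om.update(omega or {})
        return PopulationSpec(
            tv=new_tv,
            omega=new_om,
            sigma_pk=self.sigma_pk if sigma_pk is None else sigma_pk,
            sigma_pd=self.sigma_pd if sigma_pd is None else sigma_pd,
        )


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose administration."""

    subject: str
    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError("dose amount must be > 0")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")


#: observation kinds and their NONMEM-style DVID codes
OBS_KINDS = {"drug_conc": 1, "glucose": 2}


@dataclass(frozen=True)
class Observation:
    """A timed measurement of drug concentration (mg/L) or glucose (mmol/L)."""

    subject: str
    time: float
    kind: str
    value: float
    below_limit: bool = False

    def __post_init__(self) -> None:
        if self.kind not in OBS_KINDS:
            raise ValueError(f"kind must be one of {sorted(OBS_KINDS)}")
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.value < 0 and not self.below_limit:
            raise ValueError("negative value must carry the below-limit flag")


class StudyDataset:
    """Dose events plus timed observations of two kinds for many subjects.

    Backed by two pandas DataFrames:

    - ``doses``: columns ``subject, time, amount``
    - ``observations``: columns ``subject, time, kind, value, blq``

    ``(subject, time, kind)`` is unique among observations; every
    observed subject appears in the roster, and every subject has at
    least one dose event.
    """

    def __init__(self, doses: pd.DataFrame, observations: pd.DataFrame):
        self.doses = doses.reset_index(drop=True).copy()
        self.observations = observations.reset_index(drop=True).copy()
        self.doses["subject"] = self.doses["subject"].astype(str)
        self.observations["subject"] = self.observations["subject"].astype(str)
        self.validate()

    @classmethod
    def from_records(cls, doses: Iterable[DoseEvent], observations: Iterable[Observation]) -> "StudyDataset":
        ddf = pd.DataFrame(
            [(d.subject, d.time, d.amount) for d in doses],
            columns=["subject", "time", "amount"],
        )
        odf = pd.DataFrame(
            [(o.subject, o.time, o.kind, o.value, bool(o.below_limit)) for o in observations],
            columns=["subject", "time", "kind", "value", "blq"],
        )
        return cls(ddf, odf)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.doses["subject"]), key=_subject_key))

    def validate(self) -> None:
        need_d = {"subject", "time", "amount"}
        need_o = {"subject", "time", "kind", "value", "blq"}
        if not need_d <= set(self.doses.columns):
            raise ValueError(f"dose table needs columns {sorted(need_d)}")
        if not need_o <= set(self.observations.columns):
            raise ValueError(f"observation table needs columns {sorted(need_o)}")
        if len(self.doses) == 0:
            raise ValueError("dataset has no dose events")
        dup = self.observations.duplicated(subset=["subject", "time", "kind"])
        if dup.any():
            rows = self.observations.index[dup].tolist()
            raise ValueError(f"duplicate (subject, time, kind) observation rows: {rows}")
        unknown = set(self.observations["subject"]) - set(self.doses["subject"])
        if unknown:
            raise ValueError(f"observations for subjects without a dose event: {sorted(unknown)}")
        if (self.observations["time"] < 0).any() or (self.doses["time"] < 0).any():
            raise ValueError("times must be >= 0")
        bad_kind = set(self.observations["kind"]) - set(OBS_KINDS)
        if bad_kind:
            raise ValueError(f"unknown observation kinds: {sorted(bad_kind)}")
        neg = (self.observations["value"] < 0) & ~self.observations["blq"].astype(bool)
        if neg.any():
            raise ValueError("negative observation values must carry the below-limit flag")

    def observations_of(self, kind: str) -> pd.DataFrame:
        return self.observations[self.observations["kind"] == kind].reset_index(drop=True)

    def for_subject(self, subject: str) -> "StudyDataset":
        s = str(subject)
        return StudyDataset(
            self.doses[self.doses["subject"] == s],
            self.observations[self.observations["subject"] == s],
        )

    def equals(self, other: "StudyDataset") -> bool:
        return self.doses.equals(other.doses) and self.observations.equals(other.observations)


def _subject_key(s: str):
    return (0, int(s)) if s.isdigit() else (1, s)


def realize_individual(
    spec: PopulationSpec, eta: Mapping[str, float] | None = None
) -> tuple[StructuralPKParams, StructuralPDParams]:
    """Individual structural parameters from typical values and log-scale etas.

    Parameters with a random effect scale as ``tv * exp(eta)``; missing
    eta entries are treated as zero.  Supplying an eta for a
    typical-value-only parameter is an error, preventing silent model
    drift.
    """
    eta = dict(eta or {})
    bad = set(eta) - set(RANDOM_EFFECT_PARAMS)
    if bad:
        raise ValueError(f"eta supplied for parameters with no random effect: {sorted(bad)}")
    values = {}
    for name in PARAM_NAMES:
        tv = spec.tv[name]
        values[name] = tv * math.exp(eta.get(name, 0.0))
    pk = StructuralPKParams(
        ka=values["ka"], v=values["v"], v2=values["v2"],
        cl=values["cl"], cl2=values["cl2"], tlag=values["tlag"],
    )
    pd_ = StructuralPDParams(
        ke0=values["ke0"], ic50=values["ic50"], gamma=values["gamma"], e0=values["e0"],
    )
    return pk, pd_


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject substream: adding subjects never perturbs earlier draws
    return np.random.default_rng([int(seed), int(index)])


def _draw_etas(spec: PopulationSpec, rng: np.random.Generator) -> dict[str, float]:
    z = rng.standard_normal(len(RANDOM_EFFECT_PARAMS))
    return {
        name: math.sqrt(spec.omega.get(name, 0.0)) * z[i]
        for i, name in enumerate(RANDOM_EFFECT_PARAMS)
        if spec.omega.get(name, 0.0) > 0.0
    }


def sample_population(
    spec: PopulationSpec, n: int, seed: int
) -> list[tuple[StructuralPKParams, StructuralPDParams]]:
    """Draw ``n`` virtual individuals; reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        eta = _draw_etas(spec, _subject_rng(seed, i))
        out.append(realize_individual(spec, eta))
    return out


def simulate_study(spec: PopulationSpec, design, seed: int, lloq: float = 2e-4) -> StudyDataset:
    """Simulate a complete single-dose study as a :class:`StudyDataset`.

    Per subject: draw etas, evaluate the closed-form concentration and
    glucose trajectories at the design times, then apply residual error
    (proportional on concentration, additive on glucose).  Values that
    would fall below zero are truncated at zero; drug values below
    ``lloq`` (mg/L) and truncated values carry the below-limit flag.
    """
    pk_times = np.asarray(design.pk_times, dtype=float)
    pd_times = np.asarray(design.pd_times, dtype=float)
    dose = float(design.dose)
    doses: list[DoseEvent] = []
    obs: list[Observation] = []
    for i in range(design.n_subjects):
        sid = str(i + 1)
        rng = _subject_rng(seed, i)
        eta = _draw_etas(spec, rng)
        pk, pd_ = realize_individual(spec, eta)
        doses.append(DoseEvent(subject=sid, time=0.0, amount=dose))

        c = central_concentration(pk_times, dose, pk.ka, pk.v, pk.v2, pk.cl, pk.cl2, pk.tlag)
        eps_pk = rng.standard_normal(pk_times.size)
        y_c = c * (1.0 + spec.sigma_pk * eps_pk)
        trunc_c = y_c < 0
        y_c = np.maximum(y_c, 0.0)
        for t, y, tr in zip(pk_times, y_c, trunc_c):
            obs.append(Observation(sid, float(t), "drug_conc", float(y), bool(tr or y < lloq)))

        ce = effect_site_concentration(
            pd_times, dose, pk.ka, pk.v, pk.v2, pk.cl, pk.cl2, pk.tlag, pd_.ke0
        )
        e = inhibitory_effect(np.maximum(ce, 0.0), pd_)
        eps_pd = rng.standard_normal(pd_times.size)
        y_e = e + spec.sigma_pd * eps_pd
        trunc_e = y_e < 0
        y_e = np.maximum(y_e, 0.0)
        for t, y, tr in zip(pd_times, y_e, trunc_e):
            obs.append(Observation(sid, float(t), "glucose", float(y), bool(tr)))
    return StudyDataset.from_records(doses, obs)
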