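"""Synthetic stand-in for the clinical study's raw data.

The underlying trial gave 18 fasted healthy volunteers a single 10 mg
oral dose and drew blood at 0, 0.08, 0.17, 0.25, 0.33, 0.5, 0.75, 1,
1.5, 2 and 3 h for both the drug assay and glucose.  No subject-level
data are deposited, so this module regenerates datasets with that exact
design and the published population parameters, making every
downstream stage testable without a download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationSpec, StudyDataset, simulate_study

__all__ = [
    "SAMPLING_TIMES",
    "StudyDesign",
    "reference_population",
    "nca_consistent_population",
    "default_design",
    "generate",
]

#: published blood-sampling schedule (h after dosing)
SAMPLING_TIMES = (0.0, 0.08, 0.17, 0.25, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class StudyDesign:
    """Single-oral-dose sampling design."""

    n_subjects: int = 18
    dose: float = 10.0
    pk_times: tuple = SAMPLING_TIMES
    pd_times: tuple = SAMPLING_TIMES

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        for name in ("pk_times", "pd_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must start at 0 and be strictly increasing")


#: published typical values (units: 1/h, L, L/h, h, mg/L, mmol/L)
_REFERENCE_TV = {
    "ka": 9.57,
    "tlag": 0.09,
    "v": 6.15,
    "cl": 0.03,
    "v2": 104.69,
    "cl2": 9.85,
    "ke0": 7.47,
    "ic50": 1.13,
    "gamma": 1.66,
    "e0": 4.65,
}

#: published inter-individual variabilities (CV%); parameters absent here
#: (v2, cl, ic50) carry no random effect in the final model
_REFERENCE_CV = {
    "ka": 91.95,
    "tlag": 70.71,
    "v": 17.61,
    "cl2": 22.18,
    "ke0": 90.61,
    "gamma": 18.67,
    "e0": 4.35,
}


def reference_population(sigma_pk: float = 0.10, sigma_pd: float = 0.15) -> PopulationSpec:
    """The published population parameter set, taken verbatim.

    Note the published typical elimination clearance (0.03 L/h) is far
    below the non-compartmental CL/F (7.80 L/h) from the same study —
    an internal inconsistency of the source tables.  This preset stores
    the population table as printed and treats it as a self-consistent
    generating truth for simulation and recovery exercises; see
    :func:`nca_consistent_population` for an alternative.
    """
    return PopulationSpec.from_cv(_REFERENCE_TV, _REFERENCE_CV, sigma_pk=sigma_pk, sigma_pd=sigma_pd)


def nca_consistent_population(sigma_pk: float = 0.10, sigma_pd: float = 0.15) -> PopulationSpec:
    """Synthetic demonstration preset: NOT the published population set.

    Identical to :func:`reference_population` except the elimination
    clearance is raised to 7.80 L/h so that the model's clearance
    matches the study's non-compartmental CL/F.  Useful for demos where
    an identifiable elimination pathway is wanted.
    """
    tv = dict(_REFERENCE_TV, cl=7.80)
    return PopulationSpec.from_cv(tv, _REFERENCE_CV, sigma_pk=sigma_pk, sigma_pd=sigma_pd)


def default_design() -> StudyDesign:
    """The published design: 18 subjects, 10 mg, 11 sampling times over 3 h."""
    return StudyDesign()


def generate(
    seed: int,
    design: StudyDesign | None = None,
    spec: PopulationSpec | None = None,
    lloq: float = 2e-4,
) -> StudyDataset:
    """Generate a reproducible synthetic study dataset.

    ``lloq`` is the drug-assay lower limit of quantification in mg/L
    (default 0.2 ng/mL, a typical LC-MS/MS scale); drug values below it
    are flagged below-limit.
    """
    if design is None:
        design = default_design()
    if spec is None:
        spec = reference_population()
    return simulate_study(spec, design, seed=seed, lloq=lloq)
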