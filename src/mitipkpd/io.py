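"""Dataset and fit-result input/output.

Study data travel in a long-format CSV following the NONMEM column
convention familiar across pharmacometrics:

    ID, TIME, DVID, DV, AMT, MDV, BLQ

Each row is either a dose row (AMT set, DV empty, MDV = 1) or an
observation row (DV set, AMT empty).  DVID codes the observation kind:
1 = drug concentration (mg/L), 2 = glucose (mmol/L).  BLQ flags
below-limit observations.  Rows are written sorted by (ID, TIME, DVID),
dose rows first within a time point, with full floating-point precision
so a write/read round trip is exact.

Fit results serialize to JSON (machine-readable) plus a text report
formatted the way population PK tables are published (typical value,
inter-individual CV%).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .estimation import FitResult
from .population import OBS_KINDS, PopulationSpec, StudyDataset, omega_to_cv

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_fit",
    "load_fit",
    "format_fit_report",
]

_COLUMNS = ["ID", "TIME", "DVID", "DV", "AMT", "MDV", "BLQ"]
_KIND_BY_DVID = {v: k for k, v in OBS_KINDS.items()}


def _fmt(x: float) -> str:
    # shortest representation that round-trips exactly
    return repr(float(x))


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a study dataset to the interchange CSV format."""
    rows = []
    for _, d in dataset.doses.iterrows():
        rows.append((str(d["subject"]), float(d["time"]), -1, "", _fmt(d["amount"]), 1, 0))
    for _, o in dataset.observations.iterrows():
        rows.append(
            (str(o["subject"]), float(o["time"]), OBS_KINDS[o["kind"]],
             _fmt(o["value"]), "", 0, int(bool(o["blq"])))
        )
    rows.sort(key=lambda r: (_id_key(r[0]), r[1], r[2]))
    lines = [",".join(_COLUMNS)]
    for sid, time, dvid, dv, amt, mdv, blq in rows:
        dvid_txt = "" if dvid < 0 else str(dvid)
        lines.append(f"{sid},{_fmt(time)},{dvid_txt},{dv},{amt},{mdv},{blq}")
    Path(path).write_text("\n".join(lines) + "\n")


def _id_key(s: str):
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def read_dataset(path) -> StudyDataset:
    """Read and validate an interchange CSV into a :class:`StudyDataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected header {_COLUMNS}")
    df.columns = [c.strip().upper() for c in df.columns]
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    doses, obs = [], []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            sid = str(rec["ID"]).strip()
            time = float(rec["TIME"])
            amt = rec["AMT"]
            has_amt = not (amt is None or (isinstance(amt, float) and math.isnan(amt)) or str(amt).strip() == "")
            if has_amt:
                doses.append({"subject": sid, "time": time, "amount": float(amt)})
                continue
            mdv = int(rec["MDV"]) if not _isna(rec["MDV"]) else 0
            if mdv == 1:
                continue
            dvid = int(float(rec["DVID"]))
            if dvid not in _KIND_BY_DVID:
                raise ValueError(f"unknown DVID {dvid}")
            value = float(rec["DV"])
            blq = bool(int(float(rec["BLQ"]))) if not _isna(rec["BLQ"]) else False
            obs.append({"subject": sid, "time": time, "kind": _KIND_BY_DVID[dvid], "value": value, "blq": blq})
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {row_number}: {exc}") from exc
    obs_df = pd.DataFrame(obs, columns=["subject", "time", "kind", "value", "blq"])
    dup = obs_df.duplicated(subset=["subject", "time", "kind"])
    if dup.any():
        first = int(obs_df.index[dup][0])
        raise ValueError(f"{path}: duplicate (ID, TIME, DVID) observation (record {first + 1})")
    dose_df = pd.DataFrame(doses, columns=["subject", "time", "amount"])
    return StudyDataset(dose_df, obs_df)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def save_fit(fit: FitResult, path) -> None:
    """Serialize a :class:`FitResult` to JSON."""
    payload = {
        "stage": fit.stage,
        "estimates": {
            "tv": dict(fit.estimates.tv),
            "omega": dict(fit.estimates.omega),
            "sigma_pk": fit.estimates.sigma_pk,
            "sigma_pd": fit.estimates.sigma_pd,
        },
        "objective": fit.objective,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "shrinkage": dict(fit.shrinkage),
        "objective_history": list(fit.objective_history),
        "se": fit.se,
        "messages": list(fit.messages),
        "ebe": {str(i): {c: float(fit.ebe.loc[i, c]) for c in fit.ebe.columns} for i in fit.ebe.index},
        "pk_individual": (
            fit.context["pk_individual"].astype(float).to_dict(orient="index")
            if "pk_individual" in fit.context else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_fit(path) -> FitResult:
    """Load a :class:`FitResult` written by :func:`save_fit`."""
    payload = json.loads(Path(path).read_text())
    est = payload["estimates"]
    spec = PopulationSpec(
        tv=est["tv"], omega=est["omega"], sigma_pk=est["sigma_pk"], sigma_pd=est["sigma_pd"]
    )
    ebe = pd.DataFrame.from_dict(payload["ebe"], orient="index")
    ebe.index.name = "subject"
    context = {}
    if payload.get("pk_individual"):
        pk_ind = pd.DataFrame.from_dict(payload["pk_individual"], orient="index")
        pk_ind.index.name = "subject"
        context["pk_individual"] = pk_ind
    return FitResult(
        estimates=spec,
        stage=payload["stage"],
        ebe=ebe,
        objective=payload["objective"],
        converged=payload["converged"],
        n_evaluations=payload["n_evaluations"],
        shrinkage=payload["shrinkage"],
        objective_history=payload.get("objective_history", []),
        se=payload.get("se"),
        messages=payload.get("messages", []),
        context=context,
    )


_REPORT_UNITS = {
    "ka": "1/h", "v": "L", "v2": "L", "cl": "L/h", "cl2": "L/h", "tlag": "h",
    "ke0": "1/h", "ic50": "mg/L", "gamma": "-", "e0": "mmol/L",
}


def format_fit_report(fit: FitResult) -> str:
    """Human-readable estimation report (typical value, IIV CV%, shrinkage)."""
    spec = fit.estimates
    lines = [
        f"stage: {fit.stage}",
        f"converged: {fit.converged}   objective (-2LL): {fit.objective:.4f}   "
        f"model evaluations: {fit.n_evaluations}",
        "",
        f"{'parameter':<12}{'unit':<10}{'typical':>12}{'IIV CV%':>10}{'shrinkage':>11}",
    ]
    for name in spec.tv:
        cv = f"{omega_to_cv(spec.omega[name]):.1f}" if spec.omega.get(name, 0.0) > 0 else "-"
        shr = f"{fit.shrinkage[name]:.2f}" if name in fit.shrinkage else "-"
        lines.append(f"{name:<12}{_REPORT_UNITS[name]:<10}{spec.tv[name]:>12.4g}{cv:>10}{shr:>11}")
    lines.append("")
    lines.append(f"sigma (proportional, drug): {spec.sigma_pk:.4g}")
    lines.append(f"sigma (additive, glucose, mmol/L): {spec.sigma_pd:.4g}")
    for msg in fit.messages:
        lines.append(f"note: {msg}")
    return "\n".join(lines)
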