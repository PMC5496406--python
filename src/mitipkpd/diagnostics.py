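"""Model-evaluation quantities: predictions and conditional weighted residuals.

For every retained observation the table carries

- PRED : population prediction, the model at typical values (eta = 0);
- IPRED : individual prediction, the model at the subject's EBE etas;
- CWRES : conditional weighted residual under the FOCE linearisation.

CWRES expands each subject's model to first order around the EBE mode:
``y ~ f(eta_hat) + J (eta - eta_hat) + eps`` gives marginal expectation
``E[y] = f(eta_hat) - J eta_hat`` and covariance
``V = J Omega J' + R`` (R the residual covariance evaluated at the
individual prediction), whence ``CWRES = V^(-1/2) (y - E[y])``.  When
the model is correct, CWRES is approximately standard normal; drug and
glucose observations are diagnosed separately because their residual
error models differ.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimation import _FOCESession, FitResult, PK_TV_NAMES
from .population import StudyDataset

__all__ = ["population_predictions", "cwres", "diagnostic_tables"]

logger = logging.getLogger(__name__)

_KIND = {"pk": "drug_conc", "pd": "glucose"}
_UNITS = {"pk": "mg/L", "pd": "mmol/L"}


def _session_for(fit: FitResult, dataset: StudyDataset) -> _FOCESession:
    if not fit.converged:
        raise ValueError("fit did not converge; diagnostics would be meaningless")
    pk_ind = fit.context.get("pk_individual") if fit.stage == "pd" else None
    return _FOCESession(dataset, fit.estimates, fit.stage, pk_individual=pk_ind)


def _ebe_matrix(fit: FitResult, session: _FOCESession) -> np.ndarray:
    missing = set(session.subjects) - set(fit.ebe.index.astype(str))
    if missing and session.eta_names:
        raise ValueError(f"no EBEs for subjects {sorted(missing)}")
    if not session.eta_names:
        return np.zeros((session.n, 0))
    ebe = fit.ebe.copy()
    ebe.index = ebe.index.astype(str)
    return ebe.loc[list(session.subjects), session.eta_names].to_numpy(dtype=float)


def _typical_pred(fit: FitResult, dataset: StudyDataset, session: _FOCESession) -> np.ndarray:
    """Population prediction: eta = 0 and, for the PD stage, typical PK."""
    if fit.stage == "pk":
        predict = session._predict_fn(fit.estimates)
        return predict(np.zeros((session.n, len(session.eta_names))))
    tv = fit.estimates.tv
    typical = pd.DataFrame(
        {name: [tv[name]] * session.n for name in PK_TV_NAMES},
        index=pd.Index(session.subjects, name="subject"),
    )
    typ_session = _FOCESession(dataset, fit.estimates, "pd", pk_individual=typical)
    predict = typ_session._predict_fn(fit.estimates)
    return predict(np.zeros((typ_session.n, len(typ_session.eta_names))))


def _assemble(fit: FitResult, dataset: StudyDataset):
    session = _session_for(fit, dataset)
    eta_hat = _ebe_matrix(fit, session)
    predict = session._predict_fn(fit.estimates)
    ipred = predict(eta_hat)
    pred0 = _typical_pred(fit, dataset, session)
    return session, eta_hat, ipred, pred0


def _obs_times(session: _FOCESession, dataset: StudyDataset, stage: str) -> np.ndarray:
    """(n, m) matrix of observation times matching the session's padding."""
    kind = _KIND[stage]
    t = np.full_like(session.y, np.nan)
    for i, sid in enumerate(session.subjects):
        obs = dataset.observations
        sel = obs[(obs["subject"] == sid) & (obs["kind"] == kind)].sort_values("time")
        tt = sel["time"].to_numpy(dtype=float)
        if stage == "pk":
            d = dataset.doses[dataset.doses["subject"] == sid]
            keep = (tt > float(d["time"].iloc[0])) & ~sel["blq"].to_numpy(dtype=bool)
            tt = tt[keep]
        t[i, : len(tt)] = tt
    return t


def population_predictions(fit: FitResult, dataset: StudyDataset) -> pd.DataFrame:
    """Per-observation DV, PRED (eta = 0) and IPRED (EBE eta)."""
    session, eta_hat, ipred, pred0 = _assemble(fit, dataset)
    times = _obs_times(session, dataset, fit.stage)
    frame = []
    for i, sid in enumerate(session.subjects):
        for j in range(session.y.shape[1]):
            if session.mask[i, j]:
                frame.append(
                    dict(subject=sid, time=times[i, j], kind=_KIND[fit.stage],
                         dv=session.y[i, j], pred=pred0[i, j], ipred=ipred[i, j])
                )
    return pd.DataFrame(frame)


def cwres(fit: FitResult, dataset: StudyDataset, fd_h: float = 1e-5) -> pd.DataFrame:
    """Conditional weighted residuals (FOCE linearisation at the EBEs)."""
    session, eta_hat, ipred, _ = _assemble(fit, dataset)
    times = _obs_times(session, dataset, fit.stage)
    var = session._var(fit.estimates)
    d = len(session.eta_names)
    n, m = session.y.shape
    predict = session._predict_fn(fit.estimates)
    jac = np.zeros((n, m, d))
    for k in range(d):
        step = np.zeros(d)
        step[k] = fd_h
        jac[:, :, k] = (predict(eta_hat + step) - predict(eta_hat - step)) / (2.0 * fd_h)
    omega = np.diag([fit.estimates.omega[name] for name in session.eta_names]) if d else np.zeros((0, 0))
    v_res = var.value(ipred)
    rows = []
    for i, sid in enumerate(session.subjects):
        sel = session.mask[i]
        y = session.y[i, sel]
        f = ipred[i, sel]
        ji = jac[i, sel, :]
        expect = f - ji @ eta_hat[i] if d else f
        cov = ji @ omega @ ji.T + np.diag(v_res[i, sel])
        w, q = np.linalg.eigh(cov)
        floor = 1e-12 * max(float(w.max()), 1.0)
        if np.any(w <= 0):
            logger.warning("singular marginal covariance for subject %s regularised", sid)
        w = np.maximum(w, floor)
        inv_sqrt = q @ np.diag(1.0 / np.sqrt(w)) @ q.T
        cw = inv_sqrt @ (y - expect)
        for j_local, j in enumerate(np.nonzero(sel)[0]):
            rows.append(dict(subject=sid, time=times[i, j], kind=_KIND[fit.stage], cwres=float(cw[j_local])))
    return pd.DataFrame(rows)


def diagnostic_tables(fit: FitResult, dataset: StudyDataset) -> dict[str, pd.DataFrame]:
    """The four standard goodness-of-fit scatter tables, plot-ready.

    Keys: ``cwres_vs_ivar``, ``cwres_vs_pred``, ``dv_vs_ipred``,
    ``dv_vs_pred``.  Each frame's ``attrs`` records axis units and the
    zero or identity reference line.
    """
    preds = population_predictions(fit, dataset)
    resid = cwres(fit, dataset)
    merged = preds.merge(resid, on=["subject", "time", "kind"])
    unit = _UNITS[fit.stage]
    tables = {
        "cwres_vs_ivar": merged[["subject", "kind", "time", "cwres"]].rename(columns={"time": "x", "cwres": "y"}),
        "cwres_vs_pred": merged[["subject", "kind", "pred", "cwres"]].rename(columns={"pred": "x", "cwres": "y"}),
        "dv_vs_ipred": merged[["subject", "kind", "ipred", "dv"]].rename(columns={"ipred": "x", "dv": "y"}),
        "dv_vs_pred": merged[["subject", "kind", "pred", "dv"]].rename(columns={"pred": "x", "dv": "y"}),
    }
    tables["cwres_vs_ivar"].attrs.update(x_unit="h", y_unit="", reference="y=0")
    tables["cwres_vs_pred"].attrs.update(x_unit=unit, y_unit="", reference="y=0")
    tables["dv_vs_ipred"].attrs.update(x_unit=unit, y_unit=unit, reference="identity")
    tables["dv_vs_pred"].attrs.update(x_unit=unit, y_unit=unit, reference="identity")
    return tables
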