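"""Population parameter estimation by FOCE maximum likelihood.

The marginal likelihood of a nonlinear mixed-effects model has no
closed form; the first-order conditional estimation (FOCE) method
approximates each subject's contribution by a Laplace expansion of the
joint density around the conditional mode of that subject's random
effects (the empirical Bayes estimate, EBE).  Writing the per-subject
negative joint log-likelihood

    l_i(eta) = 1/2 sum_j [ (y_ij - f_ij(eta))^2 / v_ij + log(2 pi v_ij) ]
             + 1/2 eta' Omega^-1 eta ,

with v_ij the residual variance (proportional for drug concentration,
so the expansion carries the "interaction" between eta and the residual
variance; additive for glucose), the approximate marginal deviance is

    -2 log L  ~  sum_i [ 2 l_i(eta_hat_i) + log det Omega + log det H_i ] ,

where H_i is the Hessian of l_i at the mode.  The inner mode search is
a damped Newton iteration with a Gauss-Newton Hessian, run *vectorised
across all subjects simultaneously*; the Laplace Hessian is then formed
by central finite differences of l_i itself.

Fitting is sequential: the PK stage first (drug concentrations only),
then the PD stage with every subject's PK fixed at its empirical Bayes
individual values (the IPP sequential strategy), so the PD stage never
re-integrates the PK system jointly.

All positive parameters are optimised on the log scale with a
derivative-free outer optimiser (Powell) under broad physiologic
bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .model_core import (
    _follower,
    _sigmoid_fraction,
    _triexp_terms,
    central_concentration,
    effect_site_concentration,
)
from .population import PopulationSpec, StudyDataset

__all__ = [
    "EstimationError",
    "FitResult",
    "individual_joint_loglik",
    "foce_objective",
    "fit_population_pk",
    "fit_population_pd",
    "eta_shrinkage",
    "empirical_bayes",
    "evaluate_spec",
    "individual_pk_parameters",
    "PK_ETA_POOL",
    "PD_ETA_POOL",
]

logger = logging.getLogger(__name__)

PK_ETA_POOL = ("ka", "v", "tlag", "cl2")
PD_ETA_POOL = ("ke0", "gamma", "e0")
PK_TV_NAMES = ("ka", "v", "v2", "cl", "cl2", "tlag")
PD_TV_NAMES = ("ke0", "ic50", "gamma", "e0")

#: predicted concentrations below this floor (mg/L) use a floored
#: proportional variance, avoiding singular densities at pre-lag zeros
CONC_FLOOR = 1e-6

# broad physiologic box constraints (natural scale) for the outer search
_BOUNDS = {
    "tv_ka": (1e-3, 1e3),
    "tv_v": (1e-2, 1e4),
    "tv_v2": (1e-2, 1e5),
    "tv_cl": (1e-6, 1e4),
    "tv_cl2": (1e-6, 1e4),
    "tv_tlag": (1e-4, 2.0),
    "tv_ke0": (1e-3, 1e3),
    "tv_ic50": (1e-4, 1e3),
    "tv_gamma": (0.1, 15.0),
    "tv_e0": (0.1, 100.0),
    "om": (1e-8, 9.0),
    "sigma_pk": (1e-4, 2.0),
    "sigma_pd": (1e-4, 10.0),
}


class EstimationError(RuntimeError):
    """Estimation could not be run or did not produce a usable result."""


@dataclass
class FitResult:
    """Outcome of one estimation stage."""

    estimates: PopulationSpec
    stage: str
    ebe: pd.DataFrame
    objective: float
    converged: bool
    n_evaluations: int
    shrinkage: dict
    objective_history: list = field(default_factory=list)
    se: dict | None = None
    messages: list = field(default_factory=list)
    context: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# residual-error models
# ---------------------------------------------------------------------------


class _ProportionalError:
    """v = sigma^2 * max(f, floor)^2 — SD proportional to the prediction."""

    def __init__(self, sigma: float, floor: float = CONC_FLOOR):
        self.sigma = float(sigma)
        self.floor = float(floor)

    def value(self, f):
        fc = np.maximum(f, self.floor)
        return (self.sigma * fc) ** 2

    def dvdf(self, f):
        fc = np.maximum(f, self.floor)
        return np.where(f > self.floor, 2.0 * self.sigma**2 * fc, 0.0)


class _AdditiveError:
    """v = sigma^2, independent of the prediction."""

    def __init__(self, sigma: float):
        self.sigma = float(sigma)

    def value(self, f):
        return np.full_like(np.asarray(f, float), self.sigma**2)

    def dvdf(self, f):
        return np.zeros_like(np.asarray(f, float))


# ---------------------------------------------------------------------------
# data matrices and vectorised predictors
# ---------------------------------------------------------------------------


def _stage_matrices(dataset: StudyDataset, kind: str, drop_predose: bool):
    """Pad each subject's observations into (n, m) matrices (NaN-padded).

    For the PK stage (``drop_predose``), pre-dose rows and below-limit
    drug observations are excluded from the likelihood: the former are
    structural zeros, the latter carry no quantifiable signal under a
    proportional error model (standard below-limit handling).
    """
    subjects = dataset.subjects
    t_list, y_list, dose_amt, dose_time = [], [], [], []
    for sid in subjects:
        d = dataset.doses[dataset.doses["subject"] == sid]
        if len(d) != 1:
            raise EstimationError(
                f"subject {sid}: exactly one dose event required, found {len(d)}"
            )
        t0 = float(d["time"].iloc[0])
        obs = dataset.observations
        obs = obs[(obs["subject"] == sid) & (obs["kind"] == kind)].sort_values("time")
        t = obs["time"].to_numpy(dtype=float)
        y = obs["value"].to_numpy(dtype=float)
        if drop_predose:
            keep = (t > t0) & ~obs["blq"].to_numpy(dtype=bool)
            t, y = t[keep], y[keep]
        t_list.append(t - t0)
        y_list.append(y)
        dose_amt.append(float(d["amount"].iloc[0]))
        dose_time.append(t0)
    n = len(subjects)
    m = max((len(t) for t in t_list), default=0)
    if m == 0 or all(len(t) == 0 for t in t_list):
        raise EstimationError(f"no usable {kind} observations in the dataset")
    t_mat = np.full((n, m), np.nan)
    y_mat = np.full((n, m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    for i, (t, y) in enumerate(zip(t_list, y_list)):
        t_mat[i, : len(t)] = t
        y_mat[i, : len(y)] = y
        mask[i, : len(t)] = True
    return subjects, np.asarray(dose_amt), t_mat, y_mat, mask


class _PKPredictor:
    """Closed-form central concentration for all subjects at once."""

    def __init__(self, times: np.ndarray, dose: np.ndarray):
        self.times = times
        self.dose = dose[:, None]
        self.n = times.shape[0]

    def __call__(self, tv: Mapping[str, float], eta: np.ndarray, eta_names: Sequence[str]):
        with np.errstate(all="ignore"):
            p = {}
            for name in PK_TV_NAMES:
                base = tv[name]
                if name in eta_names:
                    col = eta[:, eta_names.index(name)]
                    p[name] = (base * np.exp(col))[:, None]
                else:
                    p[name] = np.full((self.n, 1), base)
            return central_concentration(
                self.times, self.dose, p["ka"], p["v"], p["v2"], p["cl"], p["cl2"], p["tlag"]
            )


class _PDPredictor:
    """Glucose response with each subject's PK fixed (IPP sequential stage)."""

    def __init__(self, times: np.ndarray, dose: np.ndarray, pk_individual: pd.DataFrame, subjects):
        pk = pk_individual.loc[list(subjects)]
        ka = pk["ka"].to_numpy()[:, None]
        v = pk["v"].to_numpy()[:, None]
        v2 = pk["v2"].to_numpy()[:, None]
        cl = pk["cl"].to_numpy()[:, None]
        cl2 = pk["cl2"].to_numpy()[:, None]
        tlag = pk["tlag"].to_numpy()[:, None]
        self.lam, self.coef = _triexp_terms(dose[:, None], ka, v, v2, cl, cl2, on_degenerate="nudge")
        self.tau = times - tlag
        self.n = times.shape[0]
        self.max_ce_seen = 0.0

    def effect_site(self, ke0_col: np.ndarray):
        ce = _follower(self.lam, self.coef, ke0_col, self.tau)
        return np.maximum(ce, 0.0)

    def __call__(self, tv: Mapping[str, float], eta: np.ndarray, eta_names: Sequence[str]):
        with np.errstate(all="ignore"):
            p = {}
            for name in PD_TV_NAMES:
                base = tv[name]
                if name in eta_names:
                    col = eta[:, eta_names.index(name)]
                    p[name] = (base * np.exp(col))[:, None]
                else:
                    p[name] = np.full((self.n, 1), base)
            ce = self.effect_site(p["ke0"])
            finite = ce[np.isfinite(ce)]
            if finite.size:
                self.max_ce_seen = max(self.max_ce_seen, float(finite.max()))
            return p["e0"] * (1.0 - _sigmoid_fraction(ce, p["ic50"], p["gamma"]))


# ---------------------------------------------------------------------------
# vectorised inner problem (conditional modes) and Laplace term
# ---------------------------------------------------------------------------


def _make_ell(predict: Callable, y, mask, var, omega_inv):
    maskf = mask.astype(float)

    def ell(eta: np.ndarray) -> np.ndarray:
        f = predict(eta)
        v = var.value(f)
        vm = np.where(mask, v, 1.0)
        r = np.where(mask, y - f, 0.0)
        data = 0.5 * np.sum(maskf * (r * r / vm + np.log(2.0 * math.pi * vm)), axis=1)
        pen = 0.5 * np.einsum("ni,ij,nj->n", eta, omega_inv, eta)
        return data + pen

    return ell


def _inner_modes(predict, y, mask, var, omega_inv, eta0, max_iter=40, fd_h=1e-5):
    """Damped Newton search for every subject's conditional mode, batched.

    Returns (eta_hat, ell_hat, ell_fn, stalled) where ``stalled`` marks
    subjects whose final line search found no descent (their best
    available point is still returned and used, with a logged warning).
    """
    n, d = eta0.shape
    maskf = mask.astype(float)
    ell = _make_ell(predict, y, mask, var, omega_inv)
    eta = eta0.copy()
    l_cur = ell(eta)
    # recover from a bad warm start
    bad = ~np.isfinite(l_cur)
    if np.any(bad):
        eta[bad] = 0.0
        l_cur = ell(eta)
    stalled = np.zeros(n, dtype=bool)
    eye = np.eye(d)
    for _ in range(max_iter):
        f0 = predict(eta)
        # forward differences reuse f0: d+1 predictor calls per iteration
        # instead of 2d+1, and O(h) Jacobian error only displaces the mode
        # by O(h), which perturbs the objective at second order
        J = np.empty((n, y.shape[1], d))
        for k in range(d):
            step = np.zeros(d)
            step[k] = fd_h
            J[:, :, k] = (predict(eta + step) - f0) / fd_h
        J = np.where(mask[:, :, None], J, 0.0)
        v = var.value(f0)
        vm = np.where(mask, v, 1.0)
        r = np.where(mask, y - f0, 0.0)
        dv = var.dvdf(f0)[:, :, None] * J
        grad = (
            -np.einsum("nm,nmd->nd", maskf * r / vm, J)
            + 0.5 * np.einsum("nm,nmd->nd", maskf * (1.0 / vm - r * r / (vm * vm)), dv)
            + eta @ omega_inv
        )
        # the forward-difference Jacobian biases the gradient by O(fd_h),
        # so a tolerance below ~1e-4 is unreachable; at this tolerance the
        # mode itself is located to ~1e-5 (gradient error over curvature)
        done = np.max(np.abs(grad), axis=1) < 1e-4
        if done.all():
            stalled = np.zeros(n, dtype=bool)
            break
        hess = (
            np.einsum("nm,nmd,nme->nde", maskf / vm, J, J)
            + 0.5 * np.einsum("nm,nmd,nme->nde", maskf / (vm * vm), dv, dv)
            + omega_inv
        )
        hess = hess + 1e-9 * eye
        try:
            step_dir = -np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step_dir = -np.linalg.solve(hess + 1e-4 * eye, grad[..., None])[..., 0]
        slope = np.einsum("nd,nd->n", grad, step_dir)
        uphill = slope >= 0
        if np.any(uphill):
            step_dir[uphill] = -grad[uphill]
            slope[uphill] = -np.sum(grad[uphill] ** 2, axis=1)
        # cap the step: huge Newton moves arise next to likelihood cliffs
        norms = np.linalg.norm(step_dir, axis=1)
        too_big = norms > 5.0
        if np.any(too_big):
            scale = np.where(too_big, 5.0 / np.maximum(norms, 1e-300), 1.0)
            step_dir = step_dir * scale[:, None]
            slope = slope * scale
        t = np.ones(n)
        accepted = done.copy()  # converged subjects need no step
        step_dir[done] = 0.0
        new_eta = eta.copy()
        new_l = l_cur.copy()
        for _ls in range(15):
            trial = eta + t[:, None] * step_dir
            lt = ell(trial)
            ok = ~accepted & np.isfinite(lt) & (lt <= l_cur + 1e-4 * t * slope)
            new_eta[ok] = trial[ok]
            new_l[ok] = lt[ok]
            accepted |= ok
            if accepted.all():
                break
            t = np.where(accepted, t, 0.5 * t)
        stalled = ~accepted
        decrease = l_cur - new_l
        moved = np.abs(new_eta - eta).max() if n else 0.0
        eta, l_cur = new_eta, new_l
        if np.max(decrease, initial=0.0) < 1e-11 or moved < 1e-10:
            break
    if np.any(stalled):
        # a stalled line search at the very end of a solve usually means
        # the subject sits at the finite-difference noise floor (benign);
        # many subjects stalling at once points at a real problem
        n_stalled = int(np.sum(stalled))
        level = logging.WARNING if n_stalled > max(1, n // 20) else logging.DEBUG
        logger.log(
            level,
            "inner optimisation stalled for %d subject(s); best available mode used",
            n_stalled,
        )
    return eta, l_cur, ell, stalled


def _fd_hessian(ell, eta, h=1e-3):
    """Central finite-difference Hessian of the per-subject objective."""
    n, d = eta.shape
    hess = np.empty((n, d, d))
    l0 = ell(eta)
    units = np.eye(d) * h
    for k in range(d):
        lp = ell(eta + units[k])
        lm = ell(eta - units[k])
        hess[:, k, k] = (lp - 2.0 * l0 + lm) / (h * h)
    for j in range(d):
        for k in range(j + 1, d):
            lpp = ell(eta + units[j] + units[k])
            lpm = ell(eta + units[j] - units[k])
            lmp = ell(eta - units[j] + units[k])
            lmm = ell(eta - units[j] - units[k])
            val = (lpp - lpm - lmp + lmm) / (4.0 * h * h)
            hess[:, j, k] = val
            hess[:, k, j] = val
    return hess


def _gn_hessian(predict, y, mask, var, omega_inv, eta, fd_h=1e-5):
    """Gauss-Newton (classic FOCE linearised) Hessian at the mode."""
    n, d = eta.shape
    maskf = mask.astype(float)
    f0 = predict(eta)
    J = np.empty((n, y.shape[1], d))
    for k in range(d):
        step = np.zeros(d)
        step[k] = fd_h
        J[:, :, k] = (predict(eta + step) - predict(eta - step)) / (2.0 * fd_h)
    J = np.where(mask[:, :, None], J, 0.0)
    v = var.value(f0)
    vm = np.where(mask, v, 1.0)
    dv = var.dvdf(f0)[:, :, None] * J
    return (
        np.einsum("nm,nmd,nme->nde", maskf / vm, J, J)
        + 0.5 * np.einsum("nm,nmd,nme->nde", maskf / (vm * vm), dv, dv)
        + omega_inv
    )


def _logdet_psd(hess):
    """log-determinant with an eigenvalue floor (regularised if not PD)."""
    w = np.linalg.eigvalsh(hess)
    floor = 1e-10 * np.maximum(np.max(np.abs(w), axis=-1, keepdims=True), 1.0)
    if np.any(w <= 0):
        logger.warning("non-positive-definite Laplace Hessian regularised")
    return np.sum(np.log(np.maximum(w, floor)), axis=-1)


# ---------------------------------------------------------------------------
# the FOCE session: one stage, one dataset, cached matrices and warm modes
# ---------------------------------------------------------------------------


class _FOCESession:
    def __init__(
        self,
        dataset: StudyDataset,
        spec: PopulationSpec,
        stage: str,
        pk_individual: pd.DataFrame | None = None,
        hessian: str = "fd",
        pooled: bool = False,
    ):
        if stage not in ("pk", "pd"):
            raise ValueError("stage must be 'pk' or 'pd'")
        self.stage = stage
        self.hessian = hessian
        kind = "drug_conc" if stage == "pk" else "glucose"
        self.subjects, dose, times, self.y, self.mask = _stage_matrices(
            dataset, kind, drop_predose=(stage == "pk")
        )
        if stage == "pk":
            self.predictor = _PKPredictor(times, dose)
            pool = PK_ETA_POOL
            with np.errstate(invalid="ignore"):
                self.first_obs_time = np.nanmin(np.where(self.mask, times, np.nan), axis=1)
        else:
            if pk_individual is None:
                raise EstimationError("the PD stage needs individual PK parameters")
            missing = set(self.subjects) - set(pk_individual.index.astype(str))
            if missing:
                raise EstimationError(f"no individual PK parameters for subjects {sorted(missing)}")
            pk_individual = pk_individual.copy()
            pk_individual.index = pk_individual.index.astype(str)
            self.predictor = _PDPredictor(times, dose, pk_individual, self.subjects)
            pool = PD_ETA_POOL
        self.eta_names = [] if pooled else list(spec.random_effect_names(pool))
        self.n = len(self.subjects)
        self.warm = np.zeros((self.n, len(self.eta_names)))
        self.n_evaluations = 0

    def _var(self, spec: PopulationSpec):
        return _ProportionalError(spec.sigma_pk) if self.stage == "pk" else _AdditiveError(spec.sigma_pd)

    def _omega(self, spec: PopulationSpec):
        w = np.array([spec.omega[name] for name in self.eta_names], dtype=float)
        if np.any(w <= 0):
            raise EstimationError("omega must be > 0 for every active random effect")
        return np.diag(w), np.diag(1.0 / w), float(np.sum(np.log(w)))

    def _predict_fn(self, spec: PopulationSpec):
        tv = spec.tv
        names = self.eta_names
        return lambda eta: self.predictor(tv, eta, names)

    def _start_etas(self, spec: PopulationSpec, eta0: np.ndarray) -> np.ndarray:
        """Feasible inner starting point.

        The likelihood is flat in the lag eta wherever the model lag
        exceeds a subject's first quantifiable time (predictions are
        identically zero there), so a mode search started in that
        region cannot escape it.  Start each subject's lag below its
        first retained observation time.
        """
        eta0 = eta0.copy()
        if self.stage == "pk" and "tlag" in self.eta_names:
            j = self.eta_names.index("tlag")
            with np.errstate(divide="ignore", invalid="ignore"):
                cap = np.log(0.95 * self.first_obs_time / spec.tv["tlag"])
            ok = np.isfinite(cap)
            eta0[ok, j] = np.minimum(eta0[ok, j], cap[ok])
        return eta0

    def _modes(self, spec: PopulationSpec, predict, var, omega_inv, warm: bool):
        """Per-subject conditional modes from several deterministic starts.

        The joint density can be multimodal in (eta_ka, eta_tlag): the
        same apparent absorption onset is explained by a longer lag with
        faster absorption or vice versa, with likelihood cliffs where
        the lag crosses a sampling time.  Each subject keeps the best
        mode over the warm start, the (lag-feasible) zero start and
        fast/slow-absorption variants.
        """
        zero_start = self._start_etas(spec, np.zeros((self.n, len(self.eta_names))))
        starts = [zero_start]
        if warm:
            warm_start = self._start_etas(spec, self.warm)
            if not np.array_equal(warm_start, zero_start):
                starts.insert(0, warm_start)
        if "ka" in self.eta_names:
            j = self.eta_names.index("ka")
            for offset in (1.2, -1.2):
                s = zero_start.copy()
                s[:, j] += offset
                starts.append(s)
        best_eta, best_l = None, None
        if len(starts) > 1:
            # basin selection happens within the first few Newton steps, so
            # each start runs briefly, the per-subject best is kept, and
            # only that point is polished to convergence below
            for s in starts:
                eta_hat, l_hat, _, _ = _inner_modes(
                    predict, self.y, self.mask, var, omega_inv, s, max_iter=8
                )
                if best_eta is None:
                    best_eta, best_l = eta_hat, l_hat
                else:
                    better = l_hat < best_l
                    best_eta = np.where(better[:, None], eta_hat, best_eta)
                    best_l = np.where(better, l_hat, best_l)
        else:
            best_eta = starts[0]
        best_eta, best_l, ell_fn, _ = _inner_modes(
            predict, self.y, self.mask, var, omega_inv, best_eta
        )
        return best_eta, best_l, ell_fn

    def neg2ll(self, spec: PopulationSpec, warm: bool = True) -> float:
        """FOCE/Laplace approximate deviance (-2 marginal log-likelihood)."""
        self.n_evaluations += 1
        predict = self._predict_fn(spec)
        var = self._var(spec)
        d = len(self.eta_names)
        if d == 0:
            eta = np.zeros((self.n, 0))
            ell = _make_ell(predict, self.y, self.mask, var, np.zeros((0, 0)))
            return float(2.0 * np.sum(ell(eta)))
        _, omega_inv, logdet_omega = self._omega(spec)
        eta_hat, ell_hat, ell_fn = self._modes(spec, predict, var, omega_inv, warm)
        if warm:
            self.warm = eta_hat
        if self.hessian == "gn":
            hess = _gn_hessian(predict, self.y, self.mask, var, omega_inv, eta_hat)
        else:
            # exact curvature where trustworthy; a finite-difference Hessian
            # evaluated beside the absorption-lag cliff (or at a stalled,
            # non-minimal point) can lose positive definiteness, and its
            # floored log-determinant would spuriously reward such fits —
            # those subjects use the always-PD Gauss-Newton form instead
            hess = _fd_hessian(ell_fn, eta_hat)
            w_min = np.linalg.eigvalsh(hess).min(axis=-1)
            bad = w_min < 1e-6
            if np.any(bad):
                gn = _gn_hessian(predict, self.y, self.mask, var, omega_inv, eta_hat)
                hess[bad] = gn[bad]
        logdet_h = _logdet_psd(hess)
        return float(np.sum(2.0 * ell_hat + logdet_omega + logdet_h))

    def ebe(self, spec: PopulationSpec) -> pd.DataFrame:
        """Empirical Bayes estimates (conditional modes), cold-started."""
        predict = self._predict_fn(spec)
        var = self._var(spec)
        if not self.eta_names:
            return pd.DataFrame(index=pd.Index(self.subjects, name="subject"))
        _, omega_inv, _ = self._omega(spec)
        eta_hat, _, _ = self._modes(spec, predict, var, omega_inv, warm=False)
        return pd.DataFrame(eta_hat, index=pd.Index(self.subjects, name="subject"), columns=self.eta_names)


# ---------------------------------------------------------------------------
# public likelihood evaluations
# ---------------------------------------------------------------------------


def individual_joint_loglik(
    spec: PopulationSpec,
    subject_data: StudyDataset,
    eta: Mapping[str, float] | Sequence[float],
    stage: str,
    pk_individual: pd.DataFrame | None = None,
) -> float:
    """Joint log-density log p(y | eta) + log p(eta) for one subject.

    This is the inner objective whose mode defines the EBE.  ``eta``
    may be a mapping (parameter name -> value) or a vector in the
    stage's canonical random-effect order.
    """
    session = _FOCESession(subject_data, spec, stage, pk_individual=pk_individual)
    if session.n != 1:
        raise ValueError("subject_data must contain exactly one subject")
    d = len(session.eta_names)
    if isinstance(eta, Mapping):
        bad = set(eta) - set(session.eta_names)
        if bad:
            raise ValueError(f"eta supplied for inactive random effects: {sorted(bad)}")
        vec = np.array([[float(eta.get(name, 0.0)) for name in session.eta_names]])
    else:
        vec = np.asarray(eta, dtype=float).reshape(1, d)
    var = session._var(spec)
    if d:
        _, omega_inv, logdet_omega = session._omega(spec)
    else:
        omega_inv, logdet_omega = np.zeros((0, 0)), 0.0
    ell = _make_ell(session._predict_fn(spec), session.y, session.mask, var, omega_inv)
    value = float(ell(vec)[0])
    return -(value + 0.5 * (d * math.log(2.0 * math.pi) + logdet_omega))


def foce_objective(
    spec: PopulationSpec,
    dataset: StudyDataset,
    stage: str,
    pk_individual: pd.DataFrame | None = None,
    hessian: str = "fd",
) -> float:
    """FOCE approximate deviance of ``spec`` on ``dataset`` for one stage."""
    session = _FOCESession(dataset, spec, stage, pk_individual=pk_individual, hessian=hessian)
    return session.neg2ll(spec, warm=False)


def empirical_bayes(
    spec: PopulationSpec,
    dataset: StudyDataset,
    stage: str,
    pk_individual: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Conditional-mode (EBE) eta vectors for every subject at fixed ``spec``."""
    session = _FOCESession(dataset, spec, stage, pk_individual=pk_individual)
    return session.ebe(spec)


def eta_shrinkage(ebe: pd.DataFrame, omega: Mapping[str, float]) -> dict:
    """Eta-shrinkage, 1 - SD(EBE)/sqrt(omega), per random-effect parameter.

    Values near 1 mean the individual data carry no information on that
    random effect; by the study's model-building rule, parameters
    shrinking above 0.5 lose their random effect.
    """
    if len(ebe) < 3:
        raise ValueError("shrinkage needs at least 3 subjects")
    out = {}
    for name in ebe.columns:
        om = omega.get(name, 0.0)
        if om <= 0:
            raise ValueError(f"omega[{name}] must be > 0 to report shrinkage")
        out[name] = 1.0 - float(np.std(ebe[name].to_numpy(), ddof=1)) / math.sqrt(om)
    return out


def individual_pk_parameters(pk_fit: FitResult) -> pd.DataFrame:
    """Per-subject PK parameters: typical values scaled by the EBE etas."""
    tv = pk_fit.estimates.tv
    rows = {}
    for sid in pk_fit.ebe.index:
        rows[sid] = {
            name: tv[name] * math.exp(float(pk_fit.ebe.loc[sid].get(name, 0.0)))
            for name in PK_TV_NAMES
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")


def evaluate_spec(
    spec: PopulationSpec,
    dataset: StudyDataset,
    stage: str,
    pk_individual: pd.DataFrame | None = None,
) -> FitResult:
    """Wrap a known parameter set as a :class:`FitResult` without fitting.

    Computes the FOCE deviance, EBEs and shrinkage at ``spec`` —
    useful for diagnostics of simulated data under the generating model.
    """
    session = _FOCESession(dataset, spec, stage, pk_individual=pk_individual)
    objective = session.neg2ll(spec, warm=False)
    ebe = session.ebe(spec)
    shrink = eta_shrinkage(ebe, spec.omega) if (len(ebe.columns) and len(ebe) >= 3) else {}
    context = {} if stage == "pk" else {"pk_individual": pk_individual}
    return FitResult(
        estimates=spec,
        stage=stage,
        ebe=ebe,
        objective=objective,
        converged=True,
        n_evaluations=session.n_evaluations,
        shrinkage=shrink,
        objective_history=[objective],
        context=context,
    )


# ---------------------------------------------------------------------------
# outer maximum-likelihood fits
# ---------------------------------------------------------------------------


def _apply_free(spec: PopulationSpec, free_names: Sequence[str], x: np.ndarray) -> PopulationSpec:
    tv, omega = {}, {}
    sigma_pk = sigma_pd = None
    for name, xv in zip(free_names, x):
        value = math.exp(float(xv))
        if name.startswith("tv_"):
            tv[name[3:]] = value
        elif name.startswith("om_"):
            omega[name[3:]] = value
        elif name == "sigma_pk":
            sigma_pk = value
        elif name == "sigma_pd":
            sigma_pd = value
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    return spec.evolve(tv=tv, omega=omega, sigma_pk=sigma_pk, sigma_pd=sigma_pd)


def _free_x0(spec: PopulationSpec, free_names: Sequence[str]) -> np.ndarray:
    vals = []
    for name in free_names:
        if name.startswith("tv_"):
            vals.append(spec.tv[name[3:]])
        elif name.startswith("om_"):
            vals.append(spec.omega[name[3:]])
        elif name == "sigma_pk":
            vals.append(spec.sigma_pk)
        else:
            vals.append(spec.sigma_pd)
    return np.log(np.asarray(vals, dtype=float))


def _log_bounds(free_names: Sequence[str]):
    out = []
    for name in free_names:
        key = name if name in _BOUNDS else ("om" if name.startswith("om_") else name)
        lo, hi = _BOUNDS[key]
        out.append((math.log(lo), math.log(hi)))
    return out


def _its_refine(
    session: "_FOCESession",
    spec: PopulationSpec,
    free_names: Sequence[str],
    max_sweeps: int = 40,
    tol: float = 0.1,
) -> tuple[PopulationSpec, float]:
    """Iterated two-stage (ITS) refinement of a population spec.

    The data likelihood depends on an eta-bearing parameter only through
    the individual values ``tv * exp(eta_i)``, so with the conditional
    modes held fixed the typical value profiles out exactly to the
    geometric mean of the individual values, and the EM update for a
    log-normal random effect sets the omega to the spread of the
    re-centred modes plus the mean posterior variance (from the Laplace
    Hessian).  Sweeping these closed-form updates walks straight down
    the tv/omega valleys where direction-set and gradient methods stall
    on mode-switching kinks, at roughly two deviance evaluations per
    sweep.  The deviance is re-checked after every sweep and the best
    spec seen is returned, so a sweep can never make the result worse.
    """
    free = set(free_names)
    best_val = session.neg2ll(spec, warm=False)
    best = spec
    if not session.eta_names:
        return best, best_val
    for _ in range(max_sweeps):
        predict = session._predict_fn(spec)
        var = session._var(spec)
        _, omega_inv, _ = session._omega(spec)
        eta_hat, _, _ = session._modes(spec, predict, var, omega_inv, warm=False)
        hess = _gn_hessian(predict, session.y, session.mask, var, omega_inv, eta_hat)
        pvar = np.diagonal(np.linalg.inv(hess), axis1=1, axis2=2)
        tv = dict(spec.tv)
        om = dict(spec.omega)
        for j, name in enumerate(session.eta_names):
            e = eta_hat[:, j]
            shift = float(np.mean(e)) if f"tv_{name}" in free else 0.0
            if f"tv_{name}" in free:
                lo, hi = _BOUNDS[f"tv_{name}"]
                tv[name] = float(np.clip(tv[name] * math.exp(shift), lo, hi))
            if f"om_{name}" in free:
                lo, hi = _BOUNDS["om"]
                om[name] = float(np.clip(np.mean((e - shift) ** 2 + pvar[:, j]), lo, hi))
        cand = spec.evolve(tv=tv, omega=om)
        val = session.neg2ll(cand, warm=False)
        if not math.isfinite(val):
            break
        improved = val < best_val - tol
        if val < best_val:
            best_val, best = val, cand
        if not improved:
            break
        spec = cand
    return best, best_val


def _run_fit(
    dataset: StudyDataset,
    init: PopulationSpec,
    stage: str,
    free_names: Sequence[str],
    pk_individual: pd.DataFrame | None,
    *,
    max_evals: int,
    ftol: float,
    xtol: float,
    hessian: str,
    compute_se: bool,
    n_starts: int,
    start_seed: int,
    two_stage_init: bool,
) -> FitResult:
    if two_stage_init:
        init = _two_stage_init(dataset, init, stage, free_names, pk_individual)
    session = _FOCESession(dataset, init, stage, pk_individual=pk_individual, hessian=hessian)
    bounds = _log_bounds(free_names)
    history: list[float] = []
    n_calls = [0]
    best = {"val": math.inf, "x": None}

    def objective(x: np.ndarray) -> float:
        n_calls[0] += 1
        spec_x = _apply_free(init, free_names, x)
        try:
            # cold inner starts only: the objective must be a pure function
            # of x, or Powell's line searches chase evaluation-order noise
            val = session.neg2ll(spec_x, warm=False)
        except (EstimationError, np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not math.isfinite(val):
            return 1e12
        if val < best["val"]:
            best["val"] = val
            best["x"] = np.array(x, dtype=float)
            history.append(val)
        return val

    x0_base = _free_x0(init, free_names)
    starts = [x0_base]
    if n_starts > 1:
        rng = np.random.default_rng(start_seed)
        for _ in range(n_starts - 1):
            # +/-30% log-perturbations of the supplied start
            starts.append(x0_base + rng.uniform(math.log(0.7), math.log(1.3), size=x0_base.size))
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    success = False
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)

        def its_pass(x: np.ndarray) -> np.ndarray:
            """ITS sweeps from x; folds any improvement into ``best``."""
            before = session.n_evaluations
            spec0 = _apply_free(init, free_names, x)
            refined, val = _its_refine(session, spec0, free_names)
            # a sweep costs roughly two deviance evaluations (modes +
            # Hessian, then the acceptance check); charge the budget
            n_calls[0] += 2 * (session.n_evaluations - before)
            if val < best["val"]:
                best["val"] = val
                best["x"] = np.clip(_free_x0(refined, free_names), lo, hi)
                history.append(val)
            return np.clip(best["x"], lo, hi) if best["x"] is not None else x

        # The deviance surface has diagonal tv/omega valleys whose floors
        # are kinked by per-subject mode switching, so direction-set and
        # gradient methods stall on them.  Each round therefore pairs the
        # closed-form ITS sweeps (which move along exactly those valleys)
        # with a Powell pass (which moves the parameters ITS cannot, e.g.
        # the residual SD and the no-eta fixed effects), repeating from
        # the best point seen until neither improves the deviance by 0.5.
        x0c = its_pass(x0c)
        for _round in range(6):
            remaining = max_evals - n_calls[0]
            if remaining <= len(free_names):
                break
            val_before = best["val"]
            res = minimize(
                objective,
                x0c,
                method="Powell",
                bounds=bounds,
                options={"maxfev": remaining, "ftol": ftol, "xtol": xtol},
            )
            success = bool(res.success)
            if max_evals - n_calls[0] > len(free_names) and best["x"] is not None:
                x0c = its_pass(np.clip(best["x"], lo, hi))
            if best["val"] < val_before - 0.5:
                x0c = np.clip(best["x"], lo, hi)  # restart from the best point seen
            else:
                break
    logger.info(
        "%s fit: best objective %.4f after %d evaluations (success=%s)",
        stage, best["val"], n_calls[0], success,
    )
    x_hat = best["x"] if best["x"] is not None else np.clip(x0_base, lo, hi)
    final = _apply_free(init, free_names, x_hat)
    # report a deterministic objective: the warm state is discarded, so
    # this value is a pure function of the final estimates and the data
    objective_final = session.neg2ll(final, warm=False)
    ebe = session.ebe(final)
    shrink = (
        eta_shrinkage(ebe, final.omega)
        if (len(ebe.columns) and len(ebe) >= 3)
        else {}
    )
    for name, value in shrink.items():
        if value > 0.5:
            logger.warning("eta-shrinkage for %s is %.2f (> 0.5): random effect poorly informed", name, value)
    se = _outer_se(session, init, free_names, x_hat) if compute_se else None
    return FitResult(
        estimates=final,
        stage=stage,
        ebe=ebe,
        objective=float(objective_final),
        converged=success and best["x"] is not None,
        n_evaluations=n_calls[0],
        shrinkage=shrink,
        objective_history=history,
        se=se,
        messages=[],
        context={},
    )


def _two_stage_init(
    dataset: StudyDataset,
    init: PopulationSpec,
    stage: str,
    free_names: Sequence[str],
    pk_individual: pd.DataFrame | None,
) -> PopulationSpec:
    """Standard two-stage initialisation before the mixed-effects run.

    Each subject's curve is fitted separately by least squares (log
    residuals for the proportional drug error, raw residuals for the
    additive glucose error); the typical values then start at the
    geometric means of the individual estimates, the omegas at the
    log-scale variances, and the residual SD at the pooled residual
    spread.  Per-subject curves identify the subject-level parameters
    directly, which puts the population start in the right basin even
    when the supplied initial estimates are far off.
    """
    free = set(free_names)
    if stage == "pk":
        fit_names = [p for p in ("ka", "v", "tlag", "cl2") if f"tv_{p}" in free]
    else:
        fit_names = [p for p in ("ke0", "gamma", "e0", "ic50") if f"tv_{p}" in free]
    if not fit_names:
        return init
    kind = "drug_conc" if stage == "pk" else "glucose"
    if stage == "pd":
        pk_individual = pk_individual.copy()
        pk_individual.index = pk_individual.index.astype(str)

    lo = np.array([math.log(_BOUNDS[f"tv_{p}"][0]) for p in fit_names])
    hi = np.array([math.log(_BOUNDS[f"tv_{p}"][1]) for p in fit_names])
    log_estimates: list[np.ndarray] = []
    resid_sq, resid_n = 0.0, 0
    for sid in dataset.subjects:
        sub = dataset.for_subject(sid)
        dose = float(sub.doses["amount"].iloc[0])
        t0 = float(sub.doses["time"].iloc[0])
        obs = sub.observations_of(kind).sort_values("time")
        if stage == "pk":
            obs = obs[(obs["time"] > t0) & ~obs["blq"]]
        t = obs["time"].to_numpy(dtype=float) - t0
        y = obs["value"].to_numpy(dtype=float)
        if t.size <= len(fit_names):
            continue
        hi_s = hi.copy()
        if "tlag" in fit_names:
            # keep the fitted lag below the first retained sample so the
            # prediction never collapses to all-zero (the lag cliff)
            j = fit_names.index("tlag")
            hi_s[j] = min(hi_s[j], math.log(max(0.95 * float(t.min()), 1e-4)))
        base = dict(init.tv)
        if stage == "pd":
            row = pk_individual.loc[str(sid)]
            base.update({k: float(row[k]) for k in PK_TV_NAMES})

        def residuals(x, t=t, y=y, base=base, hi_s=hi_s):
            p = dict(base)
            p.update({name: math.exp(val) for name, val in zip(fit_names, x)})
            with np.errstate(all="ignore"):
                if stage == "pk":
                    f = central_concentration(
                        t, dose, p["ka"], p["v"], p["v2"], p["cl"], p["cl2"], p["tlag"]
                    )
                    return np.log(y) - np.log(np.maximum(f, 1e-12))
                ce = effect_site_concentration(
                    t, dose, p["ka"], p["v"], p["v2"], p["cl"], p["cl2"], p["tlag"], p["ke0"]
                )
                f = p["e0"] * (1.0 - _sigmoid_fraction(np.maximum(ce, 0.0), p["ic50"], p["gamma"]))
                return y - f

        x0 = np.clip(np.log([init.tv[p] for p in fit_names]), lo + 1e-9, hi_s - 1e-9)
        starts = [x0]
        shift_name = "ka" if stage == "pk" else "ke0"
        if shift_name in fit_names:
            j = fit_names.index(shift_name)
            for delta in (math.log(3.0), -math.log(3.0)):
                alt = x0.copy()
                alt[j] = np.clip(alt[j] + delta, lo[j] + 1e-9, hi_s[j] - 1e-9)
                starts.append(alt)
        best = None
        for start in starts:
            try:
                res = least_squares(residuals, start, bounds=(lo, hi_s), max_nfev=200)
            except (ValueError, FloatingPointError):
                continue
            if np.all(np.isfinite(res.x)) and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            continue
        log_estimates.append(best.x)
        r = residuals(best.x)
        resid_sq += float(np.sum(r * r))
        resid_n += r.size
    if not log_estimates:
        logger.warning("two-stage initialisation failed for every subject; keeping supplied start")
        return init
    mat = np.array(log_estimates)
    tv = {name: float(math.exp(v)) for name, v in zip(fit_names, mat.mean(axis=0))}
    omega = {}
    if mat.shape[0] >= 3:
        for j, name in enumerate(fit_names):
            if f"om_{name}" in free:
                # the spread of individual estimates includes estimation
                # noise on top of the true variability (weakly identified
                # parameters such as the lag can inflate it severalfold),
                # so the starting omega is capped at 1.0 (~130% CV)
                omega[name] = float(np.clip(mat[:, j].var(ddof=1), 1e-4, 1.0))
    kwargs = {}
    if resid_n > len(fit_names):
        sd = math.sqrt(resid_sq / resid_n)
        if stage == "pk" and "sigma_pk" in free:
            kwargs["sigma_pk"] = float(np.clip(sd, 0.02, 1.0))
        elif stage == "pd" and "sigma_pd" in free:
            kwargs["sigma_pd"] = float(np.clip(sd, 1e-3, 5.0))
    out = init.evolve(tv=tv, omega=omega, **kwargs)
    logger.info(
        "two-stage %s initialisation from %d subjects: %s",
        stage, mat.shape[0], {k: round(v, 4) for k, v in tv.items()},
    )
    return out


def _outer_se(session, init, free_names, x_hat, h=1e-4):
    """Delta-method standard errors from a finite-difference outer Hessian."""
    k = len(free_names)

    def f(x):
        return session.neg2ll(_apply_free(init, free_names, x), warm=False)

    hess = np.empty((k, k))
    f0 = f(x_hat)
    units = np.eye(k) * h
    for i in range(k):
        fp, fm = f(x_hat + units[i]), f(x_hat - units[i])
        hess[i, i] = (fp - 2 * f0 + fm) / (h * h)
    for i in range(k):
        for j in range(i + 1, k):
            fpp = f(x_hat + units[i] + units[j])
            fpm = f(x_hat + units[i] - units[j])
            fmp = f(x_hat - units[i] + units[j])
            fmm = f(x_hat - units[i] - units[j])
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = 2.0 * np.linalg.inv(hess)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(k, np.nan)
    values = np.exp(np.asarray(x_hat, dtype=float))
    return {name: float(v * s) for name, v, s in zip(free_names, values, se_log)}


def fit_population_pk(
    dataset: StudyDataset,
    init: PopulationSpec,
    fixed: Sequence[str] = (),
    *,
    max_evals: int = 9000,
    ftol: float = 1e-8,
    xtol: float = 1e-6,
    hessian: str = "fd",
    compute_se: bool = False,
    n_starts: int = 1,
    start_seed: int = 0,
    two_stage_init: bool = True,
) -> FitResult:
    """FOCE fit of the population PK model to the drug concentrations.

    Free parameters: the six PK typical values, the omegas of the PK
    random effects active in ``init``, and the proportional residual
    SD — all on the log scale.  Entries of ``fixed`` (e.g. ``"tv_cl"``
    or ``"sigma_pk"``) are held at their ``init`` values.
    """
    free = [f"tv_{p}" for p in PK_TV_NAMES]
    free += [f"om_{p}" for p in init.random_effect_names(PK_ETA_POOL)]
    free += ["sigma_pk"]
    free = [f for f in free if f not in set(fixed)]
    return _run_fit(
        dataset, init, "pk", free, None,
        max_evals=max_evals, ftol=ftol, xtol=xtol, hessian=hessian,
        compute_se=compute_se, n_starts=n_starts, start_seed=start_seed,
        two_stage_init=two_stage_init,
    )


def fit_population_pd(
    dataset: StudyDataset,
    pk_fit: FitResult,
    init: PopulationSpec,
    fixed: Sequence[str] = (),
    *,
    max_evals: int = 6000,
    ftol: float = 1e-8,
    xtol: float = 1e-6,
    hessian: str = "fd",
    compute_se: bool = False,
    n_starts: int = 1,
    start_seed: int = 0,
    two_stage_init: bool = True,
) -> FitResult:
    """Sequential FOCE fit of the glucose model, PK fixed at the EBEs.

    Each subject's PK parameters are frozen at their empirical Bayes
    individual values from ``pk_fit`` (IPP strategy), so only the four
    PD typical values, the active PD omegas and the additive residual
    SD are estimated.
    """
    if not pk_fit.converged:
        raise EstimationError("PK fit did not converge; refusing to run the PD stage")
    pk_ind = individual_pk_parameters(pk_fit)
    base = init.evolve(
        tv={name: pk_fit.estimates.tv[name] for name in PK_TV_NAMES},
        omega={name: pk_fit.estimates.omega[name] for name in pk_fit.estimates.omega},
        sigma_pk=pk_fit.estimates.sigma_pk,
    )
    free = [f"tv_{p}" for p in PD_TV_NAMES]
    free += [f"om_{p}" for p in base.random_effect_names(PD_ETA_POOL)]
    free += ["sigma_pd"]
    free = [f for f in free if f not in set(fixed)]
    result = _run_fit(
        dataset, base, "pd", free, pk_ind,
        max_evals=max_evals, ftol=ftol, xtol=xtol, hessian=hessian,
        compute_se=compute_se, n_starts=n_starts, start_seed=start_seed,
        two_stage_init=two_stage_init,
    )
    result.context = {"pk_individual": pk_ind}
    # an IC50 fitted against zero effect-site exposure is meaningless
    session = _FOCESession(dataset, result.estimates, "pd", pk_individual=pk_ind)
    probe = session._predict_fn(result.estimates)
    probe(np.zeros((session.n, len(session.eta_names))))
    if session.predictor.max_ce_seen < 1e-2 * result.estimates.tv["ic50"]:
        result.messages.append(
            "ic50 not identifiable: effect-site exposure never exceeds 1% of the "
            "estimated ic50, so the data carry no information about it"
        )
    return result
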