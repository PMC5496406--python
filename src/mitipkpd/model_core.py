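"""Deterministic structural PK-PD model.

Pharmacokinetics: first-order oral absorption with a lag time into a
two-compartment disposition system, parameterised by clearances.  With
``Aa`` the depot amount, ``A1``/``A2`` the central/peripheral amounts,
``C = A1/V`` and ``C2 = A2/V2``:

    dAa/dt = -Ka * Aa
    dA1/dt =  Ka * Aa - CL * C - CL2 * (C - C2)
    dA2/dt =  CL2 * (C - C2)

Pharmacodynamics: a hypothetical effect compartment (biophase) whose
concentration ``Ce`` equilibrates with the central plasma concentration
at first-order rate ``Ke0`` and drives sigmoid inhibition of plasma
glucose ``E`` relative to the drug-free baseline ``E0``:

    dCe/dt = Ke0 * (C - Ce)
    E      = E0 * (1 - Ce^gamma / (IC50^gamma + Ce^gamma))

Units, package-wide: dose mg, volumes L, clearances L/h, time h, drug
concentration mg/L (identical to ug/mL), glucose mmol/L.

Because the PK system is linear, the central concentration has a
closed-form tri-exponential solution; the peripheral and effect
compartments are first-order "followers" of the central concentration
and are evaluated in closed form as well.  The closed-form path serves
both as a fast evaluation engine for population fitting and as an
independent oracle for the numeric ODE integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralPKParams",
    "StructuralPDParams",
    "SimulatedProfile",
    "DegenerateEigenvalueError",
    "IntegrationError",
    "derivatives",
    "inhibitory_effect",
    "simulate_profile",
    "analytic_central_conc",
    "central_concentration",
    "effect_site_concentration",
    "disposition_rates",
]


class DegenerateEigenvalueError(ValueError):
    """Absorption rate (nearly) coincides with a disposition eigenvalue.

    The standard partial-fraction coefficients of the tri-exponential
    solution are singular there; callers fall back to the numeric path.
    """


class IntegrationError(RuntimeError):
    """The adaptive ODE solver failed to converge."""


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class StructuralPKParams:
    """One individual's pharmacokinetic constants.

    ka : first-order absorption rate (1/h)
    v : central volume of distribution (L)
    v2 : peripheral volume of distribution (L)
    cl : elimination clearance from the central compartment (L/h)
    cl2 : inter-compartmental (distribution) clearance (L/h)
    tlag : absorption lag time (h)
    """

    ka: float
    v: float
    v2: float
    cl: float
    cl2: float
    tlag: float = 0.0

    def __post_init__(self) -> None:
        _check_positive(ka=self.ka, v=self.v, v2=self.v2)
        _check_nonnegative(cl=self.cl, cl2=self.cl2, tlag=self.tlag)

    @property
    def k10(self) -> float:
        return self.cl / self.v

    @property
    def k12(self) -> float:
        return self.cl2 / self.v

    @property
    def k21(self) -> float:
        return self.cl2 / self.v2


@dataclass(frozen=True)
class StructuralPDParams:
    """One individual's pharmacodynamic constants.

    ke0 : effect-compartment equilibration rate (1/h)
    ic50 : effect-site concentration at half-maximal inhibition (mg/L)
    gamma : Hill (sigmoidicity) exponent, dimensionless
    e0 : drug-free baseline plasma glucose (mmol/L)
    """

    ke0: float
    ic50: float
    gamma: float
    e0: float

    def __post_init__(self) -> None:
        _check_positive(ke0=self.ke0, ic50=self.ic50, gamma=self.gamma, e0=self.e0)


@dataclass(frozen=True)
class SimulatedProfile:
    """Dense trajectories of one individual after a single oral dose.

    Amounts in mg, concentrations mg/L, glucose mmol/L, time h.
    ``eliminated`` is the cumulative amount cleared from the central
    compartment, so ``aa + a1 + a2 + eliminated`` equals the dose.
    """

    times: np.ndarray
    aa: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    c: np.ndarray
    c2: np.ndarray
    ce: np.ndarray
    e: np.ndarray
    eliminated: np.ndarray

    def mass_balance_error(self, dose: float) -> np.ndarray:
        """Absolute deviation of ``aa + a1 + a2 + eliminated`` from the dose."""
        return np.abs(self.aa + self.a1 + self.a2 + self.eliminated - dose)


def derivatives(
    state: tuple[float, float, float, float],
    pk: StructuralPKParams,
    pd: StructuralPDParams,
) -> tuple[float, float, float, float]:
    """Right-hand side of the coupled PK / effect-compartment ODE system.

    ``state`` is ``(Aa, A1, A2, Ce)``; returns their time derivatives.
    """
    arr = np.asarray(state, dtype=float)
    if arr.shape != (4,) or not np.all(np.isfinite(arr)):
        raise ValueError("state must be four finite numbers (Aa, A1, A2, Ce)")
    aa, a1, a2, ce = arr
    c = a1 / pk.v
    c2 = a2 / pk.v2
    daa = -pk.ka * aa
    da1 = pk.ka * aa - pk.cl * c - pk.cl2 * (c - c2)
    da2 = pk.cl2 * (c - c2)
    dce = pd.ke0 * (c - ce)
    return (daa, da1, da2, dce)


def _sigmoid_fraction(ce, ic50, gamma):
    """Ce^g / (IC50^g + Ce^g), computed overflow-safely via the ratio r = Ce/IC50."""
    r = ce / ic50
    with np.errstate(over="ignore", invalid="ignore"):
        rg = np.power(r, gamma)
        upper = 1.0 / (1.0 + np.power(np.where(r > 0, r, 1.0), -gamma))
    frac = np.where(r > 1.0, upper, rg / (1.0 + rg))
    return np.where(r == 0.0, 0.0, frac)


def inhibitory_effect(ce, pd: StructuralPDParams):
    """Plasma glucose (mmol/L) at effect-site concentration ``ce`` (mg/L).

    Sigmoid inhibitory maximum-effect model with full (100%) maximal
    suppression: ``E = E0 * (1 - Ce^gamma / (IC50^gamma + Ce^gamma))``.
    Strictly decreasing in ``ce``; equals ``E0`` at ``ce = 0`` and
    ``E0/2`` at ``ce = IC50``.
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0) or not np.all(np.isfinite(ce_arr)):
        raise ValueError("effect-site concentration must be finite and >= 0")
    e = pd.e0 * (1.0 - _sigmoid_fraction(ce_arr, pd.ic50, pd.gamma))
    return float(e) if np.isscalar(ce) or ce_arr.ndim == 0 else e


# ---------------------------------------------------------------------------
# Closed-form engine (vectorised; used by fitting and as the numeric oracle)
# ---------------------------------------------------------------------------


def disposition_rates(cl, v, cl2, v2):
    """Disposition eigenvalues (alpha >= beta >= 0) of the two-compartment system.

    Roots of ``s^2 + (k10 + k12 + k21) s + k10 k21``; beta is computed
    from the product relation ``alpha * beta = k10 * k21`` to avoid
    cancellation when the roots are far apart.
    """
    cl = np.asarray(cl, dtype=float)
    k10 = cl / v
    k12 = np.asarray(cl2, dtype=float) / v
    k21 = np.asarray(cl2, dtype=float) / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    safe = np.where(alpha > 0, alpha, 1.0)
    beta = np.where(alpha > 0, k10 * k21 / safe, 0.0)
    return alpha, beta


def _separate(lam, min_rel=1e-7):
    """Nudge nearly coincident exponential rates apart (in place-safe copy).

    The partial-fraction coefficients blow up when two rates coincide;
    a relative perturbation of 1e-7 changes concentrations at the same
    order, far below fitting noise, and keeps the batch engine total.
    """
    lam = np.array(lam, dtype=float, copy=True)
    scale = np.maximum(np.max(lam, axis=-1, keepdims=True), 1e-12)
    for i in range(3):
        for j in range(i + 1, 3):
            close = np.abs(lam[..., i] - lam[..., j]) < min_rel * scale[..., 0]
            if np.any(close):
                lam[..., j] = np.where(
                    close, lam[..., j] * (1.0 + 10 * min_rel) + min_rel * scale[..., 0] * 1e-3, lam[..., j]
                )
    return lam


def _triexp_terms(dose, ka, v, v2, cl, cl2, *, on_degenerate="nudge"):
    """Rates and coefficients of ``C(tau) = sum_i coef_i * exp(-lam_i * tau)``.

    ``tau`` is time since end of lag.  Shapes broadcast; the returned
    arrays gain a trailing axis of length 3 (alpha, beta, ka terms).
    """
    alpha, beta = disposition_rates(cl, v, cl2, v2)
    ka_b, alpha, beta, v_b, v2_b, dose_b = np.broadcast_arrays(
        np.asarray(ka, float), alpha, beta, np.asarray(v, float), np.asarray(v2, float), np.asarray(dose, float)
    )
    lam = np.stack([alpha, beta, ka_b], axis=-1)
    scale = np.maximum(np.max(lam, axis=-1), 1e-12)
    min_sep = np.minimum(
        np.minimum(np.abs(ka_b - alpha), np.abs(ka_b - beta)), np.abs(alpha - beta)
    )
    if on_degenerate == "raise":
        if np.any(min_sep < 1e-8 * scale):
            raise DegenerateEigenvalueError(
                "absorption rate within 1e-8 (relative) of a disposition eigenvalue; "
                "use the numeric method"
            )
    else:
        lam = _separate(lam)
    a, b, k = lam[..., 0], lam[..., 1], lam[..., 2]
    k21 = np.asarray(cl2, float) / v2_b
    pref = dose_b * k / v_b
    c_a = (k21 - a) / ((k - a) * (b - a))
    c_b = (k21 - b) / ((k - b) * (a - b))
    c_k = (k21 - k) / ((a - k) * (b - k))
    coef = pref[..., None] * np.stack([c_a, c_b, c_k], axis=-1)
    return lam, coef


def _phi(x):
    """(1 - exp(-x)) / x, series-stabilised near zero; phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)


def _exp_sum(lam, coef, tau):
    """sum_i coef_i exp(-lam_i tau), zero for tau <= 0 (NaN-safe)."""
    tau_e = np.asarray(tau, float)[..., None]
    with np.errstate(invalid="ignore", over="ignore"):
        val = np.sum(coef * np.exp(-lam * np.maximum(tau_e, 0.0)), axis=-1)
    return np.where(np.asarray(tau, float) > 0, val, 0.0)


def _follower(lam, coef, rate, tau):
    """Concentration of a unit-gain first-order follower of the central profile.

    Solves ``dX/dt = rate * (C(tau) - X)``, ``X(0) = 0`` with
    ``C(tau) = sum coef exp(-lam tau)``.  Used for both the peripheral
    concentration (rate = k21) and the effect site (rate = Ke0); the
    near-degenerate case ``rate ~ lam_i`` uses a series form.
    """
    tau_a = np.maximum(np.asarray(tau, float), 0.0)
    tau_e = tau_a[..., None]
    rate_e = np.asarray(rate, float)[..., None]
    delta = rate_e - lam
    x = delta * tau_e
    small = np.abs(x) < 1e-6
    with np.errstate(invalid="ignore", over="ignore"):
        direct = (np.exp(-lam * tau_e) - np.exp(-rate_e * tau_e)) / np.where(small, 1.0, delta)
        series = tau_e * np.exp(-lam * tau_e) * (1.0 - x / 2.0 + x * x / 6.0)
        g = np.where(small, series, direct)
        out = np.asarray(rate, float) * np.sum(coef * g, axis=-1)
    return np.where(np.asarray(tau, float) > 0, out, 0.0)


def central_concentration(times, dose, ka, v, v2, cl, cl2, tlag):
    """Closed-form central concentration (mg/L); broadcasts over all inputs.

    Parameter arrays must be broadcastable against ``times`` (e.g. pass
    per-subject parameters with shape ``(n, 1)`` against a time matrix
    of shape ``(n, m)``).  Values are exactly zero at ``t <= tlag``.
    """
    lam, coef = _triexp_terms(dose, ka, v, v2, cl, cl2, on_degenerate="nudge")
    tau = np.asarray(times, float) - np.asarray(tlag, float)
    return _exp_sum(lam, coef, tau)


def effect_site_concentration(times, dose, ka, v, v2, cl, cl2, tlag, ke0):
    """Closed-form effect-site concentration driven by the central profile."""
    lam, coef = _triexp_terms(dose, ka, v, v2, cl, cl2, on_degenerate="nudge")
    tau = np.asarray(times, float) - np.asarray(tlag, float)
    return _follower(lam, coef, np.asarray(ke0, float), tau)


def analytic_central_conc(pk: StructuralPKParams, dose: float, t):
    """Tri-exponential central concentration of the lagged oral two-compartment model.

    Independent closed-form counterpart of the numeric integrator.
    Raises :class:`DegenerateEigenvalueError` when the absorption rate
    is within 1e-8 (relative) of a disposition eigenvalue, in which
    case the caller should use ``simulate_profile(..., method="numeric")``.
    """
    _check_nonnegative(dose=dose)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be >= 0")
    lam, coef = _triexp_terms(dose, pk.ka, pk.v, pk.v2, pk.cl, pk.cl2, on_degenerate="raise")
    out = _exp_sum(lam, coef, t_arr - pk.tlag)
    return float(out) if t_arr.ndim == 0 else out


def _analytic_profile(pk, pd, dose, times):
    lam, coef = _triexp_terms(dose, pk.ka, pk.v, pk.v2, pk.cl, pk.cl2, on_degenerate="raise")
    tau = times - pk.tlag
    tau_pos = np.maximum(tau, 0.0)
    c = _exp_sum(lam, coef, tau)
    c2 = _follower(lam, coef, np.asarray(pk.k21, float), tau)
    ce = _follower(lam, coef, np.asarray(pd.ke0, float), tau)
    aa = np.where(tau > 0, dose * np.exp(-pk.ka * tau_pos), np.where(tau == 0, dose, 0.0))
    # dose sits in the (virtual) depot throughout the lag interval
    aa = np.where(tau < 0, dose, aa)
    eliminated = pk.cl * tau_pos * np.sum(coef * _phi(lam * tau_pos[..., None]), axis=-1)
    return aa, pk.v * c, pk.v2 * c2, c, c2, ce, eliminated


def simulate_profile(
    pk: StructuralPKParams,
    pd: StructuralPDParams,
    dose: float,
    times,
    method: str = "numeric",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulatedProfile:
    """Simulate one individual's full trajectory after a single oral dose.

    The dose enters the depot at ``t = tlag`` (states are identically
    zero before the lag ends), which handles the lag exactly instead of
    approximating it with transit compartments.  ``method="numeric"``
    integrates the ODE system with an adaptive stiff-capable solver
    (LSODA, default rtol 1e-8 / atol 1e-10); ``method="analytic"``
    evaluates the closed-form solution and raises
    :class:`DegenerateEigenvalueError` on rate coincidence.
    """
    _check_nonnegative(dose=dose)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted and non-negative")

    if dose == 0.0:
        z = np.zeros_like(times)
        return SimulatedProfile(times, z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                                np.full_like(times, pd.e0), z.copy())

    if method == "analytic":
        aa, a1, a2, c, c2, ce, eliminated = _analytic_profile(pk, pd, dose, times)
    elif method == "numeric":
        aa, a1, a2, c, c2, ce, eliminated = _numeric_profile(pk, pd, dose, times, rtol, atol)
    else:
        raise ValueError(f"unknown method {method!r}")

    e = pd.e0 * (1.0 - _sigmoid_fraction(np.maximum(ce, 0.0), pd.ic50, pd.gamma))
    return SimulatedProfile(times, aa, a1, a2, c, c2, ce, e, eliminated)


def _numeric_profile(pk, pd, dose, times, rtol, atol):
    def rhs(_t, y):
        aa, a1, a2, ce, _elim = y
        c = a1 / pk.v
        c2 = a2 / pk.v2
        return [
            -pk.ka * aa,
            pk.ka * aa - pk.cl * c - pk.cl2 * (c - c2),
            pk.cl2 * (c - c2),
            pd.ke0 * (c - ce),
            pk.cl * c,
        ]

    n = times.size
    aa = np.where(times < pk.tlag, dose, 0.0)
    a1 = np.zeros(n)
    a2 = np.zeros(n)
    ce = np.zeros(n)
    eliminated = np.zeros(n)
    post = times > pk.tlag
    if np.any(post):
        t_eval = times[post]
        sol = solve_ivp(
            rhs,
            (pk.tlag, float(t_eval[-1])),
            [dose, 0.0, 0.0, 0.0, 0.0],
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        aa[post], a1[post], a2[post], ce[post], eliminated[post] = sol.y
    at_lag = times == pk.tlag
    aa[at_lag] = dose
    c = a1 / pk.v
    c2 = a2 / pk.v2
    return aa, a1, a2, c, c2, ce, eliminated
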