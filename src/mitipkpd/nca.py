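"""Non-compartmental analysis of single-dose concentration-time profiles.

Model-free PK summaries: Cmax/Tmax from the observed maximum, AUC by
trapezoidal accumulation (linear, or assay-standard linear-up/log-down),
terminal slope lambda_z by log-linear regression over the best
terminal window, and the derived quantities t1/2 = ln2/lambda_z,
AUC(0-inf) = AUC(0-t) + Clast/lambda_z, CL/F = dose/AUC(0-inf) and
Vd/F = CL/F / lambda_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NCAResult",
    "TerminalSlope",
    "terminal_slope",
    "auc_last",
    "nca_subject",
    "summarize_nca",
    "nca_study",
    "format_nca_summary",
]

#: quantities reported per subject, in publication order
NCA_QUANTITIES = (
    "t_half", "tmax", "cl_f", "vd_f", "cmax", "auc_last", "auc_inf", "pct_auc_ratio",
)


class TerminalSlope(NamedTuple):
    lambda_z: float
    r_squared: float
    n_points: int
    estimable: bool


@dataclass(frozen=True)
class NCAResult:
    """Per-subject non-compartmental quantities.

    Concentration units follow the input profile (mg/L here, so AUC is
    in mg*h/L); quantities that require lambda_z are NaN when the
    terminal slope is not estimable (``lambda_z_estimable`` False).
    """

    lambda_z: float
    t_half: float
    tmax: float
    cmax: float
    auc_last: float
    auc_inf: float
    pct_auc_ratio: float
    cl_f: float
    vd_f: float
    n_lambda_points: int
    r_squared: float
    lambda_z_estimable: bool


def _validate_profile(times, concs):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be 1-D and equal length")
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("concentrations must be finite and >= 0")
    return t, c


def terminal_slope(times, concs, min_points: int = 3) -> TerminalSlope:
    """Terminal elimination rate by log-linear regression.

    Candidate windows are the contiguous terminal runs of at least
    ``min_points`` positive concentrations strictly after Tmax; the
    window maximising adjusted R^2 wins, with ties (within 1e-4) broken
    in favour of more points.  A non-negative slope, or too few usable
    points, yields a flagged (non-estimable) result.
    """
    t, c = _validate_profile(times, concs)
    imax = int(np.argmax(c))
    idx = np.nonzero(c > 0)[0]
    idx = idx[idx > imax]
    if idx.size < min_points:
        return TerminalSlope(math.nan, math.nan, 0, False)
    best = None
    for start in range(idx.size - min_points + 1):
        sel = idx[start:]
        n = sel.size
        res = stats.linregress(t[sel], np.log(c[sel]))
        if not res.slope < 0:
            continue
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else -math.inf
        cand = (adj, n, -res.slope, r2)
        if best is None or adj > best[0] + 1e-4 or (abs(adj - best[0]) <= 1e-4 and n > best[1]):
            best = cand
    if best is None:
        return TerminalSlope(math.nan, math.nan, 0, False)
    adj, n, lam, r2 = best
    return TerminalSlope(float(lam), float(r2), int(n), True)


def _segment_auc(t0, t1, c0, c1, rule):
    dt = t1 - t0
    if rule == "linear" or c1 >= c0 or c1 <= 0 or c0 <= 0:
        return 0.5 * (c0 + c1) * dt
    # declining, both positive: log-trapezoid
    return (c0 - c1) * dt / math.log(c0 / c1)


def auc_last(times, concs, rule: str = "linuplogdown") -> float:
    """Area under the curve to the last positive concentration.

    ``rule``: ``"linear"`` for plain trapezoids, ``"linuplogdown"``
    (default) for linear on rising/flat segments and log-trapezoid on
    declining segments with positive endpoints.
    """
    if rule not in ("linear", "linuplogdown"):
        raise ValueError("rule must be 'linear' or 'linuplogdown'")
    t, c = _validate_profile(times, concs)
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        return 0.0
    last = pos[-1]
    total = 0.0
    for i in range(last):
        total += _segment_auc(t[i], t[i + 1], c[i], c[i + 1], rule)
    return total


def nca_subject(times, concs, dose: float, rule: str = "linuplogdown", min_points: int = 3) -> NCAResult:
    """Full per-subject NCA.

    Cmax/Tmax use the observed maximum (earliest time on ties).  When
    lambda_z is not estimable, the extrapolated quantities are NaN but
    AUC(0-t), Cmax and Tmax are still reported.
    """
    t, c = _validate_profile(times, concs)
    if not dose > 0:
        raise ValueError("dose must be > 0")
    imax = int(np.argmax(c))
    cmax = float(c[imax])
    tmax = float(t[imax])
    auc_t = auc_last(t, c, rule=rule)
    slope = terminal_slope(t, c, min_points=min_points)
    if slope.estimable:
        pos = np.nonzero(c > 0)[0]
        clast = float(c[pos[-1]])
        auc_inf = auc_t + clast / slope.lambda_z
        t_half = math.log(2.0) / slope.lambda_z
        cl_f = dose / auc_inf
        vd_f = cl_f / slope.lambda_z
        ratio = 100.0 * auc_t / auc_inf
    else:
        auc_inf = t_half = cl_f = vd_f = ratio = math.nan
    return NCAResult(
        lambda_z=slope.lambda_z,
        t_half=t_half,
        tmax=tmax,
        cmax=cmax,
        auc_last=auc_t,
        auc_inf=auc_inf,
        pct_auc_ratio=ratio,
        cl_f=cl_f,
        vd_f=vd_f,
        n_lambda_points=slope.n_points,
        r_squared=slope.r_squared,
        lambda_z_estimable=slope.estimable,
    )


def summarize_nca(results: Iterable[NCAResult]) -> pd.DataFrame:
    """Across-subject summary: mean +/- SD, plus median and range.

    By publication convention Tmax is summarised by its median and
    range; the mean/SD columns are still populated for completeness.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one NCA result")
    rows = {}
    for name in NCA_QUANTITIES + ("lambda_z",):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows[name] = dict(mean=math.nan, sd=math.nan, median=math.nan, min=math.nan, max=math.nan, n=0)
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows[name] = dict(
            mean=float(np.mean(vals)), sd=sd,
            median=float(np.median(vals)), min=float(np.min(vals)), max=float(np.max(vals)),
            n=int(vals.size),
        )
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "median", "min", "max", "n"]]


_LABELS = {
    "t_half": ("t1/2 (h)", 1.0),
    "tmax": ("Tmax (h)", 1.0),
    "cl_f": ("CL/F (L/h)", 1.0),
    "vd_f": ("Vd/F (L)", 1.0),
    "cmax": ("Cmax (ng/mL)", 1000.0),
    "auc_last": ("AUC0-t (ng/mL*h)", 1000.0),
    "auc_inf": ("AUC0-inf (ng/mL*h)", 1000.0),
    "pct_auc_ratio": ("AUC0-t/AUC0-inf (%)", 1.0),
}


def format_nca_summary(summary: pd.DataFrame) -> str:
    """Publication-style text table (concentrations echoed in ng/mL)."""
    lines = [f"{'Parameter':<22}{'Value'}"]
    for name, (label, scale) in _LABELS.items():
        row = summary.loc[name]
        if name == "tmax":
            txt = f"{row['median']:.2f} ({row['min']:.2f}-{row['max']:.2f})"
        else:
            txt = f"{row['mean'] * scale:.2f} +/- {row['sd'] * scale:.2f}"
        lines.append(f"{label:<22}{txt}")
    return "\n".join(lines)


def nca_study(dataset, rule: str = "linuplogdown", min_points: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run NCA for every subject of a study dataset.

    Below-limit drug observations are set to zero before the first
    positive concentration and dropped afterwards (standard handling).
    Returns (per-subject table, summary table).
    """
    per_subject = []
    for sid in dataset.subjects:
        sub = dataset.for_subject(sid)
        dose = float(sub.doses["amount"].sum())
        obs = sub.observations_of("drug_conc").sort_values("time")
        t = obs["time"].to_numpy(dtype=float)
        c = obs["value"].to_numpy(dtype=float)
        blq = obs["blq"].to_numpy(dtype=bool)
        first_pos = np.argmax((c > 0) & ~blq) if np.any((c > 0) & ~blq) else len(c)
        keep = np.ones(len(c), dtype=bool)
        c = c.copy()
        c[blq & (np.arange(len(c)) < first_pos)] = 0.0
        keep[blq & (np.arange(len(c)) >= first_pos)] = False
        res = nca_subject(t[keep], c[keep], dose, rule=rule, min_points=min_points)
        per_subject.append({"subject": sid, **res.__dict__})
    table = pd.DataFrame(per_subject)
    results = [NCAResult(**{k: row[k] for k in NCAResult.__dataclass_fields__}) for row in per_subject]
    return table, summarize_nca(results)
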