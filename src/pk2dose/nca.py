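"""Non-compartmental analysis of time–activity curves.

AUC and AUMC are computed with the log-linear trapezoidal rule: linear
trapezoids on rising or zero-touching segments, logarithmic trapezoids on
strictly decreasing positive segments. The terminal elimination rate λz is a
log-linear regression over the post-peak tail, with the number of points
chosen by maximising adjusted R² (ties broken toward more points). Derived
parameters follow the usual bolus identities:

    CL  = dose / AUC_0→∞          Vz  = CL / λz
    MRT = AUMC_0→∞ / AUC_0→∞      Vss = CL · MRT
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidInputError, TimeActivityCurve


class NotEstimableError(ValueError):
    """Raised when the terminal phase cannot be estimated from the data."""


@dataclass(frozen=True)
class NCAResult:
    """Bundle of non-compartmental PK parameters for one curve."""

    auc_0_t: float  # kBq·h/mL, observation span
    auc_0_inf: float  # kBq·h/mL, with extrapolated tail
    aumc_0_inf: float  # kBq·h²/mL
    lambda_z: float  # 1/h
    t_half: float  # h, biological
    cl: float  # mL/h
    vz: float  # mL
    vss: float  # mL
    mrt: float  # h
    n_terminal: int
    r2_adj: float

    @property
    def auc_extrapolated_percent(self) -> float:
        return 100.0 * (1.0 - self.auc_0_t / self.auc_0_inf)


def _validate_curve(times, conc) -> tuple:
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise InvalidInputError("need at least 2 points")
    if t.size != c.size:
        raise InvalidInputError("times and concentrations differ in length")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be strictly increasing")
    if not np.all(np.isfinite(c)):
        raise InvalidInputError("concentrations must be finite (no NaN)")
    if np.any(c < 0):
        raise InvalidInputError("concentrations must be >= 0")
    return t, c


def auc_linlog(times, conc) -> float:
    """Area under the curve by the log-linear trapezoidal method."""
    t, c = _validate_curve(times, conc)
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * (c1 + c2) / 2.0
    return total


def aumc_linlog(times, conc) -> float:
    """Area under the first-moment curve t·C(t), same segment rules as AUC.

    On a log segment C(t) = C1·e^{-k(t-t1)} with k = ln(C1/C2)/Δt the moment
    integral has the closed form (t1·C1 − t2·C2)/k + (C1 − C2)/k².
    """
    t, c = _validate_curve(times, conc)
    total = 0.0
    for i in range(t.size - 1):
        t1, t2 = t[i], t[i + 1]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            k = math.log(c1 / c2) / (t2 - t1)
            total += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            total += (t2 - t1) * (t1 * c1 + t2 * c2) / 2.0
    return total


def terminal_fit(times, conc, min_points: int = 3) -> tuple:
    """Estimate the terminal elimination rate λz.

    Log-linear regression over suffixes of the post-peak tail; the suffix with
    the highest adjusted R² (more points on ties) wins. Only candidates with a
    negative slope qualify.

    Returns ``(lambda_z, n_terminal, r2_adj)``.
    """
    t, c = _validate_curve(times, conc)
    i_max = int(np.argmax(c))
    # points strictly after the observed maximum, positive concentration only
    tail_idx = [i for i in range(i_max + 1, t.size) if c[i] > 0]
    if len(tail_idx) < min_points:
        raise NotEstimableError(
            f"need >= {min_points} positive post-peak points, have {len(tail_idx)}"
        )
    best = None
    for start in range(0, len(tail_idx) - min_points + 1):
        idx = tail_idx[start:]
        n = len(idx)
        x = t[idx]
        y = np.log(c[idx])
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        # prefer higher adjusted R², then more points
        key = (r2_adj, n)
        if best is None or key > best[0]:
            best = (key, -res.slope, n, r2_adj)
    if best is None:
        raise NotEstimableError("no decreasing terminal phase found")
    return best[1], best[2], best[3]


def nca_analyze(
    tac: TimeActivityCurve, dose: float, min_points: int = 3
) -> NCAResult:
    """Full non-compartmental analysis of one decay-corrected curve.

    The tail beyond the last observation is extrapolated monoexponentially:
    AUC tail = C_last/λz; AUMC tail = C_last·t_last/λz + C_last/λz².
    """
    if dose <= 0:
        raise InvalidInputError("dose must be > 0")
    if not tac.decay_corrected:
        raise InvalidInputError(
            "NCA expects a decay-corrected curve (biological kinetics)"
        )
    t, c = tac.t, tac.c
    lambda_z, n_terminal, r2_adj = terminal_fit(t, c, min_points=min_points)
    auc_0_t = auc_linlog(t, c)
    aumc_0_t = aumc_linlog(t, c)
    c_last, t_last = c[-1], t[-1]
    auc_0_inf = auc_0_t + c_last / lambda_z
    aumc_0_inf = aumc_0_t + c_last * t_last / lambda_z + c_last / lambda_z**2
    cl = dose / auc_0_inf
    mrt = aumc_0_inf / auc_0_inf
    return NCAResult(
        auc_0_t=auc_0_t,
        auc_0_inf=auc_0_inf,
        aumc_0_inf=aumc_0_inf,
        lambda_z=lambda_z,
        t_half=math.log(2) / lambda_z,
        cl=cl,
        vz=cl / lambda_z,
        vss=cl * mrt,
        mrt=mrt,
        n_terminal=n_terminal,
        r2_adj=r2_adj,
    )


_NCA_FIELDS = [
    "auc_0_t",
    "auc_0_inf",
    "aumc_0_inf",
    "lambda_z",
    "t_half",
    "cl",
    "vz",
    "vss",
    "mrt",
    "n_terminal",
    "r2_adj",
]


def nca_cohort(
    cohort, region: str, min_points: int = 3, on_not_estimable: str = "partial"
) -> pd.DataFrame:
    """Per-subject NCA for one region plus group mean/CV% summary rows.

    Sparse sampling can leave too few post-peak points for a terminal slope
    (late-peaking organs); with ``on_not_estimable='partial'`` (default) such
    curves keep their observed-span AUC/AUMC and get NaN for every
    extrapolated quantity, instead of failing the whole region. CV% uses the
    sample (n−1) standard deviation.
    """
    if on_not_estimable not in ("partial", "raise"):
        raise InvalidInputError("on_not_estimable must be 'partial' or 'raise'")
    rows = []
    for tac in cohort.curves(region):
        subj = cohort.subjects[tac.subject_id]
        row = {"subject_id": tac.subject_id, "group": subj.group, "region": region}
        try:
            res = nca_analyze(tac, subj.injected_kBq, min_points=min_points)
            row.update({f: getattr(res, f) for f in _NCA_FIELDS})
        except NotEstimableError:
            if on_not_estimable == "raise":
                raise
            row.update({f: np.nan for f in _NCA_FIELDS})
            row["auc_0_t"] = auc_linlog(tac.t, tac.c)
        rows.append(row)
    if not rows:
        raise InvalidInputError(f"no curves for region {region!r}")
    df = pd.DataFrame(rows)
    summaries = []
    for group, grp in df.groupby("group", sort=False):
        mean_row = {"subject_id": "__mean__", "group": group, "region": region}
        cv_row = {"subject_id": "__cv_percent__", "group": group, "region": region}
        for f in _NCA_FIELDS:
            vals = grp[f].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            mean_row[f] = float(np.mean(vals)) if vals.size else np.nan
            cv_row[f] = (
                100.0 * float(np.std(vals, ddof=1)) / float(np.mean(vals))
                if vals.size > 1 and np.mean(vals) != 0
                else np.nan
            )
        summaries.extend([mean_row, cv_row])
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
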