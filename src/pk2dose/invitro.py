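"""Radiolabel quality control: one-site binding affinity and Lindmo
immunoreactive fraction.

The saturation assay fits specific binding (total minus nonspecific,
subtracted point-wise) to the one-site hyperbola B = Bmax·[L]/(Kd + [L]).
The Lindmo assay extrapolates binding to infinite antigen excess: the
ratio applied/specifically-bound is regressed (ordinary least squares)
against the inverse cell concentration, and the immunoreactive fraction is
the reciprocal of the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import InvalidInputError

logger = logging.getLogger("pk2dose")


@dataclass(frozen=True)
class SaturationAssay:
    """Total and nonspecific bound counts over increasing ligand (nM)."""

    ligand_nM: tuple
    total_bound: tuple
    nonspecific_bound: tuple

    def __post_init__(self):
        L = np.asarray(self.ligand_nM, dtype=float)
        tb = np.asarray(self.total_bound, dtype=float)
        nsb = np.asarray(self.nonspecific_bound, dtype=float)
        if not (L.size == tb.size == nsb.size):
            raise InvalidInputError("assay columns differ in length")
        if np.any(L < 0):
            raise InvalidInputError("ligand concentrations must be >= 0")
        if L.size > 1 and not np.all(np.diff(L) > 0):
            raise InvalidInputError("ligand concentrations must be increasing")
        if np.any(tb < 0) or np.any(nsb < 0):
            raise InvalidInputError("counts must be >= 0")

    @property
    def specific(self) -> np.ndarray:
        return np.asarray(self.total_bound, float) - np.asarray(
            self.nonspecific_bound, float
        )


@dataclass(frozen=True)
class LindmoAssay:
    """Applied and specifically bound counts over increasing cell
    concentration (cells/mL) at constant tracer concentration."""

    cell_conc: tuple
    applied_counts: tuple
    specific_bound_counts: tuple

    def __post_init__(self):
        cells = np.asarray(self.cell_conc, dtype=float)
        app = np.asarray(self.applied_counts, dtype=float)
        spec = np.asarray(self.specific_bound_counts, dtype=float)
        if not (cells.size == app.size == spec.size):
            raise InvalidInputError("assay columns differ in length")
        if np.any(cells <= 0):
            raise InvalidInputError("cell concentrations must be > 0")
        if cells.size > 1 and not np.all(np.diff(cells) > 0):
            raise InvalidInputError("cell concentrations must be increasing")
        if np.any(app <= 0):
            raise InvalidInputError("applied counts must be > 0")
        if np.any(spec < 0) or np.any(spec > app):
            raise InvalidInputError("specific bound must be in [0, applied]")


def one_site(L, bmax, kd):
    L = np.asarray(L, dtype=float)
    return bmax * L / (kd + L)


def fit_one_site(assay: SaturationAssay) -> tuple:
    """Fit Kd (nM) and Bmax to specific binding; returns (kd, bmax, r2).

    Degenerate, non-saturating data (optimum pinned at the bounds) raises a
    non-identifiability error.
    """
    L = np.asarray(assay.ligand_nM, dtype=float)
    y = assay.specific
    if np.unique(L).size < 3:
        raise InvalidInputError("need >= 3 distinct ligand concentrations")
    bmax0 = max(float(np.max(y)), 1e-9)
    kd0 = float(L[np.argmin(np.abs(y - bmax0 / 2.0))]) or float(np.median(L[L > 0]))
    lo, hi = 1e-12, 1e12
    try:
        popt, _ = optimize.curve_fit(
            one_site,
            L,
            y,
            p0=[bmax0, kd0],
            bounds=([lo, lo], [hi, hi]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise InvalidInputError(f"one-site fit did not converge: {exc}") from exc
    bmax, kd = popt
    if kd <= lo * 10 or kd > 100.0 * float(L.max()) or bmax >= hi / 10:
        # a Kd far beyond the covered concentration range means the data
        # never approach saturation and Bmax/Kd are only jointly determined
        raise InvalidInputError(
            "one-site fit non-identifiable: data do not saturate over the "
            f"covered ligand range (Kd estimate {kd:.3g} nM)"
        )
    resid = y - one_site(L, bmax, kd)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(kd), float(bmax), r2


def lindmo_ir(assay: LindmoAssay) -> tuple:
    """Immunoreactive fraction by Lindmo extrapolation.

    OLS fit of applied/specific vs 1/cells; IR = 1/intercept, clipped into
    (0, 1] with a warning when the intercept falls below 1 (which would imply
    IR > 100%). Returns (ir, r2).
    """
    cells = np.asarray(assay.cell_conc, dtype=float)
    app = np.asarray(assay.applied_counts, dtype=float)
    spec = np.asarray(assay.specific_bound_counts, dtype=float)
    if np.any(spec <= 0):
        raise InvalidInputError("zero specific binding; cannot form applied/bound")
    if np.unique(cells).size < 2:
        raise InvalidInputError("need >= 2 distinct cell concentrations")
    x = 1.0 / cells
    y = app / spec
    res = stats.linregress(x, y)
    intercept = res.intercept
    if intercept <= 0:
        raise InvalidInputError(
            f"non-positive Lindmo intercept ({intercept:.3g}); extrapolation invalid"
        )
    ir = 1.0 / intercept
    if ir > 1.0:
        logger.warning(
            "Lindmo intercept %.4f < 1 implies IR %.1f%% > 100%%; clipping to 1",
            intercept,
            100 * ir,
        )
        ir = 1.0
    return float(ir), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_binding_table(source) -> SaturationAssay:
    """binding.csv: ligand_nM,total_counts,nonspecific_counts (duplicate
    ligand rows are averaged as replicates)."""
    df = pd.read_csv(source)
    for col in ("ligand_nM", "total_counts", "nonspecific_counts"):
        if col not in df.columns:
            raise InvalidInputError(f"binding table: missing column {col!r}")
    g = df.groupby("ligand_nM", sort=True).mean(numeric_only=True).reset_index()
    return SaturationAssay(
        ligand_nM=tuple(g["ligand_nM"]),
        total_bound=tuple(g["total_counts"]),
        nonspecific_bound=tuple(g["nonspecific_counts"]),
    )


def read_lindmo_table(source) -> LindmoAssay:
    """lindmo.csv: cells_per_mL,applied_counts,specific_counts (replicate
    rows averaged)."""
    df = pd.read_csv(source)
    for col in ("cells_per_mL", "applied_counts", "specific_counts"):
        if col not in df.columns:
            raise InvalidInputError(f"lindmo table: missing column {col!r}")
    g = df.groupby("cells_per_mL", sort=True).mean(numeric_only=True).reset_index()
    return LindmoAssay(
        cell_conc=tuple(g["cells_per_mL"]),
        applied_counts=tuple(g["applied_counts"]),
        specific_bound_counts=tuple(g["specific_counts"]),
    )
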