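"""Synthetic cohorts, phantoms and dosimetry fixtures.

The generator emulates the study design the analysis chain assumes: groups
of 7 mice (~25 g) injected with ~742 kBq of a ⁸⁹Zr-labelled antibody and
sampled at 1, 3, 24, 48, 72 and 168 h. Blood follows a two-compartment bolus
model, organs a one-compartment uptake/elimination model; inter-individual
variability is lognormal on every parameter and residual error has SD
a + b·C. Default typical values are back-calculated from the healthy-group
summary statistics the chain is meant to reproduce (blood: dose 742.3 kBq,
AUC∞ 6935.9 kBq·h/mL hence CL 0.107 mL/h, MRT 36.7 h hence Vss 3.93 mL,
terminal half-life 28.7 h; organ volumes matched to the reported per-organ
AUC₀₋₁₆₈ values). All outputs are deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .allometry import OrganMassTable
from .compartmental import (
    ErrorModel,
    OneCmtParams,
    TwoCmtParams,
    conc_model,
)
from .core import (
    Cohort,
    InvalidInputError,
    Radionuclide,
    Subject,
    TimeActivityCurve,
    ZR89,
    logger,
)
from .dosimetry import SValueMatrix, TissueWeights
from .voiquant import LabelMask, VoxelVolume

#: Nominal sampling schedule (h post-injection).
DEFAULT_SAMPLE_TIMES_H = (1.0, 3.0, 24.0, 48.0, 72.0, 168.0)

#: Blood two-compartment typicals consistent with the healthy-group summary
#: (CL = 742.3/6935.9 mL/h; V1 + V2 = CL·MRT; Q solved so the terminal
#: half-life is 28.7 h).
DEFAULT_BLOOD_PARAMS = TwoCmtParams(
    cl=0.107023, v1=2.0, v2=1.927740, q=0.224784
)

#: Organ one-compartment typicals; volumes solved so the model AUC₀₋₁₆₈ at a
#: 742.3 kBq dose matches the reported compartmental estimates (heart 1160,
#: lung 365, kidney 837, liver 2026, bone 12619 kBq·h/mL).
DEFAULT_ORGAN_PARAMS = {
    "heart": OneCmtParams(ka=0.30, ke=0.020, v=30.805),
    "lung": OneCmtParams(ka=0.30, ke=0.020, v=97.901),
    "kidney": OneCmtParams(ka=0.30, ke=0.015, v=54.116),
    "liver": OneCmtParams(ka=0.30, ke=0.010, v=29.575),
    "bone": OneCmtParams(ka=0.05, ke=0.002, v=7.518),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation settings; the defaults are the study conditions."""

    n_subjects: int = 7
    group: str = "healthy"
    sample_times_h: tuple = DEFAULT_SAMPLE_TIMES_H
    blood: TwoCmtParams = DEFAULT_BLOOD_PARAMS
    blood_iiv_cv: float = 5.0  # lognormal CV% on every blood parameter
    organs: dict = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_PARAMS)
    )
    organ_iiv_cv: float = 10.0
    error: ErrorModel = ErrorModel("constant", a=2.0, b=0.0)
    nuclide: Radionuclide = ZR89
    apply_physical_decay: bool = False
    typical_body_mass_g: float = 25.0
    body_mass_cv: float = 2.8
    typical_injected_kBq: float = 742.3
    injected_cv: float = 5.1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        t = np.asarray(self.sample_times_h, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")
        for cv in (self.blood_iiv_cv, self.organ_iiv_cv, self.body_mass_cv, self.injected_cv):
            if cv < 0:
                raise InvalidInputError("CV values must be >= 0")


def _lognormal_factor(rng, cv_percent: float) -> float:
    if cv_percent == 0:
        return 1.0
    sd = math.sqrt(math.log1p((cv_percent / 100.0) ** 2))
    return math.exp(rng.normal(0.0, sd))


def _perturb(params, rng, cv_percent: float):
    vals = {n: getattr(params, n) * _lognormal_factor(rng, cv_percent) for n in params.names}
    return replace(params, **vals)


def simulate_cohort(cfg: SimulationConfig = SimulationConfig()) -> Cohort:
    """Simulate one cohort: subjects plus blood and organ curves.

    Per subject, parameters are drawn lognormally around the typical values,
    the analytic model curves are evaluated at the sampling times, and
    residual noise with SD a + b·C is added (negative draws truncated at 0,
    with a logged count). When ``apply_physical_decay`` is set the curves are
    multiplied by e^{−λ_phys t} before noise and flagged as not
    decay-corrected.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.sample_times_h, dtype=float)
    cohort = Cohort()
    n_truncated = 0
    for i in range(cfg.n_subjects):
        sid = f"{cfg.group[0]}{i + 1:02d}"
        subject = Subject(
            id=sid,
            group=cfg.group,
            body_mass_g=cfg.typical_body_mass_g * _lognormal_factor(rng, cfg.body_mass_cv),
            injected_kBq=cfg.typical_injected_kBq * _lognormal_factor(rng, cfg.injected_cv),
        )
        cohort.subjects[sid] = subject
        curves = {"blood": _perturb(cfg.blood, rng, cfg.blood_iiv_cv)}
        for region, p in cfg.organs.items():
            curves[region] = _perturb(p, rng, cfg.organ_iiv_cv)
        for region, p in curves.items():
            pred = np.asarray(conc_model(times, p, subject.injected_kBq), dtype=float)
            if cfg.apply_physical_decay:
                pred = pred * np.exp(-cfg.nuclide.decay_constant_h * times)
            noisy = pred + rng.normal(0.0, 1.0, times.size) * cfg.error.sd(pred)
            n_truncated += int(np.sum(noisy < 0))
            noisy = np.maximum(noisy, 0.0)
            cohort.tacs.append(
                TimeActivityCurve(
                    subject_id=sid,
                    region=region,
                    times_h=tuple(times),
                    conc_kBq_per_mL=tuple(noisy),
                    decay_corrected=not cfg.apply_physical_decay,
                )
            )
    if n_truncated:
        logger.info("simulate_cohort: truncated %d negative concentrations to 0", n_truncated)
    return cohort


# ---------------------------------------------------------------------------
# Phantom generator
# ---------------------------------------------------------------------------


def simulate_phantom(
    organ_spec,
    grid_shape=(120, 120, 120),
    voxel_um: float = 251.0,
    noise_cv_percent: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Build a piecewise-constant ellipsoid phantom plus its label mask.

    ``organ_spec`` is a list of (region, center_mm (x,y,z), semi_axes_mm
    (a,b,c), conc_kBq_per_mL). Later entries overwrite earlier ones where
    ellipsoids overlap. Multiplicative Gaussian noise with the given CV is
    applied voxel-wise.

    Returns (VoxelVolume, LabelMask).
    """
    voxel_mm = voxel_um / 1000.0
    vol = np.zeros(grid_shape, dtype=float)
    labels = np.zeros(grid_shape, dtype=np.int32)
    region_names: dict = {}
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * voxel_mm for n in grid_shape], indexing="ij"
    )
    for lab, (region, center, axes, conc) in enumerate(organ_spec, start=1):
        if conc < 0:
            raise InvalidInputError(f"negative concentration for {region!r}")
        for c_mm, ax_mm, n in zip(center, axes, grid_shape):
            if c_mm - ax_mm < 0 or c_mm + ax_mm > n * voxel_mm:
                raise InvalidInputError(f"ellipsoid {region!r} outside the grid")
        dist = sum(
            ((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)
        )
        inside = dist <= 1.0
        vol[inside] = conc
        labels[inside] = lab
        region_names[lab] = region
    if noise_cv_percent > 0:
        rng = np.random.default_rng(seed)
        vol = vol * (1.0 + rng.normal(0.0, noise_cv_percent / 100.0, vol.shape))
        vol = np.maximum(vol, 0.0)
    return (
        VoxelVolume(data=vol, voxel_size_mm=(voxel_mm,) * 3),
        LabelMask(labels=labels, region_names=region_names),
    )


# ---------------------------------------------------------------------------
# Dosimetry fixtures
# ---------------------------------------------------------------------------


def fixture_svalues(regions, seed: int = 0) -> SValueMatrix:
    """Synthetic square S-value matrix over the given regions.

    Positive everywhere with the self-dose (diagonal) dominating every
    cross-dose in its column, as real photon/electron S-value tables do.
    """
    regions = list(regions)
    if not regions:
        raise InvalidInputError("need at least one region")
    rng = np.random.default_rng(seed)
    n = len(regions)
    mat = rng.uniform(0.001, 0.01, size=(n, n))
    diag = rng.uniform(0.05, 0.3, size=n)
    mat[np.arange(n), np.arange(n)] = diag
    return SValueMatrix(sources=regions, targets=list(regions), s=mat)


def fixture_weights(regions, rest_region: str = "rest_of_body") -> TissueWeights:
    """Tissue weights over exactly the available target regions.

    ICRP-103 factors are kept for the organs that have one (lung 0.12,
    liver 0.04, bone 0.01 as bone surface); all remaining weight goes to the
    pooled rest-of-body target, and any organs without a factor share the
    remainder weight equally with it.
    """
    regions = list(regions)
    named = {"lung": 0.12, "liver": 0.04, "bone": 0.01}
    w = {r: named[r] for r in regions if r in named}
    leftover_regions = [r for r in regions if r not in named]
    if not leftover_regions:
        raise InvalidInputError(f"need a {rest_region!r} or unweighted region to absorb the remainder weight")
    share = (1.0 - sum(w.values())) / len(leftover_regions)
    for r in leftover_regions:
        w[r] = share
    return TissueWeights(w=w)


def fixture_masses() -> tuple:
    """(mouse, human) organ-mass tables bundled with the package.

    Nominal C57BL/6 and ICRP-adult-male-style reference values shipped as an
    editable CSV; intended as defaults when no measured masses are supplied.
    """
    from importlib.resources import files

    from .allometry import read_mass_table

    path = files("pk2dose.data") / "reference_masses.csv"
    mouse = read_mass_table(path, "mouse_c57bl6")
    human = read_mass_table(path, "human_adult_male")
    return mouse, human


def default_mouse_masses() -> OrganMassTable:
    logger.warning(
        "using bundled nominal C57BL/6 organ masses; supply measured masses "
        "when available"
    )
    return fixture_masses()[0]


# ---------------------------------------------------------------------------
# In vitro assay generators
# ---------------------------------------------------------------------------


def simulate_saturation_assay(
    kd_nM: float = 5.6,
    bmax: float = 10000.0,
    ligand_nM=(2.5, 5, 10, 20, 40, 70, 100),
    nsb_fraction: float = 0.05,
    noise_cv_percent: float = 0.0,
    seed: int = 0,
):
    """One-site saturation assay with linear nonspecific binding."""
    from .invitro import SaturationAssay, one_site

    rng = np.random.default_rng(seed)
    L = np.asarray(ligand_nM, dtype=float)
    spec = one_site(L, bmax, kd_nM)
    nsb = nsb_fraction * bmax * L / max(L.max(), 1.0)
    if noise_cv_percent > 0:
        spec = spec * (1.0 + rng.normal(0.0, noise_cv_percent / 100.0, L.size))
    return SaturationAssay(
        ligand_nM=tuple(L),
        total_bound=tuple(np.maximum(spec + nsb, 0.0)),
        nonspecific_bound=tuple(nsb),
    )


def simulate_lindmo_assay(
    ir: float = 0.96,
    affinity_per_cell: float = 2.0e-6,
    cell_conc=(0.125e6, 0.25e6, 0.5e6, 0.75e6, 1.0e6, 1.5e6),
    applied_counts: float = 1.0e5,
    noise_cv_percent: float = 0.0,
    seed: int = 0,
):
    """Lindmo assay: applied/bound = (1 + 1/(K·cells))/IR for cell-driven
    binding with immunoreactive fraction ``ir``."""
    from .invitro import LindmoAssay

    if not (0 < ir <= 1):
        raise InvalidInputError("ir must be in (0, 1]")
    rng = np.random.default_rng(seed)
    cells = np.asarray(cell_conc, dtype=float)
    ratio = (1.0 + 1.0 / (affinity_per_cell * cells)) / ir
    bound = applied_counts / ratio
    if noise_cv_percent > 0:
        bound = bound * (1.0 + rng.normal(0.0, noise_cv_percent / 100.0, cells.size))
    bound = np.clip(bound, 1e-9, applied_counts)
    return LindmoAssay(
        cell_conc=tuple(cells),
        applied_counts=tuple(np.full(cells.size, applied_counts)),
        specific_bound_counts=tuple(bound),
    )
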