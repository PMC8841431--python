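"""End-to-end orchestration: TACs → NCA → compartmental fits → cumulated
activity → allometric scaling → MIRD/ICRP-103 dose report.

Each stage writes its artifact (nca.csv, fits.csv, rmse.csv,
residence_human.csv, report.json) into the output directory; the JSON report
carries provenance (config hash, seed, package version). Deterministic
stages are bit-stable on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import (
    OrganMassTable,
    ResidenceTimeTable,
    read_mass_table,
    residence_time,
    rest_of_body_residence,
    scale_residence_table,
    whole_body_residence_time,
)
from .compartmental import auc_ca, fit_subject, rmse_percent, two_stage_population
from .core import (
    Cohort,
    InvalidInputError,
    Radionuclide,
    TimeActivityCurve,
    ZR89,
    decay_correct,
    read_tac_table,
)
from .dosimetry import (
    DoseReport,
    SValueMatrix,
    TissueWeights,
    absorbed_doses,
    cohort_dose_summary,
    effective_dose,
    read_svalue_table,
    read_weight_table,
    write_dose_report,
)
from .nca import nca_cohort

logger = logging.getLogger("pk2dose")

REST_OF_BODY = "rest_of_body"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class PipelineConfig:
    """File paths and modelling choices for one pipeline run."""

    tacs: str
    subjects: str
    masses: str
    svalues: str
    weights: str
    out_dir: str
    blood_region: str = "blood"
    organ_regions: tuple = ("heart", "lung", "kidney", "liver", "bone")
    error_model: str = "constant"
    animal_species: str = "mouse_c57bl6"
    human_species: str = "human_adult_male"
    nuclide_name: str = "Zr-89"
    nuclide_half_life_h: float = 78.4
    n_starts: int = 10
    seed: int = 0
    density_g_per_mL: float = 1.0

    @property
    def nuclide(self) -> Radionuclide:
        return Radionuclide(self.nuclide_name, self.nuclide_half_life_h)

    def digest(self) -> str:
        # out_dir does not influence any computed number
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "organ_regions" in raw:
            raw["organ_regions"] = tuple(raw["organ_regions"])
        return cls(**raw)


def ensure_decay_corrected(tac: TimeActivityCurve, nuclide: Radionuclide) -> TimeActivityCurve:
    """Return a decay-corrected copy of the curve (identity when already
    corrected)."""
    if tac.decay_corrected:
        return tac
    corrected = decay_correct(tac.c, tac.t, nuclide)
    return TimeActivityCurve(
        subject_id=tac.subject_id,
        region=tac.region,
        times_h=tac.times_h,
        conc_kBq_per_mL=tuple(np.asarray(corrected, dtype=float)),
        decay_corrected=True,
    )


def subject_residence_table(
    organ_fits: dict,
    dose_kBq: float,
    nuclide: Radionuclide,
    animal_masses: OrganMassTable,
    density_g_per_mL: float = 1.0,
) -> ResidenceTimeTable:
    """Animal-scale residence-time table from per-organ 1-CMT fits.

    Whole-body retention of a large antibody over the ⁸⁹Zr time scale is
    taken as complete, so the whole-body residence time is the decay-only
    integral 1/λ; the rest-of-body entry is whole body minus the quantified
    organs.
    """
    taus = {}
    for region, fit in organ_fits.items():
        if region not in animal_masses.organ_kg:
            raise PipelineError(f"allometry: no {animal_masses.species} mass for region {region!r}")
        taus[region] = residence_time(
            fit.params,
            dose_kBq,
            nuclide,
            region_mass_g=animal_masses[region] * 1000.0,
            density_g_per_mL=density_g_per_mL,
        )
    wb = whole_body_residence_time(nuclide)
    taus[REST_OF_BODY] = rest_of_body_residence(wb, taus.values())
    return ResidenceTimeTable(taus_h=taus, scale="animal")


def run_pipeline(
    cfg: PipelineConfig,
    cohort: Cohort | None = None,
    svalues: SValueMatrix | None = None,
    weights: TissueWeights | None = None,
) -> DoseReport:
    """Execute the full chain and write every artifact under cfg.out_dir.

    ``cohort``/``svalues``/``weights`` may be passed in-memory (e.g. straight
    from the synthetic generator); otherwise they are read from the
    configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nuclide = cfg.nuclide

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # -- core: load inputs ---------------------------------------------------
    _stage("core")
    try:
        if cohort is None:
            cohort = read_tac_table(cfg.tacs, cfg.subjects)
        animal_masses = read_mass_table(cfg.masses, cfg.animal_species)
        human_masses = read_mass_table(cfg.masses, cfg.human_species)
        if svalues is None:
            svalues = read_svalue_table(cfg.svalues)
        if weights is None:
            weights = read_weight_table(cfg.weights)
    except (InvalidInputError, FileNotFoundError, OSError) as exc:
        raise PipelineError(f"core: {exc}") from exc

    regions = (cfg.blood_region,) + tuple(cfg.organ_regions)
    corrected = Cohort(subjects=cohort.subjects)
    for tac in cohort.tacs:
        if tac.region in regions:
            corrected.tacs.append(ensure_decay_corrected(tac, nuclide))
    cohort = corrected

    # every residence-table region must resolve to an S-value source up front
    for region in tuple(cfg.organ_regions) + (REST_OF_BODY,):
        try:
            svalues.source_index(region)
        except InvalidInputError as exc:
            raise PipelineError(f"dosimetry: {exc}") from exc

    # -- nca ------------------------------------------------------------------
    _stage("nca")
    nca_frames = []
    for region in regions:
        try:
            nca_frames.append(nca_cohort(cohort, region))
        except Exception as exc:
            raise PipelineError(f"nca: region {region!r}: {exc}") from exc
    nca_df = pd.concat(nca_frames, ignore_index=True)
    nca_df.to_csv(out / "nca.csv", index=False)

    # -- compartmental --------------------------------------------------------
    _stage("compartmental")
    fit_rows = []
    organ_fits: dict = {}  # subject -> region -> FitResult
    blood_fit_results = []
    for si, (sid, subject) in enumerate(sorted(cohort.subjects.items())):
        organ_fits[sid] = {}
        for ri, region in enumerate(regions):
            model = "2cmt" if region == cfg.blood_region else "1cmt"
            try:
                tac = cohort.curve(sid, region)
            except KeyError as exc:
                raise PipelineError(f"compartmental: {exc}") from exc
            fit = fit_subject(
                tac,
                model=model,
                error=cfg.error_model,
                dose=subject.injected_kBq,
                n_starts=cfg.n_starts,
                seed=cfg.seed + 1000 * si + ri,
            )
            if not fit.converged:
                raise PipelineError(
                    f"compartmental: no convergence for subject {sid!r} region {region!r}"
                )
            if region != cfg.blood_region:
                organ_fits[sid][region] = fit
            else:
                blood_fit_results.append(fit)
            row = {
                "subject_id": sid,
                "region": region,
                "model": model,
                "objective": fit.objective,
                "converged": fit.converged,
                "error_a": fit.error.a,
                "error_b": fit.error.b,
            }
            for name in fit.params.names:
                row[name] = getattr(fit.params, name)
                row[f"rse_{name}_percent"] = fit.rse_percent.get(name, np.nan)
            row["auc_0_168"] = auc_ca(fit.params, subject.injected_kBq, 168.0)
            row["auc_0_inf"] = auc_ca(fit.params, subject.injected_kBq)
            fit_rows.append(row)
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(out / "fits.csv", index=False)

    # CA-vs-NCA adequacy per organ
    rmse_rows = []
    per_subject_nca = nca_df[~nca_df["subject_id"].str.startswith("__")]
    for region in cfg.organ_regions:
        sub = per_subject_nca[per_subject_nca["region"] == region].set_index("subject_id")
        ca = fits_df[(fits_df["region"] == region)].set_index("subject_id")["auc_0_168"]
        common = sorted(set(sub.index) & set(ca.index))
        rmse_rows.append(
            {
                "region": region,
                "nca_auc_0_168_mean": float(sub.loc[common, "auc_0_t"].mean()),
                "ca_auc_0_168_mean": float(ca.loc[common].mean()),
                "rmse_percent": rmse_percent(
                    ca.loc[common].to_numpy(), sub.loc[common, "auc_0_t"].to_numpy()
                ),
            }
        )
    pd.DataFrame(rmse_rows).to_csv(out / "rmse.csv", index=False)

    # -- allometry ------------------------------------------------------------
    _stage("allometry")
    human_tables: dict = {}
    for sid, fits in organ_fits.items():
        dose = cohort.subjects[sid].injected_kBq
        try:
            animal_tau = subject_residence_table(
                fits, dose, nuclide, animal_masses, cfg.density_g_per_mL
            )
            human_tables[sid] = scale_residence_table(
                animal_tau, animal_masses, human_masses, REST_OF_BODY
            )
        except InvalidInputError as exc:
            raise PipelineError(f"allometry: subject {sid!r}: {exc}") from exc
    res_rows = []
    for sid, table in human_tables.items():
        for region, tau in table.items():
            res_rows.append({"subject_id": sid, "region": region, "residence_time_h": tau})
    pd.DataFrame(res_rows).to_csv(out / "residence_human.csv", index=False)

    # -- dosimetry ------------------------------------------------------------
    _stage("dosimetry")
    reports = []
    for sid, table in human_tables.items():
        try:
            doses = absorbed_doses(table, svalues)
            e = effective_dose(doses, weights)
        except InvalidInputError as exc:
            raise PipelineError(f"dosimetry: subject {sid!r}: {exc}") from exc
        reports.append(DoseReport(absorbed_mGy_per_MBq=doses, effective_mSv_per_MBq=e))
    summary = cohort_dose_summary(reports)
    provenance = {
        "config_sha256_16": cfg.digest(),
        "seed": cfg.seed,
        "pk2dose_version": __version__,
        "n_subjects": len(reports),
        "nuclide": {"name": nuclide.name, "half_life_h": nuclide.half_life_h},
    }
    write_dose_report(summary, out / "report.json", provenance)

    # population summary of the blood model, for the record / VPC use
    try:
        pop = two_stage_population(blood_fit_results, model="2cmt")
        with open(out / "population_blood.json", "w") as fh:
            json.dump(
                {"typical": pop.typical, "iiv_cv_percent": pop.iiv_cv, "n": pop.n_subjects},
                fh,
                indent=2,
            )
    except InvalidInputError:
        logger.warning("population summary skipped (too few converged blood fits)")

    return summary
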