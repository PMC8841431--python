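"""Decay-weighted cumulated activity and mouse→human allometric scaling.

For dosimetry the physical decay must stay in the curve, so the cumulated
activity in a region is the decay-weighted integral of the biological model

    Ã = ∫₀^∞ C(t) · e^{−λ_phys t} dt · V_region        [kBq·h]

evaluated in closed form from the fitted one-compartment parameters.
Concentration (kBq/mL) is converted to regional amount with the region mass
at a configurable tissue density (default 1 g/mL). Dividing by the injected
activity gives the residence time τ (h per unit injected activity), the
quantity the MIRD dose engine consumes.

Cross-species extrapolation uses mass-ratio (McParland) scaling:

    Ã_org,human = (m_WB,animal / m_WB,human) · (m_org,human / m_org,animal) · Ã_org,animal

Rest-of-body residence time is the whole-body residence time minus the sum
over explicitly quantified organs; because the rest of body scales with the
whole-body mass on both sides of the ratio, its scale factor is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import InvalidInputError, Radionuclide
from .compartmental import OneCmtParams, auc_ca


@dataclass(frozen=True)
class OrganMassTable:
    """Whole-body and per-organ masses (kg) for one species."""

    species: str
    whole_body_kg: float
    organ_kg: dict

    def __post_init__(self):
        if not (self.whole_body_kg > 0):
            raise InvalidInputError("whole_body_kg must be > 0")
        for region, m in self.organ_kg.items():
            if not (m > 0):
                raise InvalidInputError(f"mass of {region!r} must be > 0")
            if m >= self.whole_body_kg:
                raise InvalidInputError(
                    f"organ {region!r} mass {m} kg >= whole body {self.whole_body_kg} kg"
                )
        if sum(self.organ_kg.values()) > self.whole_body_kg:
            raise InvalidInputError("listed organ masses exceed whole-body mass")

    def __getitem__(self, region: str) -> float:
        return self.organ_kg[region]


@dataclass
class ResidenceTimeTable:
    """Region → residence time τ (h per unit injected activity)."""

    taus_h: dict = field(default_factory=dict)
    scale: str = "animal"  # or "human"

    def __post_init__(self):
        for region, tau in self.taus_h.items():
            if tau < 0:
                raise InvalidInputError(f"negative residence time for {region!r}")

    def items(self):
        return self.taus_h.items()

    def __getitem__(self, region):
        return self.taus_h[region]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.taus_h), "residence_time_h": list(self.taus_h.values())}
        )


def decay_weighted_auc(
    p: OneCmtParams, dose: float, nuclide: Radionuclide
) -> float:
    """∫₀^∞ C(t)·e^{−λ t} dt in kBq·h/mL, closed form.

    With λ = 0 this is exactly the biological AUC₀→∞. The ka = ke limit uses
    ∫ t·e^{−(k+λ)t} dt = 1/(k+λ)².
    """
    lam = nuclide.decay_constant_h
    if lam < 0:
        raise InvalidInputError("decay constant must be >= 0")
    if lam == 0:
        return auc_ca(p, dose, math.inf)
    if abs(p.ka - p.ke) <= 1e-12 * p.ka:
        return dose * p.ka / p.v / (p.ka + lam) ** 2
    return (
        dose
        * p.ka
        / (p.v * (p.ka - p.ke))
        * (1.0 / (p.ke + lam) - 1.0 / (p.ka + lam))
    )


def cumulated_activity(
    p: OneCmtParams,
    dose: float,
    nuclide: Radionuclide,
    region_mass_g: float,
    density_g_per_mL: float = 1.0,
) -> float:
    """Cumulated activity Ã (kBq·h) in a region of the given mass."""
    if not (region_mass_g > 0 and density_g_per_mL > 0):
        raise InvalidInputError("region mass and density must be > 0")
    volume_mL = region_mass_g / density_g_per_mL
    return decay_weighted_auc(p, dose, nuclide) * volume_mL


def residence_time(
    p: OneCmtParams,
    dose: float,
    nuclide: Radionuclide,
    region_mass_g: float,
    density_g_per_mL: float = 1.0,
) -> float:
    """Residence time τ = Ã / injected activity (h)."""
    return cumulated_activity(p, dose, nuclide, region_mass_g, density_g_per_mL) / dose


def whole_body_residence_time(nuclide: Radionuclide, retention_fraction: float = 1.0) -> float:
    """Whole-body residence time for a fully retained tracer: the decay-only
    integral 1/λ = T½/ln 2, optionally scaled by a retained fraction."""
    if not (0 < retention_fraction <= 1):
        raise InvalidInputError("retention_fraction must be in (0, 1]")
    return retention_fraction / nuclide.decay_constant_h


def rest_of_body_residence(whole_body_tau: float, organ_taus) -> float:
    """Whole-body residence time minus the explicitly quantified organs.

    A negative remainder means the organ quantification is inconsistent with
    whole-body retention and raises with the excess amount.
    """
    if whole_body_tau < 0:
        raise InvalidInputError("whole_body_tau must be >= 0")
    organ_sum = float(sum(organ_taus))
    remainder = whole_body_tau - organ_sum
    if remainder < 0:
        raise InvalidInputError(
            f"organ residence times exceed whole body by {-remainder:.6g} h"
        )
    return remainder


def mcparland_scale(
    a_animal: float,
    m_wb_animal_kg: float,
    m_wb_human_kg: float,
    m_org_animal_kg: float,
    m_org_human_kg: float,
) -> float:
    """Mass-ratio scaling of cumulated activity from animal to human."""
    for m in (m_wb_animal_kg, m_wb_human_kg, m_org_animal_kg, m_org_human_kg):
        if not (m > 0):
            raise InvalidInputError("masses must be > 0")
    return (
        (m_wb_animal_kg / m_wb_human_kg)
        * (m_org_human_kg / m_org_animal_kg)
        * a_animal
    )


def scale_residence_table(
    animal_taus: ResidenceTimeTable,
    animal_masses: OrganMassTable,
    human_masses: OrganMassTable,
    rest_of_body_region: str = "rest_of_body",
) -> ResidenceTimeTable:
    """Apply McParland scaling region-by-region.

    The rest-of-body entry uses whole-body masses for both ratio terms, which
    makes its factor exactly 1.
    """
    out = {}
    for region, tau in animal_taus.items():
        if region == rest_of_body_region:
            out[region] = tau
            continue
        if region not in animal_masses.organ_kg:
            raise InvalidInputError(f"no {animal_masses.species} mass for {region!r}")
        if region not in human_masses.organ_kg:
            raise InvalidInputError(f"no {human_masses.species} mass for {region!r}")
        out[region] = mcparland_scale(
            tau,
            animal_masses.whole_body_kg,
            human_masses.whole_body_kg,
            animal_masses[region],
            human_masses[region],
        )
    return ResidenceTimeTable(taus_h=out, scale="human")


# ---------------------------------------------------------------------------
# Mass-table I/O
# ---------------------------------------------------------------------------


def read_mass_table(source, species: str) -> OrganMassTable:
    """Read one species from a long-format masses.csv
    (columns species,region,mass_kg; one ``whole_body`` row per species)."""
    df = pd.read_csv(source)
    for col in ("species", "region", "mass_kg"):
        if col not in df.columns:
            raise InvalidInputError(f"masses table: missing column {col!r}")
    sub = df[df["species"] == species]
    if sub.empty:
        raise InvalidInputError(f"species {species!r} not in masses table")
    wb = sub[sub["region"] == "whole_body"]
    if len(wb) != 1:
        raise InvalidInputError(f"need exactly one whole_body row for {species!r}")
    organs = {
        str(r["region"]): float(r["mass_kg"])
        for _, r in sub.iterrows()
        if r["region"] != "whole_body"
    }
    return OrganMassTable(
        species=species,
        whole_body_kg=float(wb["mass_kg"].iloc[0]),
        organ_kg=organs,
    )


def write_mass_tables(tables, dest) -> None:
    rows = []
    for t in tables:
        rows.append({"species": t.species, "region": "whole_body", "mass_kg": t.whole_body_kg})
        rows.extend(
            {"species": t.species, "region": r, "mass_kg": m}
            for r, m in t.organ_kg.items()
        )
    pd.DataFrame(rows).to_csv(dest, index=False)
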