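"""MIRD absorbed-dose engine over a pluggable S-value matrix, ICRP-103
effective dose, and cohort summaries.

Absorbed dose to a target region T follows the MIRD schema

    D(T) = Σ_S τ_S · S(T ← S)          [mGy/MBq]

where τ_S is the residence time of source region S (h per unit injected
activity, MBq·h/MBq) and S(T←S) the S-value (mGy per MBq·h), a phantom- and
nuclide-specific input that this package never computes. Effective dose is
the ICRP-103 tissue-weighted sum E = Σ_T w_T·H_T with radiation weighting 1
for photons and electrons, so organ mGy/MBq sum numerically to mSv/MBq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InvalidInputError

_WEIGHT_TOL = 1e-9


@dataclass
class SValueMatrix:
    """S-values S(target ← source) in mGy/(MBq·h)."""

    sources: list
    targets: list
    s: np.ndarray  # shape (n_targets, n_sources)
    aliases: dict = field(default_factory=dict)  # residence-region -> source

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.targets), len(self.sources)):
            raise InvalidInputError("S matrix shape mismatch")
        if np.any(self.s < 0) or not np.all(np.isfinite(self.s)):
            raise InvalidInputError("S-values must be finite and >= 0")

    def source_index(self, region: str) -> int:
        name = self.aliases.get(region.lower(), region)
        lowered = [s.lower() for s in self.sources]
        if name.lower() not in lowered:
            raise InvalidInputError(
                f"region {region!r} matches no S-value source column "
                f"(sources: {self.sources})"
            )
        return lowered.index(name.lower())


@dataclass(frozen=True)
class TissueWeights:
    """ICRP-103-style tissue weighting factors; must sum to 1."""

    w: dict

    def __post_init__(self):
        if any(v < 0 for v in self.w.values()):
            raise InvalidInputError("tissue weights must be >= 0")
        total = sum(self.w.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise InvalidInputError(f"tissue weights sum to {total}, expected 1")

    def items(self):
        return self.w.items()


@dataclass
class DoseReport:
    """Per-target absorbed doses and effective dose for one subject (or a
    cohort mean with CV%)."""

    absorbed_mGy_per_MBq: dict
    effective_mSv_per_MBq: float
    cv_percent: dict = field(default_factory=dict)  # quantity -> CV%

    def to_json_dict(self, provenance: dict | None = None) -> dict:
        return {
            "targets": {
                name: {
                    "dose_mGy_per_MBq": dose,
                    **(
                        {"cv_percent": self.cv_percent[name]}
                        if name in self.cv_percent
                        else {}
                    ),
                }
                for name, dose in self.absorbed_mGy_per_MBq.items()
            },
            "effective_dose_mSv_per_MBq": self.effective_mSv_per_MBq,
            **(
                {"cv_percent": self.cv_percent["effective_dose"]}
                if "effective_dose" in self.cv_percent
                else {}
            ),
            "provenance": provenance or {},
        }


def absorbed_doses(tau, s: SValueMatrix) -> dict:
    """D(T) = Σ_S τ_S · S(T←S) for every target region of the matrix."""
    doses = np.zeros(len(s.targets))
    for region, t in tau.items():
        if t < 0:
            raise InvalidInputError(f"negative residence time for {region!r}")
        doses += t * s.s[:, s.source_index(region)]
    return dict(zip(s.targets, doses.tolist()))


def effective_dose(doses: dict, weights: TissueWeights) -> float:
    """Tissue-weighted sum Σ w_T·D_T (mSv/MBq, radiation weighting 1)."""
    lowered = {k.lower(): v for k, v in doses.items()}
    missing = [t for t, w in weights.items() if w > 0 and t.lower() not in lowered]
    if missing:
        raise InvalidInputError(f"weighted target(s) missing from dose map: {missing}")
    return sum(w * lowered[t.lower()] for t, w in weights.items() if w > 0)


def cohort_dose_summary(reports) -> DoseReport:
    """Arithmetic means and CV% (sample SD) across per-subject dose reports.

    With a single subject the mean is returned and every CV is NaN.
    """
    reports = list(reports)
    if not reports:
        raise InvalidInputError("no dose reports")
    targets = list(reports[0].absorbed_mGy_per_MBq)
    for r in reports[1:]:
        if list(r.absorbed_mGy_per_MBq) != targets:
            raise InvalidInputError("dose reports have inconsistent targets")

    def mean_cv(vals):
        vals = np.asarray(vals, dtype=float)
        m = float(np.mean(vals))
        if len(vals) < 2:
            return m, float("nan")
        cv = 100.0 * float(np.std(vals, ddof=1)) / m if m != 0 else float("nan")
        return m, cv

    absorbed = {}
    cvs = {}
    for t in targets:
        m, cv = mean_cv([r.absorbed_mGy_per_MBq[t] for r in reports])
        absorbed[t] = m
        cvs[t] = cv
    e_mean, e_cv = mean_cv([r.effective_mSv_per_MBq for r in reports])
    cvs["effective_dose"] = e_cv
    return DoseReport(
        absorbed_mGy_per_MBq=absorbed,
        effective_mSv_per_MBq=e_mean,
        cv_percent=cvs,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_svalue_table(source, aliases: dict | None = None) -> SValueMatrix:
    """Read a long-format svalues.csv: columns source,target,s_mGy_per_MBq_h.

    Missing (source, target) combinations are zero.
    """
    df = pd.read_csv(source)
    for col in ("source", "target", "s_mGy_per_MBq_h"):
        if col not in df.columns:
            raise InvalidInputError(f"svalues table: missing column {col!r}")
    sources = list(dict.fromkeys(df["source"].astype(str)))
    targets = list(dict.fromkeys(df["target"].astype(str)))
    mat = np.zeros((len(targets), len(sources)))
    for _, row in df.iterrows():
        mat[targets.index(str(row["target"])), sources.index(str(row["source"]))] = float(
            row["s_mGy_per_MBq_h"]
        )
    return SValueMatrix(
        sources=sources,
        targets=targets,
        s=mat,
        aliases={k.lower(): v for k, v in (aliases or {}).items()},
    )


def write_svalue_table(s: SValueMatrix, dest) -> None:
    rows = [
        {"source": src, "target": tgt, "s_mGy_per_MBq_h": s.s[i, j]}
        for i, tgt in enumerate(s.targets)
        for j, src in enumerate(s.sources)
    ]
    pd.DataFrame(rows).to_csv(dest, index=False)


def read_weight_table(source) -> TissueWeights:
    """Read weights.csv (columns target,w_T); the Σ=1 invariant is enforced
    at load."""
    df = pd.read_csv(source)
    for col in ("target", "w_T"):
        if col not in df.columns:
            raise InvalidInputError(f"weights table: missing column {col!r}")
    return TissueWeights(w={str(r["target"]): float(r["w_T"]) for _, r in df.iterrows()})


def icrp103_weights() -> TissueWeights:
    """Bundled ICRP-103 tissue weighting factors.

    Remainder tissues are pooled into a single ``remainder`` target
    (w = 0.12), to be mapped onto a pooled rest-of-body dose by the caller.
    """
    from importlib.resources import files

    return read_weight_table(files("pk2dose.data") / "icrp103_weights.csv")


def write_dose_report(report: DoseReport, dest, provenance: dict | None = None) -> None:
    payload = report.to_json_dict(provenance)
    if hasattr(dest, "write"):
        json.dump(payload, dest, indent=2)
    else:
        with open(dest, "w") as fh:
            json.dump(payload, fh, indent=2)
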