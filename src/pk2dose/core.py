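"""Domain types, radioactive-decay arithmetic, %ID/g, and tabular I/O.

Conventions used throughout the package:

* time zero is the injection time; every time value is hours post-injection
* activities are kBq, concentrations kBq/mL, masses g (organ-mass tables
  in the allometry stage use kg)
* a :class:`TimeActivityCurve` carries a ``decay_corrected`` flag telling
  whether physical decay has already been removed (gamma counters usually
  report decay-corrected values; dosimetry needs the non-corrected curve)
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("pk2dose")

VALID_GROUPS = ("healthy", "tumoural", "tumoural_blocking")

TAC_COLUMNS = [
    "subject_id",
    "group",
    "region",
    "time_h",
    "conc_kBq_per_mL",
    "decay_corrected",
]
SUBJECT_COLUMNS = ["subject_id", "group", "body_mass_g", "injected_kBq"]
SAMPLE_COLUMNS = [
    "subject_id",
    "region",
    "time_post_injection_h",
    "measured_kBq",
    "background_kBq",
    "mass_g",
]


class InvalidInputError(ValueError):
    """Raised when a physical precondition (non-negative time, positive mass,
    ...) is violated."""


class ParseError(ValueError):
    """Raised when a tabular input violates its column/ordering contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide characterised by its physical half-life.

    The decay constant is derived (λ = ln 2 / T½) so the pair can never be
    inconsistent.
    """

    name: str
    half_life_h: float

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0):
            raise InvalidInputError(
                f"half_life_h must be > 0, got {self.half_life_h}"
            )

    @property
    def decay_constant_h(self) -> float:
        """Physical decay constant λ in 1/h."""
        return math.log(2) / self.half_life_h


#: Zirconium-89, the positron emitter used for antibody immunoPET.
ZR89 = Radionuclide("Zr-89", 78.4)


@dataclass(frozen=True)
class Subject:
    """One animal (or, after scaling, a reference human)."""

    id: str
    group: str
    body_mass_g: float
    injected_kBq: float

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise InvalidInputError(
                f"group must be one of {VALID_GROUPS}, got {self.group!r}"
            )
        if not (self.body_mass_g > 0):
            raise InvalidInputError("body_mass_g must be > 0")
        if not (self.injected_kBq > 0):
            raise InvalidInputError("injected_kBq must be > 0")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Concentration-vs-time series for one subject and region."""

    subject_id: str
    region: str
    times_h: tuple
    conc_kBq_per_mL: tuple
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.conc_kBq_per_mL, dtype=float)
        if t.size != c.size:
            raise InvalidInputError("times and concentrations differ in length")
        if t.size and t[0] < 0:
            raise InvalidInputError("times must be >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise InvalidInputError("concentrations must be finite and >= 0")
        object.__setattr__(self, "times_h", tuple(float(x) for x in t))
        object.__setattr__(self, "conc_kBq_per_mL", tuple(float(x) for x in c))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times_h, dtype=float)

    @property
    def c(self) -> np.ndarray:
        return np.asarray(self.conc_kBq_per_mL, dtype=float)

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass(frozen=True)
class TissueSample:
    """One gamma-counted tissue sample from an ex vivo biodistribution."""

    region: str
    measured_kBq: float
    background_kBq: float
    mass_g: float
    time_post_injection_h: float

    def __post_init__(self) -> None:
        if not (self.mass_g > 0):
            raise InvalidInputError("mass_g must be > 0")
        if self.measured_kBq < 0 or self.background_kBq < 0:
            raise InvalidInputError("activities must be >= 0")
        if self.time_post_injection_h < 0:
            raise InvalidInputError("time_post_injection_h must be >= 0")


@dataclass
class Cohort:
    """Subjects plus their time–activity curves."""

    subjects: dict = field(default_factory=dict)  # id -> Subject
    tacs: list = field(default_factory=list)  # list[TimeActivityCurve]

    def curves(self, region: str | None = None) -> list:
        if region is None:
            return list(self.tacs)
        return [tac for tac in self.tacs if tac.region == region]

    def curve(self, subject_id: str, region: str) -> TimeActivityCurve:
        for tac in self.tacs:
            if tac.subject_id == subject_id and tac.region == region:
                return tac
        raise KeyError(f"no curve for subject {subject_id!r} region {region!r}")

    @property
    def regions(self) -> list:
        seen: dict = {}
        for tac in self.tacs:
            seen.setdefault(tac.region, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Decay arithmetic
# ---------------------------------------------------------------------------


def decay_correct(
    activity: float, elapsed_h: float, nuclide: Radionuclide = ZR89
) -> float:
    """Back-correct a measured activity to the injection time.

    Returns ``activity * exp(λ * elapsed_h)``: the activity the sample would
    have shown had it been counted at time zero. One physical half-life of
    elapsed time doubles the corrected value.
    """
    activity = np.asarray(activity, dtype=float)
    elapsed_h = np.asarray(elapsed_h, dtype=float)
    if np.any(elapsed_h < 0):
        raise InvalidInputError("elapsed_h must be >= 0")
    if np.any(activity < 0):
        raise InvalidInputError("activity must be >= 0")
    out = activity * np.exp(nuclide.decay_constant_h * elapsed_h)
    return float(out) if out.ndim == 0 else out


def decay_apply(
    activity: float, elapsed_h: float, nuclide: Radionuclide = ZR89
) -> float:
    """Apply physical decay forward in time: ``activity * exp(-λ t)``.

    Inverse of :func:`decay_correct`.
    """
    activity = np.asarray(activity, dtype=float)
    elapsed_h = np.asarray(elapsed_h, dtype=float)
    if np.any(elapsed_h < 0):
        raise InvalidInputError("elapsed_h must be >= 0")
    if np.any(activity < 0):
        raise InvalidInputError("activity must be >= 0")
    out = activity * np.exp(-nuclide.decay_constant_h * elapsed_h)
    return float(out) if out.ndim == 0 else out


def percent_id_per_gram(
    sample: TissueSample, subject: Subject, nuclide: Radionuclide = ZR89
) -> float:
    """Percentage of the injected dose per gram of tissue.

    Background is subtracted first, the net counts are decay-corrected to the
    injection time, then normalised by injected activity and sample mass.
    Background exceeding the measured counts (possible at near-background
    count rates) clamps the net activity to zero with a warning.
    """
    net = sample.measured_kBq - sample.background_kBq
    if net < 0:
        logger.warning(
            "background (%g kBq) exceeds measured (%g kBq) for region %s; "
            "clamping net activity to 0",
            sample.background_kBq,
            sample.measured_kBq,
            sample.region,
        )
        net = 0.0
    corrected = decay_correct(net, sample.time_post_injection_h, nuclide)
    return corrected / subject.injected_kBq / sample.mass_g * 100.0


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, io.IOBase]


def _read_csv(source: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{what}: empty file without header") from exc
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise ParseError(f"{what}: missing column(s) {missing}")
    return df


def read_subject_table(source: PathLike) -> dict:
    """Read ``subjects.csv`` into ``{subject_id: Subject}``."""
    df = _read_csv(source, SUBJECT_COLUMNS, "subjects table")
    subjects: dict = {}
    for i, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in subjects:
            raise ParseError(f"subjects table row {i}: duplicate subject_id {sid!r}")
        subjects[sid] = Subject(
            id=sid,
            group=str(row["group"]),
            body_mass_g=float(row["body_mass_g"]),
            injected_kBq=float(row["injected_kBq"]),
        )
    return subjects


def read_tac_table(
    tacs_source: PathLike, subjects_source: PathLike | None = None
) -> Cohort:
    """Read ``tacs.csv`` (and optionally ``subjects.csv``) into a Cohort.

    Rows are grouped per (subject, region) and must carry strictly increasing
    unique times; violations raise :class:`ParseError` naming the offending
    row.
    """
    df = _read_csv(tacs_source, TAC_COLUMNS, "TAC table")
    cohort = Cohort()
    if subjects_source is not None:
        cohort.subjects = read_subject_table(subjects_source)
    if df.empty:
        return cohort
    for (sid, region), grp in df.groupby(["subject_id", "region"], sort=False):
        grp = grp.reset_index()
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            row_no = int(grp.loc[bad, "index"]) + 2  # 1-based incl. header
            if times[bad] == times[bad - 1]:
                raise ParseError(
                    f"TAC table row {row_no}: duplicate time {times[bad]} h for "
                    f"subject {sid!r} region {region!r}"
                )
            raise ParseError(
                f"TAC table row {row_no}: non-monotone time {times[bad]} h for "
                f"subject {sid!r} region {region!r}"
            )
        flags = set(grp["decay_corrected"].astype(int))
        if len(flags) > 1:
            raise ParseError(
                f"TAC table: inconsistent decay_corrected flag for subject "
                f"{sid!r} region {region!r}"
            )
        cohort.tacs.append(
            TimeActivityCurve(
                subject_id=str(sid),
                region=str(region),
                times_h=tuple(times),
                conc_kBq_per_mL=tuple(grp["conc_kBq_per_mL"].astype(float)),
                decay_corrected=bool(flags.pop()),
            )
        )
    return cohort


def write_tac_table(cohort: Cohort, dest: PathLike) -> None:
    """Write a cohort's curves back to the tacs.csv column contract."""
    rows = []
    for tac in cohort.tacs:
        subj = cohort.subjects.get(tac.subject_id)
        group = subj.group if subj is not None else ""
        for t, c in zip(tac.times_h, tac.conc_kBq_per_mL):
            rows.append(
                {
                    "subject_id": tac.subject_id,
                    "group": group,
                    "region": tac.region,
                    "time_h": t,
                    "conc_kBq_per_mL": repr(c),
                    "decay_corrected": int(tac.decay_corrected),
                }
            )
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(dest, index=False)


def write_subject_table(subjects: Iterable[Subject] | dict, dest: PathLike) -> None:
    if isinstance(subjects, dict):
        subjects = subjects.values()
    rows = [
        {
            "subject_id": s.id,
            "group": s.group,
            "body_mass_g": repr(s.body_mass_g),
            "injected_kBq": repr(s.injected_kBq),
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(dest, index=False)


def read_sample_table(source: PathLike, default_background_kBq: float = 0.0) -> list:
    """Read an ex vivo ``samples.csv`` into ``[(subject_id, TissueSample)]``.

    A per-sample background column is honoured when present; missing values
    fall back to ``default_background_kBq`` (background may have been counted
    per batch rather than per sample).
    """
    required = [c for c in SAMPLE_COLUMNS if c != "background_kBq"]
    df = _read_csv(source, required, "samples table")
    if "background_kBq" not in df.columns:
        df["background_kBq"] = default_background_kBq
    df["background_kBq"] = df["background_kBq"].fillna(default_background_kBq)
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["subject_id"]),
                TissueSample(
                    region=str(row["region"]),
                    measured_kBq=float(row["measured_kBq"]),
                    background_kBq=float(row["background_kBq"]),
                    mass_g=float(row["mass_g"]),
                    time_post_injection_h=float(row["time_post_injection_h"]),
                ),
            )
        )
    return out
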