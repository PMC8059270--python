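"""Longitudinal BMI data structures and long-format table I/O.

The canonical container is :class:`LongitudinalDataset`: a list of subjects,
each carrying an age-ordered series of (age, BMI) observations taken at
numbered measurement sweeps, plus sex / birth-cohort / measurement-source
metadata.  Ages are decimal years; BMI is kg/m².  The canonical on-disk
format is a long CSV with one row per observation and the header
``id,sex,cohort,sweep,age,bmi,source``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("measured", "self_report")
SEXES = ("male", "female")

CANONICAL_COLUMNS = ("id", "sex", "cohort", "sweep", "age", "bmi", "source")

BMI_MIN = 5.0
BMI_MAX = 100.0


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (e.g. duplicate sweep)."""


class StateError(RuntimeError):
    """An operation was applied to a dataset in the wrong state."""


@dataclass(frozen=True)
class Observation:
    """One BMI measurement at one sweep.

    ``age`` is in decimal years (raw or centered depending on the parent
    dataset); ``bmi`` in kg/m²; ``sweep_index`` is the 1-based measurement
    occasion; ``source`` records whether weight/height were measured by a
    nurse or self-reported.
    """

    age: float
    bmi: float
    sweep_index: int
    source: str = "measured"

    def __post_init__(self) -> None:
        if not np.isfinite(self.age):
            raise ValueError(f"age must be finite, got {self.age}")
        if not np.isfinite(self.bmi) or not (BMI_MIN < self.bmi < BMI_MAX):
            raise ValueError(f"bmi {self.bmi} outside ({BMI_MIN}, {BMI_MAX}) kg/m²")
        if int(self.sweep_index) != self.sweep_index or self.sweep_index < 1:
            raise ValueError(f"sweep_index must be a positive integer, got {self.sweep_index}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class Subject:
    """A study participant with an ordered series of observations."""

    id: str
    sex: str
    cohort: str
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.cohort:
            raise ValueError(f"subject {self.id}: cohort must be non-missing")
        obs = tuple(sorted(self.observations, key=lambda o: o.age))
        ages = [o.age for o in obs]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise IntegrityError(f"subject {self.id}: ages must be strictly increasing")
        sweeps = [o.sweep_index for o in obs]
        if len(set(sweeps)) != len(sweeps):
            raise IntegrityError(f"subject {self.id}: duplicate sweep_index")
        object.__setattr__(self, "observations", obs)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def ages(self) -> np.ndarray:
        return np.array([o.age for o in self.observations])

    def bmis(self) -> np.ndarray:
        return np.array([o.bmi for o in self.observations])

    def sweeps(self) -> np.ndarray:
        return np.array([o.sweep_index for o in self.observations], dtype=int)


@dataclass(frozen=True)
class LongitudinalDataset:
    """A collection of subjects with an optional age-centering record.

    ``centering_age`` is None for raw ages; once :func:`center_ages` has been
    applied it holds the centering value and stored ages are (raw − center).
    """

    subjects: tuple[Subject, ...]
    centering_age: float | None = None

    def __post_init__(self) -> None:
        subs = tuple(self.subjects)
        ids = [s.id for s in subs]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index[0]
            raise IntegrityError(f"duplicate subject id {dup!r}")
        object.__setattr__(self, "subjects", subs)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    @property
    def n_sweeps(self) -> int:
        """Largest sweep index present (S)."""
        return max((o.sweep_index for s in self.subjects for o in s.observations), default=0)

    def sexes(self) -> set[str]:
        return {s.sex for s in self.subjects}

    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (s.id, s.sex, s.cohort, o.sweep_index, o.age, o.bmi, o.source)
            for s in self.subjects
            for o in s.observations
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _assemble(df: pd.DataFrame) -> tuple[Subject, ...]:
    dup = df.duplicated(subset=["id", "sweep"])
    if dup.any():
        bad = df.loc[dup, "id"].iloc[0]
        raise IntegrityError(f"duplicate (id, sweep) rows for subject {bad!r}")
    subjects = []
    for sid, grp in df.groupby("id", sort=True):
        obs = tuple(
            Observation(
                age=float(r.age),
                bmi=float(r.bmi),
                sweep_index=int(r.sweep),
                source=str(r.source),
            )
            for r in grp.itertuples()
        )
        subjects.append(
            Subject(id=str(sid), sex=str(grp["sex"].iloc[0]), cohort=str(grp["cohort"].iloc[0]), observations=obs)
        )
    return tuple(subjects)


def read_long_table(path, schema: dict[str, str] | None = None) -> LongitudinalDataset:
    """Read a long-format delimited table into a :class:`LongitudinalDataset`.

    Parameters
    ----------
    path : str or file-like
        CSV with columns for id, sex, cohort, sweep, age, bmi, source.
    schema : dict, optional
        Mapping from canonical column names to the file's column names,
        e.g. ``{"id": "serial", "bmi": "bmi_kgm2"}``.  Unmapped names are
        taken as-is.

    Rows with missing age or BMI are dropped (count logged).  A missing
    mandatory column raises :class:`SchemaError`; a duplicate (id, sweep)
    pair raises :class:`IntegrityError` naming the subject.
    """
    df = pd.read_csv(path)
    mapping = {canon: (schema or {}).get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = df.rename(columns={src: canon for canon, src in mapping.items()})[list(CANONICAL_COLUMNS)]
    n_before = len(df)
    df = df.dropna(subset=["age", "bmi"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_long_table: dropped %d row(s) with missing age or bmi", n_dropped)
    return LongitudinalDataset(subjects=_assemble(df))


def write_long_table(ds: LongitudinalDataset, path) -> None:
    """Write the dataset as canonical long CSV (one row per observation)."""
    ds.to_dataframe().to_csv(path, index=False)


def filter_min_observations(ds: LongitudinalDataset, min_n: int = 3) -> LongitudinalDataset:
    """Keep only subjects with at least ``min_n`` BMI observations.

    The default of 3 mirrors the usual practice of requiring enough serial
    measurements per person to inform trajectory classification.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = tuple(s for s in ds.subjects if s.n_obs >= min_n)
    removed = ds.n_subjects - len(kept)
    if removed:
        logger.info("filter_min_observations: removed %d subject(s) with < %d observations", removed, min_n)
    return LongitudinalDataset(subjects=kept, centering_age=ds.centering_age)


def center_ages(ds: LongitudinalDataset, center: float) -> LongitudinalDataset:
    """Subtract ``center`` (years) from every observation age.

    Centering near the middle of the age range keeps the polynomial design
    well conditioned.  Centering an already-centered dataset raises
    :class:`StateError`.
    """
    if not np.isfinite(center):
        raise ValueError("center must be finite")
    if ds.centering_age is not None:
        raise StateError(f"dataset already centered at {ds.centering_age}")
    subjects = tuple(
        replace(
            s,
            observations=tuple(replace(o, age=o.age - center) for o in s.observations),
        )
        for s in ds.subjects
    )
    return LongitudinalDataset(subjects=subjects, centering_age=float(center))


def summarize(ds: LongitudinalDataset) -> pd.DataFrame:
    """Per-cohort and total subject/observation counts and % with ≥4 observations."""
    if ds.n_subjects == 0:
        raise ValueError("summarize: empty dataset")
    rows = []
    cohorts = ds.cohorts()
    for cohort in cohorts + ["total"]:
        subs = ds.subjects if cohort == "total" else [s for s in ds.subjects if s.cohort == cohort]
        n_sub = len(subs)
        n_obs = sum(s.n_obs for s in subs)
        pct_ge4 = 100.0 * sum(s.n_obs >= 4 for s in subs) / n_sub
        rows.append((cohort, n_sub, n_obs, pct_ge4))
    return pd.DataFrame(rows, columns=["cohort", "n_subjects", "n_observations", "pct_ge4_obs"]).set_index("cohort")


def split_by_sex(ds: LongitudinalDataset) -> dict[str, LongitudinalDataset]:
    """Split into per-sex datasets (trajectory models are fitted per sex)."""
    out = {}
    for sex in sorted(ds.sexes()):
        out[sex] = LongitudinalDataset(
            subjects=tuple(s for s in ds.subjects if s.sex == sex),
            centering_age=ds.centering_age,
        )
    return out
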