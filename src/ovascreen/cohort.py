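"""Longitudinal biomarker cohort containers and the log(Z+4) level transform.

A cohort holds serial serum-biomarker measurements (e.g. CA125, HE4,
glycodelin) for screened women, each labelled as a control (0) or a case (1,
later diagnosed with ovarian/tubal cancer).  Every modelling stage in this
package works on the transformed scale ``Y = log(Z + 4)``, where ``Z`` is the
raw assay level; the shift keeps the transform defined for small and mildly
negative assay readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VisitSeries",
    "Cohort",
    "transform_level",
    "inverse_transform_level",
]

#: shift applied before the log transform
LEVEL_SHIFT = 4.0

#: allowed number of screening visits per patient
MIN_VISITS, MAX_VISITS = 2, 5


def transform_level(z):
    """Map a raw biomarker level ``z`` to the modelling scale ``log(z + 4)``.

    Accepts scalars or arrays.  Raises ``ValueError`` for ``z <= -4`` where
    the logarithm is undefined.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= -LEVEL_SHIFT):
        raise ValueError(f"raw level must exceed {-LEVEL_SHIFT}; got {z}")
    out = np.log(z + LEVEL_SHIFT)
    return float(out) if out.ndim == 0 else out


def inverse_transform_level(y):
    """Inverse of :func:`transform_level`: ``exp(y) - 4``."""
    y = np.asarray(y, dtype=float)
    out = np.exp(y) - LEVEL_SHIFT
    return float(out) if out.ndim == 0 else out


@dataclass
class VisitSeries:
    """Screening history of one patient.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    status : int
        0 for a control, 1 for a case.
    ages : array-like of float
        Strictly increasing visit ages in years; between 2 and 5 visits.
    levels : dict[str, array-like]
        Raw biomarker level per marker name; each series aligned with ``ages``.
    diagnosis_age : float, optional
        Age at clinical diagnosis (cases only); must be >= the last visit age.
    """

    patient_id: str
    status: int
    ages: np.ndarray
    levels: dict[str, np.ndarray]
    diagnosis_age: float | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if self.status not in (0, 1):
            raise ValueError("status must be 0 (control) or 1 (case)")
        n = self.ages.size
        if not (MIN_VISITS <= n <= MAX_VISITS):
            raise ValueError(
                f"patient {self.patient_id}: expected {MIN_VISITS}-{MAX_VISITS} "
                f"visits, got {n}"
            )
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"patient {self.patient_id}: ages must strictly increase")
        self.levels = {k: np.asarray(v, dtype=float) for k, v in self.levels.items()}
        for marker, z in self.levels.items():
            if z.size != n:
                raise ValueError(
                    f"patient {self.patient_id}: marker {marker} has {z.size} "
                    f"levels for {n} visits"
                )
            if np.any(z <= -LEVEL_SHIFT):
                raise ValueError(
                    f"patient {self.patient_id}: raw {marker} level <= {-LEVEL_SHIFT}"
                )
        if self.status == 1:
            if self.diagnosis_age is None:
                raise ValueError(f"case {self.patient_id} needs a diagnosis_age")
            if self.diagnosis_age < self.d - 1e-9:
                raise ValueError(
                    f"case {self.patient_id}: diagnosis_age precedes last visit"
                )
        elif self.diagnosis_age is not None:
            raise ValueError(f"control {self.patient_id} cannot carry a diagnosis_age")

    @property
    def n_visits(self) -> int:
        return self.ages.size

    @property
    def d(self) -> float:
        """Age at last measurement (years)."""
        return float(self.ages[-1])

    def transformed(self, marker: str) -> np.ndarray:
        """Levels of ``marker`` on the log(Z+4) scale."""
        return transform_level(self.levels[marker])

    def prefix(self, n: int) -> "VisitSeries":
        """The first ``n`` visits as a new series (``n >= 2``)."""
        if n < MIN_VISITS or n > self.n_visits:
            raise ValueError(f"prefix length must be in [{MIN_VISITS}, {self.n_visits}]")
        return VisitSeries(
            patient_id=self.patient_id,
            status=self.status,
            ages=self.ages[:n].copy(),
            levels={k: v[:n].copy() for k, v in self.levels.items()},
            diagnosis_age=self.diagnosis_age,
        )


@dataclass
class Cohort:
    """An ordered collection of patients sharing one biomarker panel.

    Controls are stored before cases (the index convention i = 1..n0 for
    controls used throughout the likelihood); the constructor reorders
    patients if needed.
    """

    patients: list[VisitSeries]
    biomarker_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.patients:
            raise ValueError("cohort must contain at least one patient")
        if not self.biomarker_names:
            self.biomarker_names = sorted(self.patients[0].levels.keys())
        for p in self.patients:
            missing = set(self.biomarker_names) - set(p.levels)
            if missing:
                raise ValueError(f"patient {p.patient_id} lacks markers {missing}")
        # controls precede cases; stable within group
        self.patients = sorted(self.patients, key=lambda p: p.status)
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")

    @property
    def n_controls(self) -> int:
        return sum(1 for p in self.patients if p.status == 0)

    @property
    def n_cases(self) -> int:
        return sum(1 for p in self.patients if p.status == 1)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def controls(self) -> list[VisitSeries]:
        return [p for p in self.patients if p.status == 0]

    @property
    def cases(self) -> list[VisitSeries]:
        return [p for p in self.patients if p.status == 1]

    @property
    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.status for p in self.patients], dtype=int)

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id: str) -> VisitSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def subset_patients(self, ids) -> "Cohort":
        ids = set(ids)
        kept = [p for p in self.patients if p.patient_id in ids]
        return Cohort(kept, biomarker_names=list(self.biomarker_names))

    def subset_markers(self, markers) -> "Cohort":
        """Restrict the panel to ``markers`` (order preserved as given)."""
        markers = list(markers)
        unknown = set(markers) - set(self.biomarker_names)
        if unknown:
            raise KeyError(f"unknown markers {unknown}")
        pats = [
            VisitSeries(
                patient_id=p.patient_id,
                status=p.status,
                ages=p.ages.copy(),
                levels={m: p.levels[m].copy() for m in markers},
                diagnosis_age=p.diagnosis_age,
            )
            for p in self.patients
        ]
        return Cohort(pats, biomarker_names=markers)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: patient_id, status, visit_index, age_years,
        marker, raw_level (plus diagnosis_age, repeated per row for cases)."""
        rows = []
        for p in self.patients:
            for j, age in enumerate(p.ages):
                for m in self.biomarker_names:
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "status": p.status,
                            "visit_index": j,
                            "age_years": age,
                            "marker": m,
                            "raw_level": p.levels[m][j],
                            "diagnosis_age": p.diagnosis_age
                            if p.diagnosis_age is not None
                            else np.nan,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, biomarker_names=None) -> "Cohort":
        if biomarker_names is None:
            biomarker_names = sorted(df["marker"].unique())
        patients = []
        for pid, g in df.groupby("patient_id", sort=False):
            g = g.sort_values(["visit_index", "marker"])
            ages = np.array(sorted(g["age_years"].unique()))
            levels = {}
            for m in biomarker_names:
                gm = g[g["marker"] == m].sort_values("visit_index")
                levels[m] = gm["raw_level"].to_numpy()
            status = int(g["status"].iloc[0])
            dx = g["diagnosis_age"].iloc[0] if "diagnosis_age" in g else np.nan
            patients.append(
                VisitSeries(
                    patient_id=str(pid),
                    status=status,
                    ages=ages,
                    levels=levels,
                    diagnosis_age=None if (status == 0 or pd.isna(dx)) else float(dx),
                )
            )
        return cls(patients, biomarker_names=list(biomarker_names))

    @classmethod
    def read_csv(cls, path, biomarker_names=None) -> "Cohort":
        return cls.from_frame(pd.read_csv(path), biomarker_names=biomarker_names)
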