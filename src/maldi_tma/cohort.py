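"""Core data containers: spectra collections and cohort metadata.

A tissue-microarray (TMA) MALDI-imaging cohort is represented by two
objects:

``SpectrumSet``
    All spectra of a measurement on one shared m/z axis (continuous-mode
    layout) plus a spot table carrying the spot -> core -> TMA -> patient
    lineage.

``CohortMeta``
    Per-patient clinical labels (treatment group, age, sex) and per-core
    annotations (tissue type, whether the core could be annotated by the
    pathologist).

Group labels are integers: 0 = untreated (LpPRP-0), 1 = treated (LpPRP-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical display names for the two treatment groups
GROUP_NAMES = {0: "LpPRP-0", 1: "LpPRP-1"}

SYNOVIAL = "synovial"
MUSCLE = "muscle"


@dataclass
class CohortMeta:
    """Patient- and core-level annotations of a TMA cohort.

    Parameters
    ----------
    patients : DataFrame indexed by ``patient_id`` with columns
        ``group`` (0/1), ``age``, ``sex``, ``tma``.
    cores : DataFrame indexed by ``core_id`` with columns
        ``patient_id`` (NA for muscle control cores), ``tma``,
        ``tissue`` ("synovial"/"muscle"), ``annotated`` (bool).
    """

    patients: pd.DataFrame
    cores: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"group", "age", "sex", "tma"} - set(self.patients.columns)
        if missing:
            raise ValueError(f"patients table missing columns: {sorted(missing)}")
        missing = {"patient_id", "tma", "tissue", "annotated"} - set(self.cores.columns)
        if missing:
            raise ValueError(f"cores table missing columns: {sorted(missing)}")

    # -- derived views -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def synovial_cores(self) -> pd.DataFrame:
        return self.cores[self.cores["tissue"] == SYNOVIAL]

    def muscle_cores(self) -> pd.DataFrame:
        return self.cores[self.cores["tissue"] == MUSCLE]

    def annotated_cores(self) -> pd.DataFrame:
        """Synovial cores the pathologist could annotate."""
        syn = self.synovial_cores()
        return syn[syn["annotated"]]

    def classifiable_patients(self) -> pd.Index:
        """Patients with at least one annotated synovial core.

        Patients whose cores were all lost/folded/too small drop out of the
        classification analysis.
        """
        keep = self.annotated_cores()["patient_id"].unique()
        return self.patients.index[self.patients.index.isin(keep)]

    def labels_for(self, patient_ids) -> pd.Series:
        """Group labels (0/1) for the given patients, in order."""
        return self.patients.loc[pd.Index(patient_ids), "group"]

    # -- persistence ---------------------------------------------------

    def to_csv(self, patients_path, cores_path) -> None:
        self.patients.to_csv(patients_path)
        self.cores.to_csv(cores_path)

    @classmethod
    def from_csv(cls, patients_path, cores_path) -> "CohortMeta":
        patients = pd.read_csv(patients_path, index_col=0)
        cores = pd.read_csv(cores_path, index_col=0)
        cores["annotated"] = cores["annotated"].astype(bool)
        return cls(patients=patients, cores=cores)

    def copy(self) -> "CohortMeta":
        return CohortMeta(self.patients.copy(), self.cores.copy())


@dataclass
class SpectrumSet:
    """Spectra on a shared, strictly increasing m/z axis.

    ``intensities`` has one row per spot (laser position); ``spots`` is a
    DataFrame indexed by ``spot_id`` with columns ``core_id``,
    ``patient_id`` (NA for muscle spots), ``tma`` and ``tissue`` giving the
    full lineage of each spectrum.
    """

    mz: np.ndarray
    intensities: np.ndarray
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.ndim != 1 or np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be 1-D and strictly increasing")
        if self.intensities.shape != (len(self.spots), self.mz.size):
            raise ValueError(
                "intensities must be (n_spots, n_mz) = "
                f"({len(self.spots)}, {self.mz.size}), got {self.intensities.shape}"
            )

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def subset(self, mask) -> "SpectrumSet":
        """New SpectrumSet keeping the spots selected by a boolean mask or
        integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(self.mz, self.intensities[idx], self.spots.iloc[idx])


@dataclass
class MassSpectrum:
    """A single mass spectrum (peak list) with its lineage identifiers."""

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str | None = None
    core_id: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.ndim != 1 or (self.mz.size > 1 and np.any(np.diff(self.mz) <= 0)):
            raise ValueError("mz must be 1-D and strictly increasing")


def iter_spectra(sset: SpectrumSet):
    """Yield each row of a SpectrumSet as a MassSpectrum."""
    for i, (spot_id, row) in enumerate(sset.spots.iterrows()):
        yield MassSpectrum(
            mz=sset.mz,
            intensity=sset.intensities[i],
            spot_id=spot_id,
            core_id=row["core_id"],
        )
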