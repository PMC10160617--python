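"""Spectrum preprocessing: TIC normalization, mass alignment, masking.

The preprocessing chain mirrors the standard MALDI-MSI workflow: each
spectrum is total-ion-count normalized, then all spectra are aligned onto
a common mass axis by fixed-width binning (the alignment convention is
half-open bins ``[lo, lo + w)`` anchored at the global minimum m/z), and
the annotation mask restricts the analysis to spectra from annotated
synovial cores.  Patient-level feature matrices are arithmetic means over
each patient's annotated spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import MUSCLE, SYNOVIAL, CohortMeta, MassSpectrum, SpectrumSet

__all__ = [
    "FeatureMatrix",
    "tic_normalize",
    "align_masses",
    "patient_mean_spectra",
    "filter_annotated",
    "write_imzml",
    "read_imzml",
]


@dataclass
class FeatureMatrix:
    """Units x aligned-m/z-features intensity matrix.

    ``unit_level`` is "spectrum" (rows are spots) or "patient" (rows are
    patient mean spectra).  ``units`` carries per-row lineage (core,
    patient, TMA, tissue) when known.
    """

    values: np.ndarray
    mz_bins: np.ndarray
    unit_ids: pd.Index
    unit_level: str = "spectrum"
    units: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mz_bins = np.asarray(self.mz_bins, dtype=float)
        if self.values.shape != (len(self.unit_ids), self.mz_bins.size):
            raise ValueError("values shape must be (n_units, n_bins)")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must not contain missing values")
        if self.unit_level not in ("spectrum", "patient"):
            raise ValueError("unit_level must be 'spectrum' or 'patient'")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_features(self) -> int:
        return self.mz_bins.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.mz_bins)

    def subset_units(self, mask) -> "FeatureMatrix":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        units = self.units.iloc[idx] if self.units is not None else None
        return FeatureMatrix(
            self.values[idx], self.mz_bins, self.unit_ids[idx], self.unit_level, units
        )

    def subset_features(self, mz_list) -> "FeatureMatrix":
        """Restrict to the given bin centers (order preserved, ascending)."""
        wanted = np.asarray(sorted(mz_list), dtype=float)
        idx = np.searchsorted(self.mz_bins, wanted)
        ok = (idx < self.mz_bins.size) & np.isclose(self.mz_bins[np.minimum(idx, self.mz_bins.size - 1)], wanted)
        if not ok.all():
            missing = wanted[~ok]
            raise KeyError(f"bin centers not in matrix: {missing[:5]}...")
        return FeatureMatrix(
            self.values[:, idx], self.mz_bins[idx], self.unit_ids, self.unit_level, self.units
        )

    # -- persistence ---------------------------------------------------

    def to_csv(self, path) -> None:
        self.to_dataframe().rename_axis("unit_id").to_csv(path)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("mz_bins", data=self.mz_bins)
            f.create_dataset(
                "unit_ids", data=np.asarray(self.unit_ids, dtype="S")
            )
            f.attrs["unit_level"] = self.unit_level

    @classmethod
    def from_hdf5(cls, path) -> "FeatureMatrix":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][()],
                mz_bins=f["mz_bins"][()],
                unit_ids=pd.Index([s.decode() for s in f["unit_ids"][()]]),
                unit_level=f.attrs["unit_level"],
            )


def tic_normalize(spec):
    """Scale intensities so the total ion count is 1.

    Accepts a single :class:`MassSpectrum` or a whole :class:`SpectrumSet`
    (row-wise normalization).  Rejects all-zero spectra.
    """
    if isinstance(spec, MassSpectrum):
        total = spec.intensity.sum()
        if total <= 0:
            raise ValueError("empty spectrum: total ion count is zero")
        return MassSpectrum(spec.mz, spec.intensity / total, spec.spot_id, spec.core_id)
    if isinstance(spec, SpectrumSet):
        totals = spec.intensities.sum(axis=1)
        if np.any(totals <= 0):
            bad = spec.spots.index[totals <= 0][:3].tolist()
            raise ValueError(f"empty spectrum: total ion count is zero for spots {bad}")
        return SpectrumSet(spec.mz, spec.intensities / totals[:, None], spec.spots)
    raise TypeError(f"cannot TIC-normalize {type(spec).__name__}")


def align_masses(spectra, bin_width: float = 0.5) -> FeatureMatrix:
    """Align spectra onto a common axis by fixed-width binning.

    Bins are half-open intervals ``[lo + k*w, lo + (k+1)*w)`` anchored at
    the global minimum m/z; a bin's value is the sum of member peak
    intensities, so each spectrum's total intensity is conserved.  Only
    bins containing at least one m/z position of the input axes are kept.
    Accepts a :class:`SpectrumSet` (fast path: shared axis) or any
    iterable of :class:`MassSpectrum`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")

    if isinstance(spectra, SpectrumSet):
        lo = spectra.mz.min()
        idx = np.floor((spectra.mz - lo) / bin_width).astype(int)
        kept, inverse = np.unique(idx, return_inverse=True)
        values = np.zeros((spectra.n_spots, kept.size))
        np.add.at(values.T, inverse, spectra.intensities.T)
        centers = lo + (kept + 0.5) * bin_width
        return FeatureMatrix(
            values=values,
            mz_bins=centers,
            unit_ids=spectra.spots.index,
            unit_level="spectrum",
            units=spectra.spots.copy(),
        )

    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot align an empty collection of spectra")
    lo = min(s.mz.min() for s in spectra)
    all_idx = sorted({int(i) for s in spectra for i in np.floor((s.mz - lo) / bin_width)})
    pos = {b: j for j, b in enumerate(all_idx)}
    values = np.zeros((len(spectra), len(all_idx)))
    for i, s in enumerate(spectra):
        idx = np.floor((s.mz - lo) / bin_width).astype(int)
        np.add.at(values[i], [pos[b] for b in idx], s.intensity)
    centers = lo + (np.array(all_idx) + 0.5) * bin_width
    ids = pd.Index(
        [s.spot_id if s.spot_id is not None else f"spectrum{i}" for i, s in enumerate(spectra)],
        name="spot_id",
    )
    units = pd.DataFrame(
        {"core_id": [s.core_id for s in spectra]}, index=ids
    )
    return FeatureMatrix(values=values, mz_bins=centers, unit_ids=ids, units=units)


def filter_annotated(fm: FeatureMatrix, meta: CohortMeta) -> FeatureMatrix:
    """Keep only spectra from annotated synovial cores.

    Muscle control cores and cores the pathologist could not annotate are
    excluded from classification input.  Warns (rather than fails) when
    nothing survives.
    """
    if fm.unit_level != "spectrum" or fm.units is None:
        raise ValueError("filter_annotated expects a spectrum-level matrix with lineage")
    good_cores = set(meta.annotated_cores().index)
    mask = fm.units["core_id"].isin(good_cores).to_numpy()
    if not mask.any():
        warnings.warn("no annotated synovial spectra left after filtering", stacklevel=2)
    return fm.subset_units(mask)


def patient_mean_spectra(fm: FeatureMatrix, meta: CohortMeta) -> FeatureMatrix:
    """One row per patient: the arithmetic mean of that patient's spectra.

    Operates on an annotated, spectrum-level matrix.  Patients with zero
    annotated spectra are excluded with a warning.
    """
    if fm.unit_level != "spectrum" or fm.units is None:
        raise ValueError("patient_mean_spectra expects a spectrum-level matrix with lineage")
    pids = fm.units["patient_id"]
    known = pids.notna().to_numpy()
    if not known.all():
        raise ValueError("every spectrum must map to an annotated patient")
    df = pd.DataFrame(fm.values, index=pids.to_numpy())
    means = df.groupby(level=0, sort=True).mean()

    expected = meta.classifiable_patients()
    missing = expected.difference(means.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} classifiable patients have no spectra and are excluded",
            stacklevel=2,
        )
    pat_ids = pd.Index(means.index, name="patient_id")
    units = meta.patients.loc[pat_ids, ["group", "tma"]].copy()
    return FeatureMatrix(
        values=means.to_numpy(),
        mz_bins=fm.mz_bins,
        unit_ids=pat_ids,
        unit_level="patient",
        units=units,
    )


# ---------------------------------------------------------------------------
# imzML I/O


def write_imzml(sset: SpectrumSet, path) -> None:
    """Write a SpectrumSet as continuous-mode imzML plus a spot table CSV.

    Spot lineage does not fit the imzML coordinate model, so it is saved
    next to the imzML file as ``<stem>.spots.csv`` and restored by
    :func:`read_imzml`.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    core_codes = {c: i for i, c in enumerate(sset.spots["core_id"].unique())}
    with ImzMLWriter(str(path), mode="continuous") as w:
        seen: dict[str, int] = {}
        for i, (spot_id, row) in enumerate(sset.spots.iterrows()):
            core = row["core_id"]
            seen[core] = seen.get(core, 0) + 1
            w.addSpectrum(sset.mz, sset.intensities[i], (seen[core], core_codes[core] + 1))
    sset.spots.to_csv(path.with_suffix(".spots.csv"))


def read_imzml(path) -> SpectrumSet:
    """Read imzML written by :func:`write_imzml` back into a SpectrumSet."""
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    mz0, _ = parser.getspectrum(0)
    intensities = np.empty((len(parser.coordinates), len(mz0)))
    for i in range(len(parser.coordinates)):
        mz, inten = parser.getspectrum(i)
        intensities[i] = inten
    spots = pd.read_csv(path.with_suffix(".spots.csv"), index_col=0)
    return SpectrumSet(mz=np.asarray(mz0, dtype=float), intensities=intensities, spots=spots)
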