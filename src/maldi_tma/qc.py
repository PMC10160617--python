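"""Batch-effect diagnostics and exploratory embeddings.

A TMA experiment measures arrays on different days; real treatment signal
must therefore be distinguished from technical (batch) variation.  The
diagnostics here mirror the standard control analyses:

- random-group Wilcoxon tests between arbitrary halves of the TMAs (and
  between muscle control cores of those halves): the mean per-feature
  p-value should sit near 0.5 when no batch effect exists, and collapse
  toward 0 only for the biologically meaningful treated-vs-untreated
  split;
- 2-D embeddings (PCA, and UMAP through a thin adapter) for visual
  separation of tissue types and treatment groups;
- stability of muscle-core intensity summaries across TMAs (the muscle
  cores are the internal experimental control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MUSCLE, SYNOVIAL, CohortMeta
from .featstats import wilcoxon_feature
from .preprocess import FeatureMatrix

__all__ = ["GroupSplit", "DEFAULT_SPLITS", "random_group_test", "embed", "muscle_stability"]


@dataclass
class GroupSplit:
    """Two disjoint sets of TMA ids to compare."""

    name: str
    side_a: tuple[int, ...]
    side_b: tuple[int, ...]
    tissue: str = SYNOVIAL

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a split must be non-empty")
        if set(self.side_a) & set(self.side_b):
            raise ValueError("split sides must be disjoint")
        if self.tissue not in (SYNOVIAL, MUSCLE):
            raise ValueError("tissue must be 'synovial' or 'muscle'")


#: the four published control splits over the six large TMAs (2-7)
DEFAULT_SPLITS = (
    GroupSplit("tma_group_1", (2, 3, 4), (5, 6, 7), SYNOVIAL),
    GroupSplit("tma_group_2", (2, 4, 6), (3, 5, 7), SYNOVIAL),
    GroupSplit("muscle_group_1", (2, 3, 4), (5, 6, 7), MUSCLE),
    GroupSplit("muscle_group_2", (2, 4, 6), (3, 5, 7), MUSCLE),
)


def _aggregate_independent_units(fm: FeatureMatrix, tissue: str):
    """Collapse spectra to independent sampling units for rank tests.

    The spectra of one patient (or one muscle core) are correlated, so a
    rank test over raw spectra is anti-conservative under the null —
    patient-level random variation masquerades as a group difference.
    Synovial spectra are averaged per patient (a patient's duplicate
    cores sit on one TMA), muscle spectra per core.
    """
    if fm.unit_level != "spectrum":
        mask = np.ones(fm.n_units, dtype=bool)
        return fm.values, fm.units["tma"].to_numpy(), mask
    units = fm.units
    sel = (units["tissue"] == tissue).to_numpy()
    key = units["patient_id"] if tissue == SYNOVIAL else units["core_id"]
    df = pd.DataFrame(fm.values[sel])
    df["_key"] = key.to_numpy()[sel]
    df["_tma"] = units["tma"].to_numpy()[sel]
    agg = df.groupby("_key", sort=True).agg(
        {**{c: "mean" for c in df.columns[:-2]}, "_tma": "first"}
    )
    return agg.iloc[:, :-1].to_numpy(), agg["_tma"].to_numpy(), sel


def random_group_test(fm: FeatureMatrix, meta: CohortMeta, split: GroupSplit) -> float:
    """Mean per-feature two-sided Wilcoxon p-value between two TMA groups.

    Spectra are first collapsed to independent units (patient means for
    synovial tissue, core means for muscle; see
    :func:`_aggregate_independent_units`).  Values near 0.5 are
    consistent with no systematic difference (p is uniform under the
    null); values near 0 indicate a pervasive shift.
    """
    if fm.units is None or "tma" not in fm.units.columns:
        raise ValueError("feature matrix must carry TMA lineage")
    if "tissue" in fm.units.columns:
        values, tmas, _ = _aggregate_independent_units(fm, split.tissue)
    else:
        values, tmas = fm.values, fm.units["tma"].to_numpy()
    in_a = np.isin(tmas, split.side_a)
    in_b = np.isin(tmas, split.side_b)
    if not in_a.any() or not in_b.any():
        raise ValueError(f"split {split.name!r}: a side is empty after tissue filtering")
    A = values[in_a]
    B = values[in_b]
    pvals = [wilcoxon_feature(A[:, j], B[:, j]) for j in range(values.shape[1])]
    return float(np.mean(pvals))


def treated_vs_untreated_test(fm: FeatureMatrix, meta: CohortMeta) -> float:
    """Mean per-feature Wilcoxon p for the biological (treatment) split."""
    if fm.units is None:
        raise ValueError("feature matrix must carry lineage")
    if fm.unit_level == "patient":
        y = meta.labels_for(fm.unit_ids).to_numpy()
    else:
        syn = fm.units["patient_id"].notna().to_numpy()
        fm = fm.subset_units(syn)
        y = meta.patients.loc[fm.units["patient_id"], "group"].to_numpy()
    A = fm.values[y == 0]
    B = fm.values[y == 1]
    pvals = [wilcoxon_feature(A[:, j], B[:, j]) for j in range(fm.n_features)]
    return float(np.mean(pvals))


def embed(
    fm: FeatureMatrix,
    method: str = "pca",
    seed: int = 0,
    n_neighbors: int = 2,
    min_dist: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """2-D embedding of the units for visual exploration.

    PCA is the first-line view; UMAP (defaults n_neighbors=2,
    min_dist=0.3) is available as an alternative through umap-learn.
    Returns the coordinates (indexed by unit, with lineage columns for
    plotting) and a metadata dict recording method and parameters.
    """
    if fm.n_units < 3:
        raise ValueError("need at least 3 units to embed")
    method = method.lower()
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=2, random_state=seed % (2**31))
        coords = pca.fit_transform(fm.values)
        info = {
            "method": "pca",
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        }
    elif method == "umap":
        import umap

        # with very small n_neighbors the k-NN graph is typically
        # disconnected and UMAP's spectral initialization falls back to an
        # unseeded eigensolver start; seeded random init keeps the
        # embedding exactly reproducible
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            init="random",
            random_state=seed % (2**31),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*not fully connected.*")
            coords = reducer.fit_transform(fm.values)
        info = {
            "method": "umap",
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "init": "random",
        }
    else:
        raise ValueError("method must be 'pca' or 'umap'")
    info["seed"] = seed
    df = pd.DataFrame(coords, index=fm.unit_ids, columns=["dim1", "dim2"])
    if fm.units is not None:
        for col in ("tissue", "tma", "patient_id", "group"):
            if col in fm.units.columns:
                df[col] = fm.units[col].to_numpy()
    return df, info


def muscle_stability(fm: FeatureMatrix, meta: CohortMeta, cv_bound: float = 0.5) -> pd.DataFrame:
    """Coefficient of variation of muscle-core mean intensity across TMAs.

    The muscle cores are the internal experimental control; their
    per-TMA summary intensities should be stable (CV below ``cv_bound``).
    Returns a per-TMA table with an overall CV in ``.attrs``.

    Use the *raw* (pre-TIC) aligned matrix: after TIC normalization every
    spectrum's mean intensity is 1/n_bins by construction and the check
    is vacuous.
    """
    if fm.units is None or "tissue" not in fm.units.columns:
        raise ValueError("feature matrix must carry tissue lineage")
    mus = fm.subset_units((fm.units["tissue"] == MUSCLE).to_numpy())
    if mus.n_units == 0:
        raise ValueError("no muscle spectra in the matrix")
    per_spot = mus.values.mean(axis=1)
    tab = (
        pd.DataFrame({"tma": mus.units["tma"].to_numpy(), "mean_intensity": per_spot})
        .groupby("tma")["mean_intensity"]
        .mean()
        .to_frame()
    )
    cv = float(tab["mean_intensity"].std(ddof=0) / tab["mean_intensity"].mean())
    tab.attrs["cv_across_tmas"] = cv
    tab.attrs["cv_bound"] = cv_bound
    tab.attrs["stable"] = cv < cv_bound
    return tab
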