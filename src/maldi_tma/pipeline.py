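"""End-to-end orchestration: generate -> preprocess -> screen -> classify -> QC.

A run is fully described by a serializable :class:`RunConfig`; ``run_all``
executes the stages into an output directory whose contents (feature
statistics table, the 12-row classification-strategies table, QC report,
config + hash, log) are byte-identical across re-runs with the same
master seed.  Per-stage seeds are derived deterministically from the
master seed, so one knob reproduces everything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CohortClassifier,
    CVScheme,
    max_class_guess,
    random_weighted_guess,
)
from .cohort import CohortMeta, SpectrumSet
from .featstats import ForwardSelectionConfig, SelectionConfig, feature_stats
from .preprocess import align_masses, filter_annotated, patient_mean_spectra, tic_normalize
from .qc import DEFAULT_SPLITS, embed, muscle_stability, random_group_test
from .synth import CohortConfig, FeaturePanel, NoiseModel, generate_cohort

logger = logging.getLogger("maldi_tma")

__all__ = ["RunConfig", "run_all", "classification_table", "stage_seed"]


@dataclass
class RunConfig:
    """Complete, serializable description of a pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    panel: FeaturePanel | None = None  # None -> default 48-feature panel
    bin_width: float = 0.5
    selection: tuple[SelectionConfig, ...] = (
        SelectionConfig(auroc_threshold=0.7),
        SelectionConfig(auroc_threshold=0.75),
    )
    forward: ForwardSelectionConfig = field(default_factory=ForwardSelectionConfig)
    kfold_k: int = 10
    master_seed: int = 0

    def resolved_panel(self) -> FeaturePanel:
        return self.panel if self.panel is not None else FeaturePanel.default()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cohort": asdict(self.cohort),
            "noise": asdict(self.noise),
            "panel": None if self.panel is None else self.panel.to_records(),
            "bin_width": self.bin_width,
            "selection": [asdict(s) for s in self.selection],
            "forward": asdict(self.forward),
            "kfold_k": self.kfold_k,
            "master_seed": self.master_seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = d.get("cohort", {})
        if isinstance(cohort, dict):
            cohort.setdefault("tma_layout", (116,) * 6 + (38,))
            cohort["tma_layout"] = tuple(cohort["tma_layout"])
            if "tma_ids" in cohort:
                cohort["tma_ids"] = tuple(cohort["tma_ids"])
            cohort = CohortConfig(**cohort)
        panel = d.get("panel")
        return cls(
            cohort=cohort,
            noise=NoiseModel(**d.get("noise", {})),
            panel=None if panel is None else FeaturePanel.from_records(panel),
            bin_width=d.get("bin_width", 0.5),
            selection=tuple(SelectionConfig(**s) for s in d.get("selection", [])),
            forward=ForwardSelectionConfig(**d.get("forward", {})),
            kfold_k=d.get("kfold_k", 10),
            master_seed=d.get("master_seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def classification_table(
    fm_spec,
    fm_pat,
    meta: CohortMeta,
    cfg: RunConfig,
) -> pd.DataFrame:
    """All classification strategies as one table (the 12-row analog).

    Sections: (A) spectrum-level LDA with majority vote (LOOCV and
    k-fold); (B) LDA/SVM on patient mean spectra (LOOCV and k-fold);
    (C) LDA/SVM on AUROC-screened features; (D) LDA/SVM on forward
    stepwise selected features.  Screening in (C)/(D) runs inside each
    training fold.
    """
    seed = stage_seed(cfg.master_seed, "cv")
    rows = []

    def add(section, clf):
        res = clf.fit()
        row = {"section": section, **res.report.as_dict()}
        rows.append(row)
        logger.info(
            "section %s: %s %s %s -> %s%%",
            section,
            row["model"],
            row["cv"],
            row["unit_level"],
            row["accuracy_pct"],
        )
        return res

    # (A) spectrum level, LDA, majority vote.  Folds are grouped by
    # patient (with ungrouped splits, sibling spectra of a test spectrum's
    # patient sit in the training set and the pseudo-replicated patient
    # signature inflates the estimate) and the covariance is taken
    # diagonal: the spectra of one patient are correlated, so the
    # effective covariance sample size is the number of patients, fewer
    # than the features (docs/methods.md).
    for kind in ("loocv", "kfold"):
        scheme = CVScheme(kind, k=cfg.kfold_k, group_by_patient=True, seed=seed)
        add("A", CohortClassifier(fm_spec, meta, "lda", scheme, vote=True, shrinkage="diag"))

    # (B) patient mean spectra
    for model in ("lda", "svm"):
        for kind in ("loocv", "kfold"):
            scheme = CVScheme(kind, k=cfg.kfold_k, seed=seed)
            add("B", CohortClassifier(fm_pat, meta, model, scheme))

    # (C) AUROC-screened features (k-fold, nested screening)
    for model in ("lda", "svm"):
        for sel in cfg.selection:
            scheme = CVScheme("kfold", k=cfg.kfold_k, seed=seed)
            add(
                f"C(auroc>={sel.auroc_threshold})",
                CohortClassifier(fm_pat, meta, model, scheme, feature_selector=("auroc", sel)),
            )

    # (D) forward stepwise selection (k-fold, nested selection)
    fwd = replace(cfg.forward, seed=stage_seed(cfg.master_seed, "forward"))
    for model in ("lda", "svm"):
        scheme = CVScheme("kfold", k=cfg.kfold_k, seed=seed)
        add("D", CohortClassifier(fm_pat, meta, model, scheme, feature_selector=("forward", fwd)))

    table = pd.DataFrame(rows)
    y = meta.labels_for(fm_pat.unit_ids).to_numpy()
    table.attrs["max_class_guess"] = max_class_guess(y)
    table.attrs["random_weighted_guess"] = random_weighted_guess(y)
    return table


def run_all(cfg: RunConfig, output_dir, skip_qc: bool = False, write_spectra: bool = False) -> Path:
    """Execute the full pipeline into ``output_dir``; returns the path.

    Outputs: ``config.yaml`` (+hash), ``patients.csv``/``cores.csv``,
    ``feature_stats.csv`` (screening table analog),
    ``classification.csv`` (strategy table analog), ``qc.csv`` and
    ``embedding_pca.csv`` unless ``skip_qc``, and a ``run.log``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        chash = cfg.config_hash()
        logger.info("maldi-tma %s | config hash %s", __version__, chash)
        cfg.to_yaml(out / "config.yaml")

        stage = "generate"
        try:
            cohort_cfg = replace(cfg.cohort, seed=stage_seed(cfg.master_seed, "cohort"))
            sset, meta = generate_cohort(cohort_cfg, cfg.resolved_panel(), cfg.noise)
            meta.to_csv(out / "patients.csv", out / "cores.csv")
            if write_spectra:
                from .preprocess import write_imzml

                write_imzml(sset, out / "spectra.imzML")

            stage = "preprocess"
            fm_all = align_masses(tic_normalize(sset), cfg.bin_width)
            fm_syn = filter_annotated(fm_all, meta)
            fm_pat = patient_mean_spectra(fm_syn, meta)

            stage = "screen"
            y_pat = meta.labels_for(fm_pat.unit_ids).to_numpy()
            stats = feature_stats(fm_pat, y_pat, cfg.resolved_panel())
            stats.insert(0, "config_hash", chash)
            stats.to_csv(out / "feature_stats.csv", index=False)
            for sel in cfg.selection:
                n_sel = int(
                    (
                        (np.maximum(stats["auroc"], 1 - stats["auroc"]) >= sel.auroc_threshold)
                        & (stats["p_value"] <= sel.p_threshold)
                    ).sum()
                )
                logger.info(
                    "screen auroc>=%s p<=%s: %d features", sel.auroc_threshold, sel.p_threshold, n_sel
                )

            stage = "classify"
            table = classification_table(fm_syn, fm_pat, meta, cfg)
            table.insert(0, "config_hash", chash)
            table.to_csv(out / "classification.csv", index=False)
            baselines = {
                "max_class_guess": table.attrs["max_class_guess"],
                "random_weighted_guess": table.attrs["random_weighted_guess"],
                "config_hash": chash,
            }
            (out / "baselines.json").write_text(json.dumps(baselines, indent=2, sort_keys=True))

            if not skip_qc:
                stage = "qc"
                qc_rows = []
                for split in DEFAULT_SPLITS:
                    try:
                        p = random_group_test(fm_all, meta, split)
                    except ValueError:
                        continue
                    qc_rows.append(
                        {"config_hash": chash, "split": split.name, "tissue": split.tissue, "mean_p": p}
                    )
                # stability control on raw intensities: TIC normalization
                # fixes every spectrum's mean by construction
                fm_raw = align_masses(sset, cfg.bin_width)
                mus = muscle_stability(fm_raw, meta)
                qc_rows.append(
                    {
                        "config_hash": chash,
                        "split": "muscle_cv_across_tmas",
                        "tissue": "muscle",
                        "mean_p": mus.attrs["cv_across_tmas"],
                    }
                )
                pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)
                coords, info = embed(fm_all, "pca", seed=stage_seed(cfg.master_seed, "embed"))
                coords.to_csv(out / "embedding_pca.csv")
                _plot_embedding(coords, info, out / "embedding_pca.png")
        except Exception as exc:
            (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _plot_embedding(coords: pd.DataFrame, info: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    hue = coords["tissue"] if "tissue" in coords.columns else None
    if hue is not None:
        for tissue, sub in coords.groupby(hue):
            ax.scatter(sub["dim1"], sub["dim2"], s=4, alpha=0.5, label=str(tissue))
        ax.legend(markerscale=3, fontsize=8)
    else:
        ax.scatter(coords["dim1"], coords["dim2"], s=4, alpha=0.5)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(info["method"].upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
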