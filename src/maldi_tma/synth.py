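"""Synthetic MALDI-MSI TMA cohort generator.

Emulates the statistical structure of a two-arm synovial-tissue cohort
measured on tissue microarrays: patients carrying a treatment label
(LpPRP-1 treated / LpPRP-0 untreated), two cores per patient distributed
over seven TMAs, muscle control cores on every TMA, and a planted panel of
discriminative m/z features whose per-feature AUROCs are prescribed
exactly.

Signal model
------------
Each patient has a latent scalar "treatment response" t_p ~ N(+Delta/2, 1)
for treated and N(-Delta/2, 1) for untreated patients.  A discriminative
feature with target AUROC ``a`` gets a loading

    beta_j = delta_j / Delta,     delta_j = sqrt(2) * Phi^{-1}(a),

and the patient-level latent value of feature j is

    l_pj = beta_j * t_p + sqrt(1 - beta_j^2) * z_pj,   z_pj ~ N(0, 1),

so the class-conditional marginals are N(+/- delta_j/2, 1) and the
patient-level AUROC of feature j is exactly Phi(delta_j / sqrt(2)) = a.
Because all class information flows through the single axis t_p, the joint
(Bayes) patient-level accuracy is capped at Phi(Delta/2) regardless of how
many panel features are planted — features are informative but mutually
redundant, as peptides of the same proteins are.  Spot-level spectra add
independent Gaussian noise around the patient latent, and intensities are
the exponential of the latent (log-normal positive intensities; rank
statistics such as AUROC are invariant to this monotone map).

Background features have identical class-conditional distributions by
construction; muscle control cores carry a disjoint dominant peak set and
no class signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import GROUP_NAMES, MUSCLE, SYNOVIAL, CohortMeta, SpectrumSet

__all__ = [
    "CohortConfig",
    "FeaturePanel",
    "PanelEntry",
    "NoiseModel",
    "TABLE_PANEL",
    "calibrate_effect_size",
    "generate_cohort",
    "simulate_annotation_loss",
    "sample_patient_intensities",
]

#: The 16 identified discriminative tryptic peptides used as the default
#: planted panel: (m/z, target AUROC with LpPRP-1 positive, protein, UniProt).
TABLE_PANEL: tuple[tuple[float, float, str, str], ...] = (
    (961.49, 0.26, "Collagen alpha-1(III) chain", "P02461"),
    (1121.54, 0.74, "IL-1 receptor accessory protein precursor", "Q9NPH3"),
    (1137.74, 0.29, "Receptor-type tyrosine-protein phosphatase C (CD45)", "P08575"),
    (1138.5, 0.78, "Collagen alpha-2(IX) chain", "Q14055"),
    (1140.65, 0.78, "Integrin beta-1 (CD29)", "P05556"),
    (1141.6, 0.70, "Proteoglycan 4 (Lubricin)", "Q92954"),
    (1510.72, 0.28, "Receptor-type tyrosine-protein phosphatase C (CD45)", "P08575"),
    (1512.73, 0.28, "Receptor-type tyrosine-protein phosphatase C (CD45)", "P08575"),
    (1671.8, 0.71, "Interleukin-17 receptor E", "Q8NFR9"),
    (1672.8, 0.72, "Collagen alpha-1(I) chain precursor", "P02452"),
    (1759.9, 0.28, "Collagen alpha-1(II) chain", "P02458"),
    (1816.94, 0.71, "Collagen alpha-1(I) chain precursor", "P02452"),
    (1818.94, 0.72, "Receptor-type tyrosine-protein phosphatase C (CD45)", "P08575"),
    (1850.1, 0.23, "Protein S100-A11 (Calgizzarin)", "P31949"),
    (2164.1, 0.75, "Interleukin-17 receptor E", "Q8NFR9"),
    (2303.17, 0.6, "Proteoglycan 4 (Lubricin)", "Q92954"),
)

MZ_LO, MZ_HI = 600.0, 3200.0

# fixed seed for the padded default panel: the panel is configuration, not
# a random draw of each run
_PANEL_PAD_SEED = 20230421 % (2**31)


def calibrate_effect_size(target_auroc: float) -> float:
    """Standardized class-mean shift realizing a target AUROC.

    For two Gaussian class conditionals with equal unit variance and mean
    difference delta, AUROC = Phi(delta / sqrt(2)); inverting gives
    ``delta = sqrt(2) * Phi^{-1}(target_auroc)`` (negative below 0.5).

    Raises
    ------
    ValueError
        If ``target_auroc`` is not strictly inside (0, 1) — perfect
        separation would need an infinite shift.
    """
    if not 0.0 < target_auroc < 1.0:
        raise ValueError(
            f"target_auroc must be in (0, 1), got {target_auroc!r} "
            "(0 or 1 would require an infinite shift)"
        )
    return math.sqrt(2.0) * float(norm.ppf(target_auroc))


@dataclass(frozen=True)
class PanelEntry:
    """One planted discriminative feature."""

    mz: float
    target_auroc: float
    annotation: str | None = None

    @property
    def direction(self) -> str:
        return "up_in_treated" if self.target_auroc > 0.5 else "up_in_untreated"


@dataclass
class FeaturePanel:
    """A set of discriminative m/z features with prescribed AUROCs."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        mzs = [e.mz for e in self.entries]
        if len(set(mzs)) != len(mzs):
            raise ValueError("panel m/z values must be unique")
        for e in self.entries:
            if not 0.0 < e.target_auroc < 1.0:
                raise ValueError(f"target_auroc out of (0,1) for m/z {e.mz}")
            if not MZ_LO <= e.mz <= MZ_HI:
                raise ValueError(f"panel m/z {e.mz} outside [{MZ_LO}, {MZ_HI}]")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mz(self) -> np.ndarray:
        return np.array([e.mz for e in self.entries])

    @property
    def target_auroc(self) -> np.ndarray:
        return np.array([e.target_auroc for e in self.entries])

    def entry_for(self, mz: float) -> PanelEntry:
        for e in self.entries:
            if e.mz == mz:
                return e
        raise KeyError(f"no panel entry at m/z {mz}")

    @classmethod
    def default(cls, n_padding: int = 32) -> "FeaturePanel":
        """The identified 16-peptide panel padded to 48 planted features.

        Padding entries are unannotated m/z positions with target AUROC
        drawn (with a fixed internal seed — the default panel is a
        constant) from [0.72, 0.80] for half of them and [0.20, 0.28] for
        the other half, a margin above/below the 0.7 screening threshold.
        """
        entries = [PanelEntry(mz, a, f"{name} ({acc})") for mz, a, name, acc in TABLE_PANEL]
        rng = np.random.default_rng(_PANEL_PAD_SEED)
        taken = [e.mz for e in entries]
        for i in range(n_padding):
            while True:
                mz = float(rng.uniform(MZ_LO + 20, MZ_HI - 20))
                if all(abs(mz - t) >= 2.0 for t in taken):
                    break
            taken.append(mz)
            if i % 2 == 0:
                a = float(rng.uniform(0.72, 0.80))
            else:
                a = float(rng.uniform(0.20, 0.28))
            entries.append(PanelEntry(round(mz, 2), round(a, 3)))
        return cls(entries)

    def to_records(self) -> list[dict]:
        return [
            {"mz": e.mz, "target_auroc": e.target_auroc, "annotation": e.annotation}
            for e in self.entries
        ]

    @classmethod
    def from_records(cls, records) -> "FeaturePanel":
        return cls([PanelEntry(r["mz"], r["target_auroc"], r.get("annotation")) for r in records])


@dataclass
class CohortConfig:
    """Cohort shape and demographics.

    Defaults reproduce the classification cohort: 128 treated + 161
    untreated patients, duplicate 1-mm cores over six 116-core TMAs plus
    one 38-core TMA, four muscle control cores per TMA.  The full enrolled
    cohort (163 treated / 204 untreated, 367 patients, filling the TMA
    capacity exactly) is obtained by overriding the two patient counts.
    ``spectra_per_core`` defaults to a desk scale of 20 spectra; the
    instrument-scale value (~99 per core) is a knob.
    """

    n_patients_treated: int = 128
    n_patients_untreated: int = 161
    cores_per_patient: int = 2
    tma_layout: tuple[int, ...] = (116, 116, 116, 116, 116, 116, 38)
    muscle_cores_per_tma: int = 4
    spectra_per_core: int = 20
    age_mean_treated: float = 53.8
    age_mean_untreated: float = 54.6
    age_sd: float = 9.8
    seed: int = 0

    #: TMA identifiers; the six large TMAs are numbered 2-7 and the small
    #: 38-core TMA is number 8.
    tma_ids: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)

    def __post_init__(self) -> None:
        counts = (
            self.n_patients_treated,
            self.n_patients_untreated,
            self.cores_per_patient,
            self.muscle_cores_per_tma,
            self.spectra_per_core,
        )
        if any(int(c) <= 0 for c in counts[:3]) or any(int(c) < 0 for c in counts[3:]):
            raise ValueError("cohort counts must be strictly positive")
        if len(self.tma_ids) != len(self.tma_layout):
            raise ValueError("tma_ids and tma_layout must have equal length")
        needed = (self.n_patients_treated + self.n_patients_untreated) * self.cores_per_patient
        if self.capacity_cores < needed:
            raise ValueError(
                f"TMA layout capacity ({self.capacity_cores} synovial cores) cannot hold "
                f"{self.n_patients} patients x {self.cores_per_patient} cores = {needed} cores"
            )

    @property
    def n_patients(self) -> int:
        return self.n_patients_treated + self.n_patients_untreated

    @property
    def capacity_cores(self) -> int:
        # each patient's duplicate cores sit on one TMA, so per-TMA capacity
        # is floor(cores / cores_per_patient) patients
        return sum(
            (c // self.cores_per_patient) * self.cores_per_patient for c in self.tma_layout
        )


@dataclass
class NoiseModel:
    """Distributional knobs of the generator.

    All scales act on the log-intensity (latent Gaussian) axis.

    - ``between_patient_sd``: total patient-level SD per feature (the
      AUROC calibration is relative to it, so it rescales the log-axis
      without changing any rank statistic; the default 0.35 corresponds
      to a realistic ~35% between-patient intensity CV).
    - ``within_patient_sd``: spot-to-spot SD around the patient latent.
    - ``baseline_intensity``: median peak magnitude on the raw intensity
      scale; per-channel base log-intensities scatter around its log.
    - ``muscle_profile_shift``: log-intensity offset separating the muscle
      peak set from the synovial profile in muscle cores.
    - ``class_separation``: Delta, the distance between the class means of
      the latent treatment-response axis; Phi(Delta/2) bounds the
      patient-level Bayes accuracy (default 2.0 -> ~0.84).
    """

    n_background_peaks: int = 300
    within_patient_sd: float = 0.2
    between_patient_sd: float = 0.35
    baseline_intensity: float = 1.0
    muscle_profile_shift: float = 3.0
    n_muscle_peaks: int = 40
    class_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.within_patient_sd < 0 or self.between_patient_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be > 0")


def _draw_positions(rng, n, taken, min_spacing=1.2):
    """Random m/z positions keeping a minimum spacing from existing ones."""
    taken = list(taken)
    out = []
    while len(out) < n:
        mz = float(rng.uniform(MZ_LO + 5, MZ_HI - 5))
        if all(abs(mz - t) >= min_spacing for t in taken):
            taken.append(mz)
            out.append(mz)
    return np.array(out)


def generate_cohort(
    config: CohortConfig | None = None,
    panel: FeaturePanel | None = None,
    noise: NoiseModel | None = None,
) -> tuple[SpectrumSet, CohortMeta]:
    """Generate a synthetic TMA cohort.

    Returns the spectra (shared m/z axis, one row per spot) and the cohort
    metadata with complete spot -> core -> TMA -> patient lineage.  Output
    is a pure function of the configuration: the same seed reproduces the
    dataset bit for bit.
    """
    config = config or CohortConfig()
    panel = panel if panel is not None else FeaturePanel.default()
    noise = noise or NoiseModel()
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")

    rng = np.random.default_rng(config.seed)

    # ---- m/z axis: panel + background + muscle channels ---------------
    mz_panel = panel.mz
    mz_bg = _draw_positions(rng, noise.n_background_peaks, mz_panel)
    mz_mus = _draw_positions(rng, noise.n_muscle_peaks, np.concatenate([mz_panel, mz_bg]))
    mz_all = np.concatenate([mz_panel, mz_bg, mz_mus])
    kind = np.array(
        ["panel"] * len(mz_panel) + ["background"] * len(mz_bg) + ["muscle"] * len(mz_mus)
    )
    order = np.argsort(mz_all)
    mz_all, kind = mz_all[order], kind[order]
    n_ch = mz_all.size
    is_panel = kind == "panel"
    is_mus = kind == "muscle"

    # ---- loadings on the latent treatment-response axis ----------------
    delta = np.zeros(n_ch)
    panel_auroc = {e.mz: e.target_auroc for e in panel.entries}
    delta[is_panel] = [calibrate_effect_size(panel_auroc[m]) for m in mz_all[is_panel]]
    beta = delta / noise.class_separation
    if np.any(np.abs(beta) >= 1.0):
        worst = float(np.abs(delta).max())
        raise ValueError(
            "class_separation too small for the panel: needs > "
            f"{worst:.3f} (largest per-feature shift)"
        )
    resid_sd = np.sqrt(1.0 - beta**2)

    # ---- per-channel base log-intensities ------------------------------
    base = math.log(noise.baseline_intensity) + 0.5 * rng.standard_normal(n_ch)
    syn_base = base.copy()
    syn_base[is_mus] -= noise.muscle_profile_shift
    mus_base = base.copy()
    mus_base[~is_mus] -= noise.muscle_profile_shift
    mus_base[is_mus] += noise.muscle_profile_shift

    # ---- patients, cores, TMA placement --------------------------------
    n_pat = config.n_patients
    groups = np.array([1] * config.n_patients_treated + [0] * config.n_patients_untreated)
    rng.shuffle(groups)
    patient_ids = np.array([f"P{i + 1:04d}" for i in range(n_pat)])
    ages = np.where(
        groups == 1,
        rng.normal(config.age_mean_treated, config.age_sd, n_pat),
        rng.normal(config.age_mean_untreated, config.age_sd, n_pat),
    ).round(1)
    sexes = rng.choice(["F", "M"], size=n_pat)

    pat_tma = np.empty(n_pat, dtype=int)
    slots = [
        (tid, cap // config.cores_per_patient)
        for tid, cap in zip(config.tma_ids, config.tma_layout)
    ]
    i = 0
    for tid, n_slots in slots:
        take = min(n_slots, n_pat - i)
        pat_tma[i : i + take] = tid
        i += take
        if i == n_pat:
            break

    patients = pd.DataFrame(
        {"group": groups, "age": ages, "sex": sexes, "tma": pat_tma},
        index=pd.Index(patient_ids, name="patient_id"),
    )

    core_rows = []
    for pid, tma in zip(patient_ids, pat_tma):
        for k in range(config.cores_per_patient):
            core_rows.append((f"{pid}-c{k + 1}", pid, tma, SYNOVIAL, True))
    for tid in config.tma_ids:
        for k in range(config.muscle_cores_per_tma):
            core_rows.append((f"T{tid}-M{k + 1}", pd.NA, tid, MUSCLE, True))
    cores = pd.DataFrame(
        core_rows, columns=["core_id", "patient_id", "tma", "tissue", "annotated"]
    ).set_index("core_id")
    meta = CohortMeta(patients=patients, cores=cores)

    # ---- latent draws ---------------------------------------------------
    t = rng.standard_normal(n_pat) + np.where(
        groups == 1, noise.class_separation / 2.0, -noise.class_separation / 2.0
    )
    z = rng.standard_normal((n_pat, n_ch))
    pat_latent = noise.between_patient_sd * (np.outer(t, beta) + z * resid_sd)

    syn_cores = cores[cores["tissue"] == SYNOVIAL]
    m = config.spectra_per_core
    pat_index = {pid: i for i, pid in enumerate(patient_ids)}

    spot_rows = []
    spot_pat_idx = []
    for core_id, row in syn_cores.iterrows():
        pi = pat_index[row["patient_id"]]
        for s in range(m):
            spot_rows.append(
                (f"{core_id}-s{s + 1:03d}", core_id, row["patient_id"], row["tma"], SYNOVIAL)
            )
            spot_pat_idx.append(pi)
    spot_pat_idx = np.array(spot_pat_idx, dtype=int)
    n_syn_spots = len(spot_rows)

    syn_latent = (
        syn_base[None, :]
        + pat_latent[spot_pat_idx]
        + noise.within_patient_sd * rng.standard_normal((n_syn_spots, n_ch))
    )

    mus_cores = cores[cores["tissue"] == MUSCLE]
    mus_core_latent = noise.between_patient_sd * rng.standard_normal((len(mus_cores), n_ch))
    mus_rows = []
    mus_core_idx = []
    for ci, (core_id, row) in enumerate(mus_cores.iterrows()):
        for s in range(m):
            mus_rows.append((f"{core_id}-s{s + 1:03d}", core_id, pd.NA, row["tma"], MUSCLE))
            mus_core_idx.append(ci)
    mus_core_idx = np.array(mus_core_idx, dtype=int)
    mus_latent = (
        mus_base[None, :]
        + mus_core_latent[mus_core_idx]
        + noise.within_patient_sd * rng.standard_normal((len(mus_rows), n_ch))
    )

    spots = pd.DataFrame(
        spot_rows + mus_rows,
        columns=["spot_id", "core_id", "patient_id", "tma", "tissue"],
    ).set_index("spot_id")
    intensities = np.exp(np.vstack([syn_latent, mus_latent]))

    return SpectrumSet(mz=mz_all, intensities=intensities, spots=spots), meta


def simulate_annotation_loss(
    meta: CohortMeta,
    loss_fraction: float = 0.0,
    seed: int = 0,
    n_patients_lost: int | None = None,
) -> CohortMeta:
    """Mark a random subset of synovial cores as unannotatable.

    ``loss_fraction`` drops each synovial core independently; a patient
    whose cores are all unannotated disappears from the classification
    analysis.  ``n_patients_lost`` instead (or additionally) removes all
    cores of exactly that many randomly chosen patients — the mode that
    emulates a known count of unusable patients.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in [0, 1)")
    out = meta.copy()
    rng = np.random.default_rng(seed)

    lost_patients = np.array([], dtype=object)
    if n_patients_lost:
        if n_patients_lost >= meta.n_patients:
            raise ValueError("cannot lose all patients")
        lost_patients = rng.choice(
            meta.patients.index.to_numpy(), size=n_patients_lost, replace=False
        )
        lost_mask = out.cores["patient_id"].isin(lost_patients)
        out.cores.loc[lost_mask, "annotated"] = False

    if loss_fraction > 0.0:
        syn = out.cores["tissue"] == SYNOVIAL
        eligible = syn & ~out.cores["patient_id"].isin(lost_patients)
        drop = rng.random(len(out.cores)) < loss_fraction
        out.cores.loc[eligible & drop, "annotated"] = False

    return out


def sample_patient_intensities(
    target_auroc: float,
    n_untreated: int,
    n_treated: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw patient-level intensities from one feature's class conditionals.

    The marginal patient-level model of a planted feature is log-normal:
    exp(N(-delta/2, 1)) for untreated and exp(N(+delta/2, 1)) for treated
    patients, with ``delta = calibrate_effect_size(target_auroc)``.
    Returns ``(untreated, treated)`` intensity arrays.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    delta = calibrate_effect_size(target_auroc)
    x0 = np.exp(rng.normal(-delta / 2.0, 1.0, size=n_untreated))
    x1 = np.exp(rng.normal(+delta / 2.0, 1.0, size=n_treated))
    return x0, x1
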