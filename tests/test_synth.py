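"""Generator tests: effect-size calibration, cohort shape, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from maldi_tma import (
    CohortConfig,
    FeaturePanel,
    NoiseModel,
    calibrate_effect_size,
    generate_cohort,
    sample_patient_intensities,
    simulate_annotation_loss,
)
from maldi_tma.synth import TABLE_PANEL

from conftest import SMALL_CONFIG, SMALL_NOISE


class TestCalibrateEffectSize:
    def test_no_separation_is_zero_shift(self):
        assert calibrate_effect_size(0.5) == 0.0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_targets_rejected(self, bad):
        with pytest.raises(ValueError):
            calibrate_effect_size(bad)

    def test_antisymmetry(self):
        assert calibrate_effect_size(0.26) == pytest.approx(-calibrate_effect_size(0.74))

    def test_monte_carlo_auroc_of_shifted_normals(self):
        """Independent oracle: two unit-variance normals shifted by delta
        must produce an empirical AUROC equal to the calibration target."""
        rng = np.random.default_rng(123)
        n = 100_000
        for target in (0.74, 0.6, 0.29):
            delta = calibrate_effect_size(target)
            x0 = rng.normal(0.0, 1.0, n)
            x1 = rng.normal(delta, 1.0, n)
            emp = np.mean(x1[rng.integers(0, n, n)] > x0[rng.integers(0, n, n)])
            assert emp == pytest.approx(target, abs=0.006)

    @given(st.floats(0.02, 0.98))
    @settings(max_examples=50, deadline=None)
    def test_closed_form_roundtrip(self, a):
        delta = calibrate_effect_size(a)
        assert norm.cdf(delta / np.sqrt(2)) == pytest.approx(a, abs=1e-9)


class TestFeaturePanel:
    def test_default_panel_composition(self):
        panel = FeaturePanel.default()
        assert len(panel) == 48
        assert len(set(panel.mz)) == 48
        annotated = [e for e in panel.entries if e.annotation]
        assert len(annotated) == len(TABLE_PANEL)
        padded = [e for e in panel.entries if e.annotation is None]
        for e in padded:
            assert 0.20 <= e.target_auroc <= 0.28 or 0.72 <= e.target_auroc <= 0.80

    def test_direction_follows_auroc(self):
        panel = FeaturePanel.default()
        for e in panel.entries:
            expected = "up_in_treated" if e.target_auroc > 0.5 else "up_in_untreated"
            assert e.direction == expected

    def test_duplicate_mz_rejected(self):
        from maldi_tma import PanelEntry

        with pytest.raises(ValueError, match="unique"):
            FeaturePanel([PanelEntry(900.0, 0.7), PanelEntry(900.0, 0.3)])


class TestGenerateCohort:
    def test_default_cohort_shape(self):
        cfg = CohortConfig(spectra_per_core=1, seed=1)
        sset, meta = generate_cohort(cfg)
        assert meta.n_patients == 289
        assert len(meta.synovial_cores()) == 578
        assert len(meta.muscle_cores()) == 28
        assert len(meta.classifiable_patients()) == 289
        assert sset.n_spots == 578 + 28

    def test_minimal_cohort(self):
        cfg = CohortConfig(
            n_patients_treated=1,
            n_patients_untreated=1,
            tma_layout=(4,),
            tma_ids=(2,),
            muscle_cores_per_tma=0,
            spectra_per_core=1,
            seed=0,
        )
        sset, meta = generate_cohort(cfg)
        assert sset.n_spots == 4

    def test_capacity_violation_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            CohortConfig(tma_layout=(116, 38), tma_ids=(2, 3), seed=0)

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(
            n_patients_treated=5,
            n_patients_untreated=6,
            tma_layout=(22,),
            tma_ids=(2,),
            spectra_per_core=2,
            seed=9,
        )
        noise = NoiseModel(n_background_peaks=30, n_muscle_peaks=5)
        a, meta_a = generate_cohort(cfg, noise=noise)
        b, meta_b = generate_cohort(cfg, noise=noise)
        assert np.array_equal(a.mz, b.mz)
        assert np.array_equal(a.intensities, b.intensities)
        assert meta_a.patients.equals(meta_b.patients)

        import dataclasses

        c, _ = generate_cohort(dataclasses.replace(cfg, seed=10), noise=noise)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_lineage_complete(self, small_cohort):
        sset, meta = small_cohort
        assert sset.spots["core_id"].isin(meta.cores.index).all()
        syn = sset.spots[sset.spots["tissue"] == "synovial"]
        assert syn["patient_id"].isin(meta.patients.index).all()
        counts = meta.patients["group"].value_counts()
        assert counts[1] == SMALL_CONFIG.n_patients_treated
        assert counts[0] == SMALL_CONFIG.n_patients_untreated

    def test_class_separation_too_small_rejected(self):
        with pytest.raises(ValueError, match="class_separation"):
            generate_cohort(
                SMALL_CONFIG, FeaturePanel.default(), NoiseModel(class_separation=0.5)
            )


class TestAnnotationLoss:
    def test_zero_loss_is_identity(self, small_cohort):
        _, meta = small_cohort
        out = simulate_annotation_loss(meta, loss_fraction=0.0, seed=3)
        assert out.cores["annotated"].all()

    def test_exact_patient_loss_count(self):
        """Losing all cores of 78 of 367 enrolled patients leaves the
        289-patient classification cohort."""
        cfg = CohortConfig(
            n_patients_treated=163,
            n_patients_untreated=204,
            spectra_per_core=1,
            seed=1,
        )
        _, meta = generate_cohort(cfg)
        assert meta.n_patients == 367
        lost = simulate_annotation_loss(meta, seed=1, n_patients_lost=78)
        assert len(lost.classifiable_patients()) == 289

    def test_reproducible_mask(self, small_cohort):
        _, meta = small_cohort
        a = simulate_annotation_loss(meta, loss_fraction=0.5, seed=11)
        b = simulate_annotation_loss(meta, loss_fraction=0.5, seed=11)
        assert a.cores["annotated"].equals(b.cores["annotated"])
        assert not a.cores["annotated"].all()

    def test_invalid_fraction_rejected(self, small_cohort):
        _, meta = small_cohort
        with pytest.raises(ValueError):
            simulate_annotation_loss(meta, loss_fraction=1.0, seed=0)


class TestPlantedEffects:
    def test_patient_level_auroc_converges_to_target(self):
        """Large-sample empirical AUROC of the class-conditional model
        matches the planted target (closed-form oracle)."""
        from maldi_tma import auroc

        for target in (0.74, 0.26, 0.6):
            x0, x1 = sample_patient_intensities(target, 20_000, 20_000, rng=5)
            assert auroc(x0, x1) == pytest.approx(target, abs=0.01)

    def test_background_features_are_null(self, small_cohort, small_fm_pat, small_labels):
        """Background channels carry no class signal: their AUROCs hover
        around 0.5."""
        sset, meta = small_cohort
        panel_mz = FeaturePanel.default().mz
        from maldi_tma import auroc

        y = small_labels
        vals = small_fm_pat.values
        bg_cols = [
            j
            for j, mz in enumerate(small_fm_pat.mz_bins)
            if np.min(np.abs(panel_mz - mz)) > 1.0
        ]
        aurocs = np.array([auroc(vals[y == 0, j], vals[y == 1, j]) for j in bg_cols])
        assert abs(aurocs.mean() - 0.5) < 0.03
        assert (np.abs(aurocs - 0.5) < 0.35).all()
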