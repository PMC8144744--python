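import numpy as np
import pandas as pd
import pytest

import phase4d as p4
from phase4d.synthetic_data import PhantomDesign, SimulationDesign, phantom_masks

PHASES = p4.core_data.DEFAULT_PHASES


class TestGenPhaseFeatures:
    def test_zero_noise_argmin_at_designed_phase_every_feature(self):
        design = SimulationDesign(n_patients=6, n_features=8, seed=0,
                                  noise_sd=0.0, artifact_rate=0.0)
        table, truth = p4.gen_phase_features(design)
        for roi in ("tumour", "peritumour"):
            wide = table.wide(roi)
            for (pat, feat), row in wide.iterrows():
                dx = p4.neighbour_difference(row.to_numpy(float))
                got = PHASES[int(np.argmin(dx))]
                assert got == truth.designed_phase[pat], (pat, feat)

    def test_seed_reproducibility(self):
        d = SimulationDesign(n_patients=5, n_features=6, seed=3)
        a, ta = p4.gen_phase_features(d)
        b, tb = p4.gen_phase_features(d)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_series_equal(ta.designed_phase, tb.designed_phase)
        c, _ = p4.gen_phase_features(
            SimulationDesign(n_patients=5, n_features=6, seed=4))
        assert not a.data["value"].equals(c.data["value"])

    def test_table_dimensions(self):
        d = SimulationDesign(n_patients=4, n_features=7, seed=1)
        table, _ = p4.gen_phase_features(d)
        assert len(table.data) == 4 * 10 * 2 * 7
        assert table.missing.empty
        assert len(table.features) == 14      # 7 per ROI, roi-qualified names

    def test_artifact_spike_magnitude_and_location(self):
        d = SimulationDesign(n_patients=30, n_features=10, seed=2,
                             noise_sd=0.0, artifact_rate=1.0,
                             artifact_magnitude=1.0,
                             artifact_feature_fraction=1.0)
        table, truth = p4.gen_phase_features(d)
        wide = table.wide("tumour")
        phases = list(PHASES)
        for pat in truth.designed_phase.index:
            art = truth.artifact_phase[pat]
            assert art is not None
            des_i = phases.index(truth.designed_phase[pat])
            art_i = phases.index(art)
            dist = min(abs(art_i - des_i), 10 - abs(art_i - des_i))
            assert dist >= 2      # artifacts stay away from the designed phase
            # noise-free: spike at the artifact phase is exactly +-1.0 off the
            # smooth trajectory; check one feature via the quadratic residual
        block = wide.xs(truth.designed_phase.index[0], level="patient")
        assert block.shape == (10, 10)

    def test_artifact_rate_zero_no_artifacts(self):
        d = SimulationDesign(n_patients=20, n_features=4, seed=5,
                             artifact_rate=0.0)
        _, truth = p4.gen_phase_features(d)
        assert truth.artifact_phase.isna().all()

    def test_designed_phase_prior_peaks_at_exhale(self):
        d = SimulationDesign(n_patients=400, n_features=1, seed=6)
        _, truth = p4.gen_phase_features(d)
        counts = truth.designed_phase.value_counts()
        assert counts.idxmax() in ("40%", "50%", "60%")
        assert counts.get("50%", 0) > counts.get("0%", 0)

    def test_volume_positive_lognormal(self):
        d = SimulationDesign(n_patients=200, n_features=1, seed=7)
        _, truth = p4.gen_phase_features(d)
        assert (truth.volume > 0).all()
        assert 2.0 < truth.volume.median() < 8.0

    def test_invalid_event_fraction(self):
        with pytest.raises(ValueError):
            SimulationDesign(event_fraction=1.0)

    def test_planted_mismatch_raises(self):
        with pytest.raises(ValueError):
            SimulationDesign(planted_features=["a"], planted_log_hr=[])


class TestGenOutcomes:
    def test_null_betas_concordance_near_half(self):
        rng = np.random.default_rng(8)
        d = SimulationDesign(n_patients=300, seed=8, event_fraction=0.5,
                             clinical_log_hr_volume=0.0)
        matrix = pd.DataFrame(rng.normal(size=(300, 5)),
                              columns=[f"f{j}" for j in range(5)],
                              index=[f"P{i:03d}" for i in range(300)])
        survival, clinical = p4.gen_outcomes(matrix, d)
        from phase4d._coxutils import harrell_cindex
        c = harrell_cindex(survival["time"].to_numpy(),
                           survival["event"].to_numpy(float),
                           matrix["f0"].to_numpy())
        assert 0.45 < c < 0.55

    def test_planted_beta_recovered(self):
        rng = np.random.default_rng(9)
        n = 400
        matrix = pd.DataFrame(rng.normal(size=(n, 3)),
                              columns=["f0", "f1", "f2"],
                              index=[f"P{i:03d}" for i in range(n)])
        d = SimulationDesign(n_patients=n, seed=9, event_fraction=0.7,
                             planted_features=["f0"], planted_log_hr=[0.8],
                             clinical_log_hr_volume=0.0)
        survival, _ = p4.gen_outcomes(matrix, d)
        from phase4d._coxutils import fit_cox_fast
        fit = fit_cox_fast(survival["time"].to_numpy(),
                           survival["event"].to_numpy(float),
                           matrix[["f0"]].to_numpy())
        assert fit.beta[0] == pytest.approx(0.8, abs=0.2)

    def test_event_fraction_tuned(self):
        rng = np.random.default_rng(10)
        n = 258
        matrix = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"],
                              index=[f"P{i:03d}" for i in range(n)])
        d = SimulationDesign(n_patients=n, seed=10, event_fraction=0.18)
        survival, _ = p4.gen_outcomes(matrix, d)
        assert abs(survival["event"].mean() - 0.18) <= 0.03

    def test_zero_event_fraction_all_censored(self):
        rng = np.random.default_rng(11)
        matrix = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"],
                              index=[f"P{i:02d}" for i in range(50)])
        d = SimulationDesign(n_patients=50, seed=11, event_fraction=0.0)
        survival, _ = p4.gen_outcomes(matrix, d)
        assert (survival["event"] == 0).all()

    def test_clinical_table_schema_and_ranges(self):
        rng = np.random.default_rng(12)
        matrix = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"],
                              index=[f"P{i:03d}" for i in range(500)])
        d = SimulationDesign(n_patients=500, seed=12)
        survival, clinical = p4.gen_outcomes(matrix, d)
        p4.validate_clinical(clinical)
        p4.validate_survival(survival)
        assert clinical["age"].between(45, 93).all()
        assert set(clinical["lobe"]) <= {"lower", "middle", "upper"}
        assert 0.4 < (clinical["sex"] == "male").mean() < 0.62
        assert clinical["motion_amplitude"].median() == pytest.approx(5.5,
                                                                      rel=0.3)

    def test_missing_planted_feature_raises(self):
        matrix = pd.DataFrame({"a": np.arange(30.0)},
                              index=[f"P{i:02d}" for i in range(30)])
        d = SimulationDesign(n_patients=30, planted_features=["ghost"],
                             planted_log_hr=[1.0])
        with pytest.raises(ValueError, match="ghost"):
            p4.gen_outcomes(matrix, d)


class TestPhantom:
    def test_motion_amplitude_matches_design(self, phantom):
        design, images, gtv_ref, translations, phases = phantom
        amp = p4.motion_amplitude(translations)
        assert amp == pytest.approx(design.amplitude_mm, abs=1e-9)

    def test_reference_phase_has_zero_translation(self, phantom):
        _, _, _, translations, _ = phantom
        np.testing.assert_allclose(translations[5], 0.0)

    def test_masks_track_sphere(self, phantom):
        design, images, gtv_ref, translations, phases = phantom
        masks = phantom_masks(gtv_ref, translations, images, phases)
        for p, label in enumerate(phases):
            gtv = masks[label]["tumour"]
            assert gtv.n_voxels == gtv_ref.n_voxels
            # GTV voxels are soft tissue, not lung, in the matching image
            vals = images[label].array[gtv.array]
            assert vals.mean() > -300.0
            band = masks[label]["peritumour"]
            # the band spans 3 mm inside and outside the tumour boundary
            assert (band.array & gtv.array).any()
            assert (band.array & ~gtv.array).any()
            assert p4.min_volume_check(band)

    def test_slab_removes_band_voxels(self):
        base = PhantomDesign(shape=(40, 40, 32), radius_mm=6.0,
                             amplitude_mm=4.0, seed=1, noise_sd=0.0)
        imgs0, gtv0, tr0, ph = p4.gen_phantom_4d(base)
        slab = PhantomDesign(shape=(40, 40, 32), radius_mm=6.0,
                             amplitude_mm=4.0, seed=1, noise_sd=0.0,
                             slab_x_mm=28.0)
        imgs1, gtv1, tr1, _ = p4.gen_phantom_4d(slab)
        m0 = phantom_masks(gtv0, tr0, imgs0, ph)
        m1 = phantom_masks(gtv1, tr1, imgs1, ph)
        assert m1["50%"]["peritumour"].n_voxels < m0["50%"]["peritumour"].n_voxels

    def test_duplicated_slice_artifact_applied(self):
        d = PhantomDesign(shape=(24, 24, 24), radius_mm=5.0, seed=2,
                          noise_sd=10.0, artifact_phase=3)
        images, _, _, phases = p4.gen_phantom_4d(d)
        arr = images[phases[3]].array
        np.testing.assert_array_equal(arr[:, :, 12], arr[:, :, 11])
        clean = images[phases[4]].array
        assert not np.array_equal(clean[:, :, 12], clean[:, :, 11])

    def test_hu_ranges(self, phantom):
        _, images, _, _, _ = phantom
        for img in images.values():
            assert img.array.min() >= -1090
            assert img.array.max() <= 3090
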