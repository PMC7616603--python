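"""Synthetic design, norms and epoch generation."""

import numpy as np
import pytest

from contextrsa import (
    DesignError,
    SimConfig,
    ZeroVarianceError,
    build_congruency_rdm,
    generate_design,
    generate_epochs,
    generate_feature_norms,
    neural_rdm_series,
    rsa_timeseries,
    simulate_cohort,
    write_epochs,
)
from contextrsa.io import file_sha256
from contextrsa.modelrdm import cosine_distance


class TestGenerateDesign:
    def test_full_design_has_76_trials_per_condition(self):
        design = generate_design(152, "A", seed=0)
        counts = design["condition"].value_counts()
        assert counts["congruent"] == 76 and counts["incongruent"] == 76
        assert design["scene_id"].nunique() == 152

    def test_group_b_is_complementary_for_every_scene(self):
        a = generate_design(20, "A", seed=5).set_index("scene_id")["condition"]
        b = generate_design(20, "B", seed=5).set_index("scene_id")["condition"]
        assert (a != b.loc[a.index]).all()

    def test_same_seed_reproduces_table(self):
        x = generate_design(16, "A", seed=9)
        y = generate_design(16, "A", seed=9)
        assert x.equals(y)

    def test_scene_objects_are_distinct_concepts(self):
        a = generate_design(20, "A", seed=1).set_index("scene_id")["object_label"]
        b = generate_design(20, "B", seed=1).set_index("scene_id")["object_label"]
        assert (a != b.loc[a.index]).all()

    def test_odd_scene_count_rejected(self):
        with pytest.raises(DesignError, match="even"):
            generate_design(151, "A", seed=0)


class TestGenerateFeatureNorms:
    def test_mean_row_sum_matches_binomial_expectation(self):
        norms = generate_feature_norms(100, 300, density=0.1, seed=0)
        row_sums = norms.values.sum(axis=1)
        se = np.sqrt(300 * 0.1 * 0.9 / 100)  # SE of the mean row sum
        assert abs(row_sums.mean() - 30.0) < 3 * se + 0.5  # +resampling bias slack

    def test_no_all_zero_rows_even_at_low_density(self):
        norms = generate_feature_norms(50, 40, density=0.03, seed=1)
        assert (norms.values.sum(axis=1) > 0).all()

    def test_planted_categories_shrink_within_category_distances(self):
        within, between = [], []
        for seed in range(20):
            norms = generate_feature_norms(
                20, 200, density=0.05, seed=seed, n_categories=2, category_mixing=0.5
            )
            cat = np.arange(20) % 2
            for i in range(20):
                for j in range(i):
                    d = cosine_distance(norms.values[i], norms.values[j])
                    (within if cat[i] == cat[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_infeasible_density_rejected(self):
        with pytest.raises(DesignError, match="infeasible"):
            generate_feature_norms(10, 50, density=0.01, seed=0)


class TestGenerateEpochs:
    def _small_cfg(self, **kw):
        base = dict(
            n_subjects=1, n_scenes=12, n_channels=8,
            tmin_ms=-100.0, tmax_ms=500.0, tstep_ms=20.0,
            n_concepts=30, n_features=60, feature_density=0.1,
            n_categories=2, category_mixing=0.5,
            congruency_window_ms=(100.0, 300.0),
            semantic_window_congruent_ms=(0.0, 100.0),
            semantic_window_incongruent_ms=(0.0, 200.0),
        )
        base.update(kw)
        return SimConfig(**base)

    def test_byte_identical_determinism(self, tmp_path):
        cfg = self._small_cfg(seed=4)
        _, subs1 = simulate_cohort(cfg)
        _, subs2 = simulate_cohort(cfg)
        p1 = write_epochs(subs1[0], tmp_path / "a.h5")
        p2 = write_epochs(subs2[0], tmp_path / "b.h5")
        assert file_sha256(p1) == file_sha256(p2)

    def test_unresolvable_labels_rejected(self):
        cfg = self._small_cfg()
        design = generate_design(cfg.n_scenes, "A", seed=0, n_concepts=cfg.n_concepts)
        norms = generate_feature_norms(5, 60, 0.1, seed=0)  # too few concepts
        from contextrsa import ValidationError

        with pytest.raises(ValidationError, match="not resolvable"):
            generate_epochs(cfg, design, norms, "sub-001", seed=0)

    def test_noise_free_congruency_fit_is_exact_inside_window(self):
        """With zero noise and only the congruency signal, the neural RDM
        inside the window is proportional to the binary model: rho = 1 at
        interior timepoints; outside every window patterns are exactly
        zero, which the pipeline flags as zero-variance."""
        cfg = self._small_cfg(
            noise_sd=0.0, congruency_amplitude=1.0,
            semantic_amplitude_congruent=0.0, semantic_amplitude_incongruent=0.0,
        )
        design = generate_design(cfg.n_scenes, "A", seed=0, n_concepts=cfg.n_concepts)
        norms = generate_feature_norms(cfg.n_concepts, cfg.n_features, 0.1, seed=0)
        eps = generate_epochs(cfg, design, norms, "sub-001", seed=0)
        inside = eps.crop(120.0, 280.0)  # interior of the 100-300 ms window
        ts = rsa_timeseries(neural_rdm_series(inside), build_congruency_rdm(eps.trials))
        np.testing.assert_allclose(ts.rho, 1.0, atol=1e-10)
        with pytest.raises(ZeroVarianceError):
            neural_rdm_series(eps)  # zero signal outside the window is flagged

    def test_amplitude_zero_gives_pure_noise_statistics(self):
        cfg = self._small_cfg(
            congruency_amplitude=0.0, semantic_amplitude_congruent=0.0,
            semantic_amplitude_incongruent=0.0, noise_sd=1.0, seed=2,
        )
        _, (eps,) = simulate_cohort(cfg)
        assert abs(eps.data.mean()) < 0.05
        assert abs(eps.data.std() - 1.0) < 0.05

    def test_ar1_noise_is_temporally_correlated(self):
        cfg = self._small_cfg(
            congruency_amplitude=0.0, semantic_amplitude_congruent=0.0,
            semantic_amplitude_incongruent=0.0, ar1_coefficient=0.8, seed=3,
        )
        _, (eps,) = simulate_cohort(cfg)
        x = eps.data.reshape(-1, eps.n_times)
        lag1 = np.mean([np.corrcoef(r[:-1], r[1:])[0, 1] for r in x])
        assert lag1 > 0.5


class TestSimConfig:
    def test_default_grid_matches_target_design(self):
        cfg = SimConfig()
        assert cfg.times.size == 221
        assert cfg.times[0] == -200.0 and cfg.times[-1] == 900.0
        assert cfg.sfreq == 200.0

    def test_round_trip_through_dict(self):
        cfg = SimConfig(n_subjects=5, congruency_window_ms=(250.0, 400.0))
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_window_outside_grid_rejected(self):
        with pytest.raises(DesignError, match="outside"):
            SimConfig(congruency_window_ms=(800.0, 1000.0))
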