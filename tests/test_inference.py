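"""Spearman model fit, cluster construction and sign-flip permutation inference."""

import numpy as np
import pytest
from scipy import stats

from contextrsa import (
    RDM,
    ValidationError,
    find_clusters,
    group_tvalues,
    neural_rdm_series,
    paired_cluster_test,
    rsa_timeseries,
    signflip_cluster_test,
    spearman_rho,
    timecourse_correlation,
)
from contextrsa.inference import cluster_forming_threshold

from conftest import make_epochs


def _rdm(matrix, labels=None, metric="correlation"):
    matrix = np.asarray(matrix, dtype=float)
    return RDM(labels or list(range(matrix.shape[0])), matrix, metric)


def _brute_average_ranks(x):
    """O(n^2) tie-aware average ranks, independent of scipy."""
    x = np.asarray(x, dtype=float)
    return np.array(
        [np.sum(x < xi) + (np.sum(x == xi) + 1) / 2.0 for xi in x]
    )


def _brute_spearman(a, b):
    ra, rb = _brute_average_ranks(a), _brute_average_ranks(b)
    ra, rb = ra - ra.mean(), rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def _brute_max_cluster_mass(t, thr):
    """Max |sum of t| over suprathreshold sign-homogeneous runs (0 if none)."""
    best, i, n = 0.0, 0, len(t)
    while i < n:
        if abs(t[i]) > thr:
            j = i
            while j + 1 < n and abs(t[j + 1]) > thr and np.sign(t[j + 1]) == np.sign(t[i]):
                j += 1
            best = max(best, abs(t[i : j + 1].sum()))
            i = j + 1
        else:
            i += 1
    return best


class TestSpearman:
    def test_identity_gives_one(self, rng):
        m = rng.random((5, 5))
        m = np.triu(m, 1)
        m = m + m.T
        rdm = _rdm(m)
        assert spearman_rho(rdm, rdm) == pytest.approx(1.0, abs=1e-12)

    def test_order_reversal_gives_minus_one(self, rng):
        m = np.array([[0, 0.1, 0.5, 0.9], [0.1, 0, 0.3, 0.7],
                      [0.5, 0.3, 0, 0.2], [0.9, 0.7, 0.2, 0]])
        rev = 1.0 - m
        np.fill_diagonal(rev, 0.0)
        assert spearman_rho(_rdm(m), _rdm(rev)) == pytest.approx(-1.0, abs=1e-12)

    def test_tie_handling_matches_brute_force_rank_oracle(self, rng):
        # 4-item RDMs whose triangles contain ties (binary model vs noisy data)
        a = np.array([[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], float)
        b = rng.random((4, 4))
        b = np.triu(b, 1)
        b[0, 1] = b[0, 2] = 0.4  # ties in the data triangle too
        b = b + b.T
        got = spearman_rho(_rdm(a, metric="euclidean"), _rdm(b))
        i, j = np.tril_indices(4, k=-1)
        assert got == pytest.approx(_brute_spearman(a[i, j], b[i, j]), abs=1e-12)

    def test_label_mismatch_rejected(self, rng):
        m = np.array([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        with pytest.raises(ValidationError, match="labels"):
            spearman_rho(_rdm(m, labels=[0, 1, 2]), _rdm(m, labels=[2, 1, 0]))


class TestRSATimeseries:
    def test_matches_per_timepoint_brute_force(self, rng):
        eps = make_epochs(rng.standard_normal((8, 6, 5)))
        series = neural_rdm_series(eps)
        model = series.rdm_at(0)
        ts = rsa_timeseries(series, model)
        i, j = np.tril_indices(8, k=-1)
        for t in range(5):
            expect = _brute_spearman(series.dissimilarities[t][i, j], model.matrix[i, j])
            assert ts.rho[t] == pytest.approx(expect, abs=1e-12)

    def test_planted_identity_gives_rho_one(self, rng):
        eps = make_epochs(rng.standard_normal((6, 5, 4)))
        series = neural_rdm_series(eps)
        ts = rsa_timeseries(series, series.rdm_at(2))
        assert ts.rho[2] == pytest.approx(1.0, abs=1e-12)

    def test_model_labels_subset_the_series(self, rng):
        eps = make_epochs(rng.standard_normal((8, 6, 3)))
        series = neural_rdm_series(eps)
        model = series.rdm_at(1).subset([1, 3, 5, 7])
        ts = rsa_timeseries(series, model)
        assert ts.rho[1] == pytest.approx(1.0, abs=1e-12)

    def test_null_mean_rho_near_zero(self, rng):
        """Monte-Carlo under the null: pure-noise epochs across many
        simulated subjects give mean rho within 3 SE of zero."""
        rhos = []
        for _ in range(40):
            eps = make_epochs(rng.standard_normal((10, 6, 4)))
            series = neural_rdm_series(eps)
            from contextrsa import build_congruency_rdm

            rhos.append(rsa_timeseries(series, build_congruency_rdm(eps.trials)).rho)
        rhos = np.stack(rhos)
        se = rhos.std(ddof=1) / np.sqrt(rhos.size)
        assert abs(rhos.mean()) < 3 * se + 1e-3


class TestGroupT:
    def test_null_and_hand_computed_values(self):
        rhos = np.array([[0.0, 0.1], [0.0, 0.2], [0.0, 0.3]])
        t = group_tvalues(rhos)
        assert t[0] == 0.0
        assert t[1] == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_antisymmetry_under_global_negation(self, rng):
        rhos = rng.standard_normal((6, 10))
        np.testing.assert_allclose(group_tvalues(-rhos), -group_tvalues(rhos), atol=1e-12)

    def test_zero_variance_exceeds_any_threshold(self):
        rhos = np.array([[0.2, 0.0], [0.2, 0.0], [0.2, 0.0]])
        t = group_tvalues(rhos)
        # identical values: sd is zero up to float error, t is effectively infinite
        assert np.isposinf(t[0]) or t[0] > 1e12
        assert t[1] == 0.0


class TestFindClusters:
    def test_all_subthreshold_gives_empty_list(self):
        assert find_clusters(np.array([0.1, -0.2, 0.3]), df=9, alpha=0.01) == []

    def test_two_clusters_with_signed_masses(self):
        t = np.array([0.0, 4.0, 4.0, 0.0, -4.0])
        clusters = find_clusters(t, df=9, alpha=0.01)  # threshold ~3.25
        assert [(c.start_index, c.end_index) for c in clusters] == [(1, 2), (4, 4)]
        assert clusters[0].mass == pytest.approx(8.0)
        assert clusters[1].mass == pytest.approx(-4.0)

    def test_sign_change_splits_a_suprathreshold_run(self):
        t = np.array([4.0, 4.0, -4.0, -4.0])
        clusters = find_clusters(t, df=9, alpha=0.01)
        assert len(clusters) == 2
        assert clusters[0].mass > 0 > clusters[1].mass

    def test_cluster_times_follow_the_time_axis(self):
        times = np.array([-10.0, 0.0, 10.0, 20.0])
        t = np.array([0.0, 5.0, 5.0, 0.0])
        (c,) = find_clusters(t, df=9, alpha=0.01, times=times)
        assert (c.start_time, c.end_time) == (0.0, 10.0)


class TestSignFlipClusterTest:
    def _effect_rhos(self, rng, n=10, T=40):
        rhos = 0.1 * rng.standard_normal((n, T))
        rhos[:, 10:18] += 0.25
        rhos[:, 30:33] -= 0.2
        return rhos

    def test_observed_mass_above_all_permutations_gives_floor_p(self, rng):
        n_perm = 500
        # 20 subjects: the chance a random permutation reproduces the identity
        # (or global-flip) sign pattern within 500 draws is ~1e-3
        rhos = 0.01 * rng.standard_normal((20, 20))
        rhos[:, 5:10] += 5.0  # colossal effect: no permutation can beat it
        res = signflip_cluster_test(rhos, alpha=0.01, n_perm=n_perm, seed=0)
        big = max(res.clusters, key=lambda c: abs(c.mass))
        assert big.p_value == pytest.approx(1.0 / (n_perm + 1))

    def test_p_values_bounded_and_monotone_in_mass(self, rng):
        rhos = self._effect_rhos(rng)
        res = signflip_cluster_test(rhos, alpha=0.05, n_perm=300, seed=3)
        assert len(res.clusters) >= 2
        for c in res.clusters:
            assert 1.0 / 301 <= c.p_value <= 1.0
        by_mass = sorted(res.clusters, key=lambda c: abs(c.mass), reverse=True)
        ps = [c.p_value for c in by_mass]
        assert ps == sorted(ps)

    def test_deterministic_given_seed(self, rng):
        rhos = self._effect_rhos(rng)
        a = signflip_cluster_test(rhos, alpha=0.05, n_perm=200, seed=7)
        b = signflip_cluster_test(rhos, alpha=0.05, n_perm=200, seed=7)
        assert [(c.mass, c.p_value) for c in a.clusters] == [
            (c.mass, c.p_value) for c in b.clusters
        ]

    def test_invariant_to_global_negation(self, rng):
        rhos = self._effect_rhos(rng)
        a = signflip_cluster_test(rhos, alpha=0.05, n_perm=200, seed=7)
        b = signflip_cluster_test(-rhos, alpha=0.05, n_perm=200, seed=7)
        assert [c.p_value for c in a.clusters] == [c.p_value for c in b.clusters]
        np.testing.assert_allclose(
            [c.mass for c in a.clusters], [-c.mass for c in b.clusters], atol=1e-12
        )

    def test_matches_exhaustive_enumeration_for_ten_subjects(self, rng):
        """Monte-Carlo p within 3 SE of the exhaustive 2^10 sign-flip p."""
        n, T, n_perm = 10, 40, 4000
        rhos = self._effect_rhos(rng, n, T)
        alpha = 0.05
        res = signflip_cluster_test(rhos, alpha=alpha, n_perm=n_perm, seed=11)
        thr = cluster_forming_threshold(n - 1, alpha)
        # exhaustive oracle over all sign patterns
        patterns = np.array(
            [[1 if (k >> s) & 1 else -1 for s in range(n)] for k in range(2**n)], float
        )
        maxima = np.empty(2**n)
        for k, signs in enumerate(patterns):
            flipped = signs[:, None] * rhos
            maxima[k] = _brute_max_cluster_mass(group_tvalues(flipped), thr)
        assert res.clusters
        for c in res.clusters:
            p_exact = np.mean(maxima >= abs(c.mass))
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(c.p_value - p_exact) <= 3 * se + 2.0 / n_perm


class TestPairedClusterTest:
    def test_identical_conditions_give_no_clusters(self, rng):
        rhos = rng.standard_normal((8, 20))
        res = paired_cluster_test(rhos, rhos.copy(), alpha=0.01, n_perm=100, seed=0)
        assert res.clusters == []

    def test_equivalent_to_signflip_on_difference(self, rng):
        a = rng.standard_normal((8, 30)) * 0.1
        b = rng.standard_normal((8, 30)) * 0.1
        a[:, 5:12] += 0.4
        paired = paired_cluster_test(a, b, alpha=0.05, n_perm=300, seed=5)
        direct = signflip_cluster_test(a - b, alpha=0.05, n_perm=300, seed=5)
        assert [(c.start_index, c.end_index, c.mass, c.p_value) for c in paired.clusters] == [
            (c.start_index, c.end_index, c.mass, c.p_value) for c in direct.clusters
        ]

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="matching"):
            paired_cluster_test(rng.standard_normal((8, 10)), rng.standard_normal((7, 10)))


class TestTimecourseCorrelation:
    def test_identity_and_reflection(self, rng):
        x = rng.standard_normal(50)
        assert timecourse_correlation(x, x)[0] == pytest.approx(1.0)
        assert timecourse_correlation(x, -x + 3.0)[0] == pytest.approx(-1.0)

    def test_matches_closed_form_r_and_p(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r, p = timecourse_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        tstat = r_expect * np.sqrt(28 / (1 - r_expect**2))
        p_expect = 2 * stats.t.sf(abs(tstat), 28)
        assert r == pytest.approx(r_expect, abs=1e-10)
        assert p == pytest.approx(p_expect, rel=1e-6)

    def test_window_restricts_timepoints(self, rng):
        times = np.arange(0.0, 100.0, 10.0)
        x = rng.standard_normal(10)
        y = x.copy()
        y[:5] = -x[:5]  # anti-correlated early, identical late
        r, _ = timecourse_correlation(x, y, times=times, window=(50.0, 90.0))
        assert r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        from contextrsa import ZeroVarianceError

        with pytest.raises(ZeroVarianceError):
            timecourse_correlation(np.ones(10), np.arange(10.0))
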