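import warnings

import numpy as np
import pytest

from alfak.inference import (
    InferenceConfig,
    LongitudinalCounts,
    bootstrap_fitness,
    cv_score,
    fit_frequent_fitness,
    fit_kriging,
    fit_landscape,
    fit_neighbor_fitness,
    growth_offset_correction,
    identify_frequent_clones,
    replicator_solution,
)
from alfak.karyotype import DIPLOID, charted_region, one_step_neighbors

K2 = (3,) + DIPLOID[1:]
K3 = (3, 3) + DIPLOID[2:]


def make_counts(times, freq_rows, n=1000, rng=None, karyotypes=(DIPLOID, K2, K3)):
    tables = []
    for row in np.asarray(freq_rows, dtype=float):
        if rng is None:
            cts = row * n
        else:
            cts = rng.multinomial(n, row / row.sum())
        tables.append({k: c for k, c in zip(karyotypes, cts) if c > 0})
    return LongitudinalCounts(times=times, tables=tables)


class TestFrequentClones:
    def test_threshold_and_monotonicity(self):
        counts = make_counts([0, 10], [[0.6, 0.3, 0.1], [0.6, 0.3, 0.1]], n=100)
        sizes = [len(identify_frequent_clones(counts, m)) for m in (1, 50, 100)]
        assert sizes == [3, 2, 1]
        assert sizes == sorted(sizes, reverse=True)

    def test_error_when_empty(self):
        counts = make_counts([0, 10], [[0.5, 0.3, 0.2], [0.5, 0.3, 0.2]], n=10)
        with pytest.raises(ValueError, match="lower the threshold"):
            identify_frequent_clones(counts, 100)


class TestReplicatorSolution:
    def test_neutral_is_constant(self):
        x0 = np.array([0.2, 0.3, 0.5])
        X = replicator_solution(np.zeros(3) + 0.4, x0, [0, 5, 50])
        np.testing.assert_allclose(X, np.tile(x0, (3, 1)), atol=1e-12)

    def test_two_clone_closed_form(self):
        # x2(10) = 0.1 e^2 / (0.9 + 0.1 e^2)
        X = replicator_solution(np.array([0.0, 0.2]), np.array([0.9, 0.1]), [10.0])
        expect = 0.1 * np.e**2 / (0.9 + 0.1 * np.e**2)
        assert X[0, 1] == pytest.approx(expect, abs=1e-12)
        assert X[0, 1] == pytest.approx(0.4508, abs=1e-4)

    def test_matches_ode_integration(self):
        from scipy.integrate import solve_ivp

        f = np.array([0.0, 0.1, 0.25])
        x0 = np.array([0.5, 0.3, 0.2])

        def rhs(_, x):
            return x * (f - x @ f)

        sol = solve_ivp(rhs, (0, 20), x0, t_eval=[20.0], rtol=1e-10, atol=1e-12)
        X = replicator_solution(f, x0, [20.0])
        np.testing.assert_allclose(X[0], sol.y[:, 0], atol=1e-7)

    def test_simplex_conservation(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=6)
        x0 = rng.dirichlet(np.ones(6))
        X = replicator_solution(f, x0, np.linspace(0, 30, 10))
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(X >= 0)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            replicator_solution(np.zeros(2), np.array([0.7, 0.7]), [1.0])


class TestFrequentFitness:
    def test_constant_frequencies_give_equal_fitness(self):
        counts = make_counts(
            [0, 10, 20, 30], [[0.5, 0.3, 0.2]] * 4, n=10_000
        )
        fit = fit_frequent_fitness(counts, [DIPLOID, K2, K3], InferenceConfig())
        assert np.ptp(fit.fitness) < 1e-6

    def test_noiseless_recovery(self):
        f_true = np.array([0.0, 0.1, 0.2])
        times = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        X = replicator_solution(f_true, np.ones(3) / 3, times)
        counts = make_counts(times, X, n=10_000)
        fit = fit_frequent_fitness(counts, [DIPLOID, K2, K3], InferenceConfig())
        est = fit.fitness
        for i in range(3):
            for j in range(3):
                assert (est[i] - est[j]) == pytest.approx(
                    f_true[i] - f_true[j], abs=0.01
                )

    def test_error_shrinks_with_sample_size(self):
        from alfak.validation import recovery_study

        assert recovery_study(5000, 30, seed=1) < recovery_study(500, 30, seed=1)


class TestGrowthOffset:
    def test_baseline_pinned_and_differences_invariant(self):
        counts = make_counts([0, 10], [[0.6, 0.4, 0.0], [0.5, 0.5, 0.0]])
        rel = {DIPLOID: -0.05, K2: 0.05}
        out0 = growth_offset_correction(rel, counts, baseline=0.0)
        w = np.array([0.6, 0.4])
        assert np.average([out0[DIPLOID], out0[K2]], weights=w) == pytest.approx(0.0)
        out5 = growth_offset_correction(rel, counts, baseline=0.5)
        assert out5[K2] - out5[DIPLOID] == pytest.approx(rel[K2] - rel[DIPLOID])

    def test_equal_clones_get_baseline(self):
        counts = make_counts([0, 10], [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        out = growth_offset_correction({DIPLOID: 0.0, K2: 0.0}, counts, 0.5)
        assert out[DIPLOID] == pytest.approx(0.5)
        assert out[K2] == pytest.approx(0.5)


class TestNeighborFitness:
    @staticmethod
    def _counts_with_neighbor(neighbor_counts):
        times = [0.0, 5.0, 10.0, 15.0]
        nb = (2, 3) + DIPLOID[2:]
        tables = []
        for t_idx in range(4):
            tab = {DIPLOID: 600, K2: 400}
            if neighbor_counts[t_idx]:
                tab[nb] = neighbor_counts[t_idx]
            tables.append(tab)
        return LongitudinalCounts(times=times, tables=tables), nb

    def test_prior_dominates_as_sigma_vanishes(self):
        counts, nb = self._counts_with_neighbor([0, 0, 0, 0])
        frequent = {DIPLOID: 0.5, K2: 0.5}
        cfg = InferenceConfig(p=0.001, sigma_delta=1e-4, mu_delta=0.02)
        out = fit_neighbor_fitness(counts, frequent, cfg)
        # nb is distance-1 from both frequent clones (both at 0.5)
        assert out[nb] == pytest.approx(0.5 + 0.02, abs=1e-3)

    def test_absence_caps_fitness(self):
        frequent = {DIPLOID: 0.5, K2: 0.5}
        cfg = InferenceConfig(p=0.001, sigma_delta=0.3)
        absent, nb = self._counts_with_neighbor([0, 0, 0, 0])
        present, _ = self._counts_with_neighbor([0, 2, 5, 12])
        f_absent = fit_neighbor_fitness(absent, frequent, cfg)[nb]
        f_present = fit_neighbor_fitness(present, frequent, cfg)[nb]
        assert np.isfinite(f_absent)
        assert f_absent < f_present

    def test_prior_width_sensitivity(self):
        """For an unobserved neighbor, a wider prior lets the absence
        likelihood pull the estimate further below its parents."""
        counts, nb = self._counts_with_neighbor([0, 0, 0, 0])
        frequent = {DIPLOID: 0.5, K2: 0.5}
        ests = [
            fit_neighbor_fitness(
                counts, frequent, InferenceConfig(p=0.001, sigma_delta=sd)
            )[nb]
            for sd in (0.02, 0.1, 0.3)
        ]
        assert ests[0] >= ests[1] >= ests[2]
        assert all(e <= 0.5 + 1e-9 for e in ests)

    def test_requires_positive_p(self):
        counts, _ = self._counts_with_neighbor([0, 0, 0, 0])
        with pytest.raises(ValueError):
            fit_neighbor_fitness(counts, {DIPLOID: 0.5, K2: 0.5}, InferenceConfig(p=0.0))


class TestKriging:
    @staticmethod
    def _linear_anchors():
        rng = np.random.default_rng(3)
        ks = {DIPLOID}
        k = list(DIPLOID)
        while len(ks) < 25:
            c = rng.integers(22)
            k[c] = max(1, k[c] + rng.choice([-1, 1]))
            ks.add(tuple(k))
        return {q: 0.01 * q[0] for q in sorted(ks)}

    def test_zero_nugget_interpolates(self):
        anchors = self._linear_anchors()
        gp = fit_kriging(anchors, InferenceConfig(nugget=0.0))
        ks = sorted(anchors)
        mean, _ = gp.predict(ks)
        for k, m in zip(ks, mean):
            assert m == pytest.approx(anchors[k], abs=1e-6)

    def test_linear_function_extrapolates_to_neighbor(self):
        anchors = self._linear_anchors()
        gp = fit_kriging(anchors, InferenceConfig(nugget=1e-8))
        base = next(iter(sorted(anchors)))
        unseen = (base[0] + 1,) + base[1:]
        assert unseen not in anchors
        mean, _ = gp.predict([unseen])
        assert mean[0] == pytest.approx(0.01 * unseen[0], abs=0.005)

    def test_prediction_invariant_to_anchor_ordering(self):
        anchors = self._linear_anchors()
        shuffled = dict(reversed(list(anchors.items())))
        cfg = InferenceConfig(nugget=1e-6)
        g1 = fit_kriging(anchors, cfg)
        g2 = fit_kriging(shuffled, cfg)
        q = [(3, 3) + DIPLOID[2:]]
        assert g1.predict(q)[0][0] == pytest.approx(g2.predict(q)[0][0], abs=1e-10)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate|at least 3"):
            fit_kriging({DIPLOID: 0.5, K2: 0.6}, InferenceConfig())


class TestCVScore:
    def test_interpolable_anchors_score_near_one(self):
        from alfak.validation import cv_interpolable

        assert cv_interpolable(0) > 0.95

    def test_zero_variance_flagged_nan(self):
        frequent = {k: 0.5 for k in list(charted_region({DIPLOID}, 1))[:6]}
        neighbors = {}
        with pytest.warns(RuntimeWarning, match="zero variance"):
            out = cv_score(frequent, neighbors, InferenceConfig())
        assert np.isnan(out)

    def test_requires_four_frequent(self):
        with pytest.raises(ValueError):
            cv_score({DIPLOID: 0.1, K2: 0.2}, {}, InferenceConfig())


class TestFitLandscape:
    def test_lut_covers_charted_region_exactly(self, smooth_fixture, smooth_fit):
        S = [k for k, s in smooth_fit.source.items() if s == "frequent"]
        region = charted_region(S, smooth_fit.config.radius)
        assert set(smooth_fit.lut) == region

    def test_rerun_is_identical(self, smooth_fixture, smooth_fit):
        from alfak.inference import fit_landscape as fl

        again = fl(smooth_fixture.counts, smooth_fit.config)
        assert again.cv_score == smooth_fit.cv_score
        assert again.lut == smooth_fit.lut

    def test_positive_cv_and_sane_values(self, smooth_fit):
        assert np.isfinite(smooth_fit.cv_score)
        assert smooth_fit.cv_score <= 1.0
        vals = np.array(list(smooth_fit.lut.values()))
        assert np.all(np.isfinite(vals))

    def test_constant_added_to_anchors_shifts_predictions(self, smooth_fit):
        """Identifiability: adding a constant to every anchor fitness shifts
        the interpolated landscape by exactly that constant."""
        anchors = dict(smooth_fit.neighbors)
        anchors.update(smooth_fit.frequent)
        shifted = {k: v + 0.2 for k, v in anchors.items()}
        cfg = smooth_fit.config
        g1 = fit_kriging(anchors, cfg)
        g2 = fit_kriging(shifted, cfg)
        query = sorted(smooth_fit.lut)[:200]
        m1, _ = g1.predict(query)
        m2, _ = g2.predict(query)
        np.testing.assert_allclose(m2 - m1, 0.2, atol=1e-6)

    def test_growth_baseline_shifts_pipeline_scale(self, smooth_fixture, smooth_fit):
        """A different growth baseline moves the whole LUT up by roughly the
        same constant (exactly for the direct anchors; the neighbor influx
        term makes interpolated values only approximately equivariant)."""
        import dataclasses

        cfg2 = dataclasses.replace(
            smooth_fit.config, baseline_growth=smooth_fit.config.baseline_growth + 0.2
        )
        shifted = fit_landscape(smooth_fixture.counts, cfg2)
        fk = [k for k, s in smooth_fit.source.items() if s == "frequent"]
        d_freq = np.array([shifted.lut[k] - smooth_fit.lut[k] for k in fk])
        np.testing.assert_allclose(d_freq, 0.2, atol=1e-6)
        d_all = np.array(
            [shifted.lut[k] - smooth_fit.lut[k] for k in smooth_fit.lut]
        )
        assert abs(np.median(d_all) - 0.2) < 0.05


class TestBootstrap:
    @staticmethod
    def _noisy_counts(n, seed):
        f_true = np.array([0.0, 0.12])
        times = np.array([0.0, 8.0, 16.0, 24.0])
        X = replicator_solution(f_true, np.array([0.7, 0.3]), times)
        rng = np.random.default_rng(seed)
        return make_counts(times, X, n=n, rng=rng, karyotypes=(DIPLOID, K2))

    def test_deterministic_under_seed(self):
        counts = self._noisy_counts(500, 0)
        cfg = InferenceConfig()
        a = bootstrap_fitness(counts, [DIPLOID, K2], cfg, n_boot=50, seed=9)
        b = bootstrap_fitness(counts, [DIPLOID, K2], cfg, n_boot=50, seed=9)
        assert a == b

    def test_ci_width_shrinks_with_sample_size(self):
        cfg = InferenceConfig()
        wide = bootstrap_fitness(self._noisy_counts(100, 1), [DIPLOID, K2], cfg, 100, 1)
        narrow = bootstrap_fitness(
            self._noisy_counts(100_000, 1), [DIPLOID, K2], cfg, 100, 1
        )
        width = lambda ci: ci[1] - ci[0]
        assert width(narrow[K2]) < width(wide[K2])
        assert width(narrow[K2]) < 0.01

    def test_coverage_of_fitness_difference(self):
        # nominal 95% percentile CIs on the gauge-fixed fitness should cover
        # the true (gauge-fixed) difference in most replicates
        f_true = np.array([0.0, 0.12])
        hits = 0
        reps = 50
        for r in range(reps):
            counts = self._noisy_counts(800, 100 + r)
            ci = bootstrap_fitness(counts, [DIPLOID, K2], InferenceConfig(), 80, r)
            lo = ci[K2][0] - ci[DIPLOID][1]
            hi = ci[K2][1] - ci[DIPLOID][0]
            if lo <= f_true[1] - f_true[0] <= hi:
                hits += 1
        assert hits / reps >= 0.8
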