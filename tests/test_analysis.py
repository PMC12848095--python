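import warnings

import networkx as nx
import numpy as np
import pytest

from alfak.analysis import (
    EmergenceFeatures,
    assign_rate_response_groups,
    build_transition_matrix,
    delta_f_profile,
    dominance_screen,
    emergence_features,
    fit_emergence_model,
    permutation_ks_test,
    profile_correlation,
    sample_nonoverlapping_trajectories,
    steady_state,
    wgd_classify,
)
from alfak.karyotype import DIPLOID, charted_region

K2 = (3,) + DIPLOID[1:]


class TestDeltaFProfile:
    def test_flat_landscape_all_zero(self):
        lut = {k: 0.5 for k in charted_region({DIPLOID}, 1)}
        prof = delta_f_profile(DIPLOID, lut)
        assert len(prof.effects) == 44
        np.testing.assert_allclose(prof.effects[prof.viable], 0.0)

    def test_linear_landscape_isolated_to_chr5(self):
        lut = {k: 0.01 * k[4] for k in charted_region({DIPLOID}, 1)}
        prof = delta_f_profile(DIPLOID, lut)
        assert prof.effects[2 * 4] == pytest.approx(-0.01)  # loss of chr5
        assert prof.effects[2 * 4 + 1] == pytest.approx(+0.01)  # gain of chr5
        others = np.delete(prof.effects, [8, 9])
        np.testing.assert_allclose(others[np.isfinite(others)], 0.0, atol=1e-12)

    def test_linear_landscape_effects_cancel(self):
        lut = {
            k: 0.01 * k[0] - 0.02 * k[7] + 0.004 * k[21]
            for k in charted_region({DIPLOID}, 1)
        }
        prof = delta_f_profile(DIPLOID, lut)
        assert np.nansum(prof.effects) == pytest.approx(0.0, abs=1e-12)

    def test_absent_karyotype_rejected(self):
        with pytest.raises(KeyError):
            delta_f_profile(DIPLOID, {K2: 0.1})


class TestProfileCorrelation:
    @staticmethod
    def _profile(effects):
        effects = np.asarray(effects, dtype=float)
        return type(
            "P", (), {"effects": effects, "viable": np.isfinite(effects)}
        )()

    def test_identical_and_negated(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=44)
        r, z = profile_correlation(self._profile(e), self._profile(e))
        assert r == pytest.approx(1.0)
        r2, _ = profile_correlation(self._profile(e), self._profile(-e))
        assert r2 == pytest.approx(-1.0)

    def test_fisher_z_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.normal(size=44)
            b = rng.normal(size=44)
            r, z = profile_correlation(self._profile(a), self._profile(b))
            assert z == pytest.approx(np.arctanh(r))
        # atanh(0.5) ~ 0.5493
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_too_few_joint_entries(self):
        a = np.full(44, np.nan)
        a[:2] = 1.0
        with pytest.raises(ValueError):
            profile_correlation(self._profile(a), self._profile(a))


class TestWGD:
    def test_rules(self):
        assert wgd_classify(DIPLOID) == "WGD-"
        assert wgd_classify((4,) * 22) == "WGD+"
        tied = (2,) * 11 + (3,) * 11  # modal tie 2 vs 3 -> smaller -> WGD-
        assert wgd_classify(tied) == "WGD-"
        assert wgd_classify((3,) * 12 + (2,) * 10) == "WGD+"


class TestPermutationKS:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        labels = ["WGD+"] * 6 + ["WGD-"] * 6
        a = permutation_ks_test(values, labels, n_perm=200, seed=3)
        b = permutation_ks_test(values, labels, n_perm=200, seed=3)
        assert a == b

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
        labels = ["WGD-"] * 10 + ["WGD+"] * 10
        res = permutation_ks_test(values, labels, n_perm=10_000, seed=0)
        assert res.p_value <= 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_ks_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestEmergenceFeatures:
    def test_single_clone_distance_one(self):
        theta = {DIPLOID: 0.5, K2: 0.55}
        feats = emergence_features(theta, {DIPLOID: 1.0}, psi={K2})
        (ft,) = feats
        assert ft.karyotype == K2
        np.testing.assert_allclose(ft.d, [1, 0, 0, 0, 0])
        assert ft.emerged

    def test_two_clone_weighting(self):
        cand = (3, 3) + DIPLOID[2:]
        near = (3, 3, 3) + DIPLOID[3:]  # distance 1 from cand
        far = (2, 2, 3) + DIPLOID[3:]  # distance 3 from cand
        theta = {cand: 0.5, near: 0.5, far: 0.5}
        zeta = {near: 0.5, far: 0.5}
        (ft,) = emergence_features(theta, zeta, psi=set())
        np.testing.assert_allclose(ft.d, [0.5, 0, 0.5, 0, 0])
        # cell weighting follows abundance
        (ft2,) = emergence_features(theta, {near: 0.9, far: 0.1}, psi=set())
        np.testing.assert_allclose(ft2.d, [0.9, 0, 0.1, 0, 0])

    def test_remote_candidate_all_zero(self):
        cand = (8,) * 22
        theta = {cand: 0.1, DIPLOID: 0.5}
        (ft,) = emergence_features(theta, {DIPLOID: 1.0}, psi=set())
        np.testing.assert_allclose(ft.d, 0.0)

    def test_empty_candidates(self):
        assert emergence_features({DIPLOID: 0.5}, {DIPLOID: 1.0}, set()) == []


class TestEmergenceModel:
    def test_degenerate_labels_rejected(self):
        feats = [
            EmergenceFeatures(DIPLOID, 0.5, np.zeros(5), False) for _ in range(10)
        ]
        with pytest.raises(ValueError):
            fit_emergence_model(feats)

    def test_d1_signal_recovered(self):
        rng = np.random.default_rng(5)
        feats = []
        for _ in range(400):
            d = np.clip(rng.dirichlet(np.ones(5)) * rng.uniform(0, 1), 0, 1)
            eta = -2 + 6 * d[0]
            feats.append(
                EmergenceFeatures(
                    None, rng.normal(), d, bool(rng.random() < 1 / (1 + np.exp(-eta)))
                )
            )
        model = fit_emergence_model(feats)
        assert model.coefficients["d1"] > 0
        assert model.p_values["d1"] < 0.05

    def test_separation_flagged(self):
        feats = []
        rng = np.random.default_rng(0)
        for i in range(60):
            d = np.zeros(5)
            d[0] = rng.uniform(0.6, 1.0) if i % 2 else rng.uniform(0.0, 0.4)
            feats.append(EmergenceFeatures(None, 0.5, d, bool(i % 2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_emergence_model(feats)
        assert model.separation


class TestTrajectorySampling:
    def test_single_chain(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        out = sample_nonoverlapping_trajectories(g, seed=0)
        assert len(out) == 1

    def test_two_disjoint_chains(self):
        g = nx.DiGraph([("a", "b"), ("c", "d")])
        out = sample_nonoverlapping_trajectories(g, seed=0)
        assert len(out) == 2

    def test_y_graph_disjointness(self):
        g = nx.DiGraph([("r", "a"), ("a", "b"), ("a", "c")])
        for seed in range(5):
            out = sample_nonoverlapping_trajectories(g, seed=seed)
            used = [n for path in out for n in path]
            assert len(used) == len(set(used))

    def test_seed_varies_selection(self):
        g = nx.DiGraph([("r", "a"), ("a", "b"), ("a", "c"), ("c", "d")])
        picks = {
            tuple(sorted(sample_nonoverlapping_trajectories(g, seed=s)))
            for s in range(20)
        }
        assert len(picks) > 1

    def test_cyclic_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            sample_nonoverlapping_trajectories(g)


def _three_state_toy():
    """States differing only in chr1 copy number (1, 2, 3); fitness ordered."""
    s1 = (1,) + DIPLOID[1:]
    s2 = DIPLOID
    s3 = (3,) + DIPLOID[1:]
    lut = {s1: 0.05, s2: 0.25, s3: 0.15}
    return [s1, s2, s3], lut


def _hand_kernel_chr1(p):
    """Per-chromosome daughter probabilities derived by hand from the
    per-copy model (m missegregating copies, half resolving here)."""
    P = np.zeros((4, 4))  # [parent copies 0..3, child copies 0..3]
    P[1, 0], P[1, 1], P[1, 2] = p / 2, 1 - p, p / 2
    P[2, 1] = p * (1 - p)
    P[2, 2] = (1 - p) ** 2 + p**2 / 2
    P[2, 3] = p * (1 - p)
    P[3, 1] = 0.75 * p**2 * (1 - p)
    P[3, 2] = 1.5 * p * (1 - p) ** 2 + 0.375 * p**3
    P[3, 3] = (1 - p) ** 3 + 1.5 * p**2 * (1 - p)
    return P


class TestTransitionMatrix:
    def test_p_zero_is_identity(self):
        states, lut = _three_state_toy()
        P, _ = build_transition_matrix(lut, p=0.0, mutation_only=True)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-15)

    def test_mutation_columns_sum_to_one(self, smooth_fit):
        sub = dict(list(smooth_fit.lut.items())[:50])
        P, _ = build_transition_matrix(sub, p=0.05, mutation_only=True)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)

    def test_three_state_toy_matches_hand_computation(self):
        p, dt = 0.1, 1.0
        states, lut = _three_state_toy()
        A, order = build_transition_matrix(lut, p=p, dt=dt)
        hand1 = _hand_kernel_chr1(p)
        q22 = (1 - p) ** 2 + p**2 / 2  # each background chromosome stays at 2
        raw = np.zeros((3, 3))
        copies = [1, 2, 3]
        for j, cj in enumerate(copies):  # parent
            for i, ci in enumerate(copies):  # child
                raw[i, j] = hand1[cj, ci] * q22**21
        raw /= raw.sum(axis=0, keepdims=True)
        f = np.array([lut[k] for k in order])
        expected = raw * np.exp(f * dt)[None, :]
        np.testing.assert_allclose(A, expected, rtol=1e-12)


class TestSteadyState:
    def test_identity_matrix_flagged_reducible(self):
        with pytest.warns(RuntimeWarning, match="reducible"):
            steady_state(np.eye(3))

    def test_small_p_concentrates_on_fittest(self):
        states, lut = _three_state_toy()
        A, order = build_transition_matrix(lut, p=1e-6, dt=1.0)
        ss = steady_state(A)
        best = order[int(np.argmax([lut[k] for k in order]))]
        assert ss[order.index(best)] >= 0.99

    def test_matches_brute_force_matrix_powers(self):
        states, lut = _three_state_toy()
        A, order = build_transition_matrix(lut, p=0.05, dt=1.0)
        ss = steady_state(A)
        x = np.ones(3) / 3
        M = np.linalg.matrix_power(A / A.sum(axis=0).max(), 400)
        brute = M @ x
        brute /= brute.sum()
        np.testing.assert_allclose(ss, brute, atol=1e-8)
        assert ss.sum() == pytest.approx(1.0, abs=1e-9)


class TestDominanceScreen:
    def test_identical_landscape_all_distances_zero(self):
        states, lut = _three_state_toy()
        res = dominance_screen(lut, [1e-5, 1e-4, 1e-3])
        assert res.distances[0] == 0
        assert all(
            np.asarray(d).sum() == pytest.approx(1.0, abs=1e-9)
            for d in res.distributions
        )

    def test_needs_two_rates(self):
        _, lut = _three_state_toy()
        with pytest.raises(ValueError):
            dominance_screen(lut, [0.01])


class TestRateResponseGroups:
    @staticmethod
    def _fake_screen(freqs, rates):
        from alfak.analysis import SteadyStateResult

        states = [(c,) + DIPLOID[1:] for c in range(1, len(freqs[0]) + 1)]
        return SteadyStateResult(
            rates=np.asarray(rates, dtype=float),
            states=states,
            distributions=[np.asarray(f) for f in freqs],
            dominants=[states[int(np.argmax(f))] for f in freqs],
            distances=[0] * len(freqs),
        )

    def test_monotone_assignments(self):
        rates = [1e-4, 1e-3, 1e-2]
        freqs = [
            [0.6, 0.1, 0.3],
            [0.4, 0.3, 0.3],
            [0.2, 0.5, 0.3],
        ]
        screen = self._fake_screen(freqs, rates)
        groups = assign_rate_response_groups(screen, top_n=3)
        states = screen.states
        assert groups[states[0]] == "x"  # decreasing with rate
        assert groups[states[1]] == "y"  # increasing with rate
        assert groups[states[2]] is None  # flat
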