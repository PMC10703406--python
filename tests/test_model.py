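"""Core model: probability field, likelihood, gradients, fitting,
generation and local-optimum search."""

import itertools

import numpy as np
import pytest

from generalist import (
    FitConfig,
    generate,
    gradients,
    greedy_hill_climb,
    fit,
    fit_restarts,
    load_model,
    log_likelihood,
    model_score,
    optimal_sequence,
    per_position_log_fold_improvement,
    probability_field,
    save_model,
    sequence_log_probability,
)
from generalist.model import ModelIOError
from generalist.msa import EncodedMSA, one_hot
from generalist.stats import moment_comparison
from generalist import synthetic

A = 21


def _random_instance(seed, n=4, length=5, k=2, scale=1.0):
    rng = np.random.default_rng(seed)
    theta = rng.normal(scale=scale, size=(A, k, length))
    z = rng.normal(scale=scale, size=(n, k))
    codes = rng.integers(0, A, size=(n, length)).astype(np.int8)
    msa = EncodedMSA(ids=[f"s{i}" for i in range(n)], codes=codes)
    return theta, z, msa


class TestProbabilityField:
    def test_zero_latents_give_uniform(self):
        theta = np.random.default_rng(0).normal(size=(A, 3, 4))
        field = probability_field(theta, np.zeros((2, 3)))
        np.testing.assert_allclose(field.pi, 1.0 / A)

    def test_boltzmann_weights_k1(self):
        """theta_a = -ln w_a with z = 1 recovers pi_a = w_a / sum(w)."""
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 5.0, size=A)
        theta = -np.log(w).reshape(A, 1, 1)
        field = probability_field(theta, np.array([[1.0]]))
        np.testing.assert_allclose(field.pi[0, :, 0], w / w.sum(), rtol=1e-12)

    def test_matches_naive_exponentiation(self):
        theta, z, _ = _random_instance(2)
        field = probability_field(theta, z)
        for n in range(z.shape[0]):
            for l in range(theta.shape[2]):
                e = np.exp(-(z[n] * theta[:, :, l]).sum(axis=1))
                np.testing.assert_allclose(field.pi[n, :, l], e / e.sum(), rtol=1e-12)

    def test_normalized_even_at_extreme_energies(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(-10, 10, size=(A, 1, 6))
        z = rng.uniform(-50, 50, size=(8, 1))  # |z.theta| up to 500
        field = probability_field(theta, z)
        np.testing.assert_allclose(field.pi.sum(axis=1), 1.0, atol=1e-10)
        assert np.isfinite(field.log_omega).all()

    def test_non_finite_rejected(self):
        theta, z, _ = _random_instance(4)
        theta[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            probability_field(theta, z)


class TestLogLikelihood:
    def test_uniform_closed_form(self, small_random_msa):
        n, length = small_random_msa.codes.shape
        theta = np.random.default_rng(0).normal(size=(A, 2, length))
        field = probability_field(theta, np.zeros((n, 2)))
        ll = log_likelihood(one_hot(small_random_msa), field)
        np.testing.assert_allclose(ll, -n * length * np.log(A), rtol=1e-13)

    def test_matches_direct_summation(self):
        theta, z, msa = _random_instance(5)
        field = probability_field(theta, z)
        oh = one_hot(msa)
        direct = sum(
            np.log(field.pi[n, msa.codes[n, l], l])
            for n in range(msa.n_sequences)
            for l in range(msa.length)
        )
        np.testing.assert_allclose(log_likelihood(oh, field), direct, rtol=1e-10)
        assert log_likelihood(oh, field) <= 0

    def test_shape_mismatch_rejected(self):
        theta, z, msa = _random_instance(6)
        field = probability_field(theta, z[:2])
        with pytest.raises(ValueError):
            log_likelihood(one_hot(msa), field)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_finite_difference_oracle(self, seed):
        """Analytical gradients match central differences everywhere."""
        theta, z, msa = _random_instance(seed)
        oh = one_hot(msa)
        g_theta, g_z = gradients(oh, theta, z)
        eps = 1e-5

        def ll(th, zz):
            return log_likelihood(oh, probability_field(th, zz))

        rng = np.random.default_rng(seed + 100)
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in theta.shape)
            tp, tm = theta.copy(), theta.copy()
            tp[idx] += eps
            tm[idx] -= eps
            fd = (ll(tp, z) - ll(tm, z)) / (2 * eps)
            assert abs(fd - g_theta[idx]) <= 1e-5 * max(1e-3, abs(fd))
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in z.shape)
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (ll(theta, zp) - ll(theta, zm)) / (2 * eps)
            assert abs(fd - g_z[idx]) <= 1e-5 * max(1e-3, abs(fd))

    def test_uniform_specialization(self):
        """At z=0 the latent gradient reduces to sum_l,a theta (1/A - sigma)."""
        theta, _, msa = _random_instance(7)
        z = np.zeros((msa.n_sequences, theta.shape[1]))
        oh = one_hot(msa)
        _, g_z = gradients(oh, theta, z)
        for n in range(msa.n_sequences):
            expected = np.einsum("akl,al->k", theta, 1.0 / A - oh[n])
            np.testing.assert_allclose(g_z[n], expected, rtol=1e-10)


class TestFit:
    def test_identical_sequences_concentrate(self, edge_cases):
        msa = edge_cases["identical"]
        state = fit(msa, FitConfig(k_dim=1, seed=0))
        field = probability_field(state.theta, state.z)
        observed = np.take_along_axis(
            field.pi, msa.codes.astype(np.intp)[:, None, :], axis=1
        )
        assert observed.mean() >= 0.99

    def test_trace_non_decreasing_and_final_above_initial(self, edge_cases):
        state = fit(edge_cases["duplicated"], FitConfig(k_dim=2, seed=1, max_iters=300))
        trace = np.array(state.fit_meta["trace"])
        assert np.all(np.diff(trace) >= 0)
        assert trace[-1] >= trace[0]

    def test_same_seed_bit_identical(self, edge_cases):
        cfg = FitConfig(k_dim=2, seed=9, max_iters=100)
        a = fit(edge_cases["duplicated"], cfg)
        b = fit(edge_cases["duplicated"], cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.z, b.z)

    def test_restart_spread_of_cumulant_recovery_is_small(self):
        """Different initializations reach equivalent generated statistics."""
        planted = synthetic.make_planted_model(length=20, k_true=2, seed=31)
        msa, _, _ = synthetic.sample_msa(planted, 500, seed=32)
        cfg = FitConfig(k_dim=2, seed=40, max_iters=800, n_restarts=4)
        states, best = fit_restarts(msa, cfg, n_generated=500)
        assert best.fit_meta["delta_sq"] == min(
            s.fit_meta["delta_sq"] for s in states
        )
        rs = []
        for i, s in enumerate(states):
            gen = generate(s, 500, seed=50 + i)
            rs.append(moment_comparison(msa, gen, 2, n_samples=4000, seed=60).pearson_r)
        q75, q25 = np.percentile(rs, [75, 25])
        assert q75 - q25 < 0.05

    def test_single_restart_returns_single_run(self, edge_cases):
        cfg = FitConfig(k_dim=1, seed=2, max_iters=50, n_restarts=1)
        states, best = fit_restarts(edge_cases["duplicated"], cfg, n_generated=4)
        assert len(states) == 1 and best is states[0]


class TestGenerate:
    def test_uniform_model_symbol_frequencies(self):
        theta = np.random.default_rng(0).normal(size=(A, 1, 3))
        model = synthetic.planted_model_state(
            synthetic.PlantedModel(theta_true=theta, z_spec="zero", k_true=1, seed=0),
            np.zeros((10, 1)),
        )
        ens = generate(model, 5000, seed=4)
        freqs = np.bincount(ens.codes.ravel(), minlength=A) / ens.codes.size
        se = np.sqrt((1 / A) * (1 - 1 / A) / ens.codes.size)
        assert np.abs(freqs - 1 / A).max() <= 3 * se
        assert ens.length == 3

    def test_near_deterministic_model_reproduces_consensus(self):
        """With pi > 0.999 on one symbol per position per latent sign,
        every generated sequence is the consensus of its drawn latent."""
        rng = np.random.default_rng(8)
        length = 6
        plus = rng.integers(0, A, size=length)
        minus = (plus + rng.integers(1, A, size=length)) % A  # distinct from plus
        theta = np.zeros((A, 1, length))
        theta[plus, 0, np.arange(length)] -= 20.0  # favored when z = +1
        theta[minus, 0, np.arange(length)] += 20.0  # favored when z = -1
        z = np.array([[1.0], [-1.0]])
        model = synthetic.planted_model_state(
            synthetic.PlantedModel(theta_true=theta, z_spec="normal", k_true=1, seed=0), z
        )
        ens = generate(model, 50, seed=9)
        allowed = {
            optimal_sequence(model, np.array([1.0])).tobytes(),
            optimal_sequence(model, np.array([-1.0])).tobytes(),
        }
        for row in ens.codes:
            assert row.tobytes() in allowed

    def test_invalid_count_rejected(self, fitted_small=None):
        theta = np.zeros((A, 1, 2))
        model = synthetic.planted_model_state(
            synthetic.PlantedModel(theta_true=theta, z_spec="zero", k_true=1, seed=0),
            np.zeros((2, 1)),
        )
        with pytest.raises(ValueError):
            generate(model, 0, seed=0)


class TestOptimalSequence:
    def test_zero_latent_tie_breaks_to_first_symbol(self):
        theta = np.random.default_rng(0).normal(size=(A, 2, 4))
        model = synthetic.planted_model_state(
            synthetic.PlantedModel(theta_true=theta, z_spec="zero", k_true=2, seed=0),
            np.zeros((3, 2)),
        )
        seq = optimal_sequence(model, np.zeros(2))
        assert np.all(seq == 0)

    def test_matches_per_position_enumeration(self):
        theta, z, _ = _random_instance(11)
        model = synthetic.planted_model_state(
            synthetic.PlantedModel(theta_true=theta, z_spec="normal", k_true=2, seed=0), z
        )
        field = probability_field(theta, z)
        for n in range(z.shape[0]):
            seq = optimal_sequence(model, z[n])
            for l in range(theta.shape[2]):
                assert field.pi[n, seq[l], l] == field.pi[n, :, l].max()

    def test_dominates_natural_sequence(self, fitted_k4, planted_sample):
        msa = planted_sample["msa"]
        for n in range(0, 200, 7):
            opt = optimal_sequence(fitted_k4, fitted_k4.z[n])
            lp_opt = sequence_log_probability(fitted_k4, opt, fitted_k4.z[n])
            lp_nat = sequence_log_probability(fitted_k4, msa.codes[n], fitted_k4.z[n])
            assert lp_opt >= lp_nat


class TestHillClimb:
    def test_separable_landscape_reaches_global_optimum(self):
        rng = np.random.default_rng(12)
        table = rng.normal(size=(6, 3))  # L=6, A=3, no interactions

        def score(codes):
            return float(table[np.arange(6), codes].sum())

        start = np.zeros(6, dtype=np.int8)
        end, trace = greedy_hill_climb(score, start, seed=0, n_symbols=3)
        np.testing.assert_array_equal(end, table.argmax(axis=1))
        assert np.all(np.diff(trace) > 0)
        assert trace[-1] >= trace[0]

    def test_terminal_is_local_optimum_by_enumeration(self):
        """On a rugged enumerable landscape (L=4, A=3) the terminal point
        beats every single-substitution neighbor."""
        rng = np.random.default_rng(13)
        values = {
            codes: rng.normal()
            for codes in itertools.product(range(3), repeat=4)
        }

        def score(codes):
            return values[tuple(int(c) for c in codes)]

        for seed in range(5):
            start = np.array(rng.integers(0, 3, size=4), dtype=np.int8)
            end, _ = greedy_hill_climb(score, start, seed=seed, n_symbols=3)
            s_end = score(end)
            for l in range(4):
                for a in range(3):
                    if a == end[l]:
                        continue
                    nb = end.copy()
                    nb[l] = a
                    assert score(nb) <= s_end


class TestLogFoldImprovement:
    def test_identity_and_tenfold(self):
        def score(codes):
            return 0.0 if codes[0] == 0 else np.log(10.0)

        start = np.array([0])
        end = np.array([1])
        assert per_position_log_fold_improvement(score, start, start) == 0.0
        np.testing.assert_allclose(
            per_position_log_fold_improvement(score, start, end), 1.0
        )

    def test_consistent_with_model_score(self, fitted_k4, planted_sample):
        msa = planted_sample["msa"]
        z0 = fitted_k4.z[0]
        score = model_score(fitted_k4, z0)
        opt = optimal_sequence(fitted_k4, z0)
        direct = (
            sequence_log_probability(fitted_k4, opt, z0)
            - sequence_log_probability(fitted_k4, msa.codes[0], z0)
        ) / (msa.length * np.log(10))
        np.testing.assert_allclose(
            per_position_log_fold_improvement(score, msa.codes[0], opt), direct
        )


class TestEmbed:
    def test_unseen_sequences_land_near_their_population(self, mixture_sample):
        """Frozen-theta embedding places held-out sequences on the correct
        side of the two-population latent structure."""
        from generalist import embed

        msa = mixture_sample["msa"]
        labels = mixture_sample["labels"]
        train = msa.subset(np.arange(0, 1500))
        held = msa.subset(np.arange(1500, 1600))
        state = fit(train, FitConfig(k_dim=4, seed=70, max_iters=600))
        z_held = embed(state, held, FitConfig(k_dim=4, max_iters=400, seed=71))
        # the training latents of each planted population define a centroid;
        # held-out embeddings should be nearer their own population's centroid
        c0 = state.z[labels[:1500] == 0].mean(axis=0)
        c1 = state.z[labels[:1500] == 1].mean(axis=0)
        held_labels = labels[1500:1600]
        d0 = np.linalg.norm(z_held - c0, axis=1)
        d1 = np.linalg.norm(z_held - c1, axis=1)
        predicted = (d1 < d0).astype(int)
        assert (predicted == held_labels).mean() >= 0.9

    def test_length_mismatch_rejected(self, edge_cases):
        from generalist import embed

        state = fit(edge_cases["duplicated"], FitConfig(k_dim=1, seed=0, max_iters=30))
        with pytest.raises(ValueError):
            embed(state, edge_cases["all_gap"])


class TestModelIO:
    def test_round_trip_bit_identical(self, tmp_path, edge_cases):
        state = fit(edge_cases["duplicated"], FitConfig(k_dim=2, seed=3, max_iters=50))
        path = tmp_path / "model.npz"
        save_model(state, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.theta, state.theta)
        np.testing.assert_array_equal(back.z, state.z)
        assert back.alphabet.symbols == state.alphabet.symbols
        assert back.fit_meta == state.fit_meta

    def test_corrupted_file_raises(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not an archive")
        with pytest.raises(ModelIOError):
            load_model(path)
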