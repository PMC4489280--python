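"""Copy-number HMM: exact inference, EM calibration, decoding, scoring."""

import numpy as np
import pytest

from conftest import make_profile, random_model, uniform_grid
from oracles import best_path_logprob, enumerate_posteriors, path_logprob
from wescnv.errors import EmptyProfileError, ParameterError, ValidationError
from wescnv.hmm_caller import (
    CallerConfig,
    CNVCall,
    call_sample,
    decode_to_segments,
    em_fit,
    filter_calls,
    forward_backward,
    init_model,
    score_call,
    viterbi,
)
from wescnv.normalization import ReferenceProfile, build_reference
from wescnv.targets_io import SampleCounts, TargetGrid, TargetRegion


class TestInitModel:
    def test_default_means(self):
        model = init_model()
        np.testing.assert_allclose(
            model.means, [np.log2(0.05), -1.0, 0.0, np.log2(1.5), 1.0], atol=1e-4
        )

    def test_transition_row(self):
        row = init_model().transition[2]
        np.testing.assert_allclose(row, [0.0025, 0.0025, 0.99, 0.0025, 0.0025])

    def test_initial_distribution(self):
        np.testing.assert_allclose(
            init_model().initial, [0.025, 0.025, 0.9, 0.025, 0.025]
        )

    def test_state_set_must_contain_diploid(self):
        with pytest.raises(ValidationError):
            init_model(copy_numbers=(0, 1, 3))


class TestForwardBackward:
    def test_single_observation_at_diploid_mean(self):
        model = init_model()
        post = forward_backward(model, make_profile([0.0]))
        assert int(np.argmax(post.gamma[0])) == model.copy_numbers.index(2)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = init_model()
        obs = make_profile(rng.normal(0, 1, 300))
        post = forward_backward(model, obs)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_exhaustive_enumeration(self):
        """Posteriors and loglik equal brute-force path summation (random instances)."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(60):
            k = int(rng.integers(2, 4))
            t = int(rng.integers(1, 7))
            model = random_model(rng, k)
            x = rng.normal(0, 1.5, t)
            post = forward_backward(model, make_profile(x))
            gamma_ref, ll_ref = enumerate_posteriors(
                model.initial, model.transition, model.means, model.variance, x
            )
            worst = max(worst, np.abs(post.gamma - gamma_ref).max())
            assert post.loglik == pytest.approx(ll_ref, abs=1e-8)
        assert worst < 1e-8

    def test_empty_profile_rejected(self):
        with pytest.raises(EmptyProfileError):
            forward_backward(init_model(), make_profile([1.0], mask=[True]))

    def test_masked_target_removal_is_neutral(self):
        """Posteriors at unmasked targets ignore where masked targets sat."""
        rng = np.random.default_rng(5)
        model = init_model()
        x = rng.normal(0, 0.5, 40)
        with_mask = make_profile(np.insert(x, 17, 99.0),
                                 mask=np.arange(41) == 17)
        without = make_profile(x)
        g1 = forward_backward(model, with_mask).gamma
        g2 = forward_backward(model, without).gamma
        np.testing.assert_allclose(np.delete(g1, 17, axis=0), g2, atol=1e-12)


class TestViterbi:
    def test_noise_free_diploid(self):
        path = viterbi(init_model(), make_profile(np.zeros(50)))
        assert (path == 2).all()

    def test_block_deletion_change_points(self):
        model = init_model()
        model.variance = 0.04
        x = np.r_[np.zeros(50), -np.ones(20), np.zeros(50)]
        path = viterbi(model, make_profile(x))
        expected = np.r_[np.full(50, 2), np.full(20, 1), np.full(50, 2)]
        np.testing.assert_array_equal(path, expected)

    def test_block_pattern_matches_brute_force(self):
        """Shortened 12-target version of the block pattern, vs enumeration."""
        from wescnv.hmm_caller import HMMModel

        model = HMMModel(  # loss/diploid/gain states keep enumeration feasible
            copy_numbers=(1, 2, 3),
            means=np.array([-1.0, 0.0, np.log2(1.5)]),
            variance=0.04,
            stay_prob=0.99,
            initial=np.array([0.05, 0.9, 0.05]),
        )
        x = np.r_[np.zeros(4), -np.ones(4), np.zeros(4)]
        path = viterbi(model, make_profile(x))
        states = np.array([model.copy_numbers.index(c) for c in path])
        lp = path_logprob(model.initial, model.transition, model.means,
                          model.variance, x, states)
        lp_best = best_path_logprob(model.initial, model.transition, model.means,
                                    model.variance, x)
        assert lp == pytest.approx(lp_best, abs=1e-8)
        np.testing.assert_array_equal(path, np.r_[np.full(4, 2), np.full(4, 1),
                                                  np.full(4, 2)])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            k = int(rng.integers(2, 6))
            t = int(rng.integers(1, 8))
            model = random_model(rng, k)
            x = rng.normal(0, 1.5, t)
            path = viterbi(model, make_profile(x))
            states = np.array([model.copy_numbers.index(c) for c in path])
            lp = path_logprob(model.initial, model.transition, model.means,
                              model.variance, x, states)
            lp_best = best_path_logprob(model.initial, model.transition,
                                        model.means, model.variance, x)
            assert lp == pytest.approx(lp_best, abs=1e-8)

    def test_tie_breaks_toward_diploid_then_lower(self):
        from wescnv.hmm_caller import HMMModel

        model = HMMModel(
            copy_numbers=(1, 3),
            means=np.array([-1.0, 1.0]),
            variance=0.1,
            stay_prob=0.9,
            initial=np.array([0.5, 0.5]),
        )
        path = viterbi(model, make_profile([0.0]))  # exactly between the means
        assert path[0] == 1  # |1-2| == |3-2|, lower copy number preferred

    def test_chains_are_per_chromosome(self):
        """A run reaching a chromosome boundary never crosses it."""
        regions = [TargetRegion("chr1", 1 + i * 1000, 100 + i * 1000, 0.5) for i in range(5)]
        regions += [TargetRegion("chr2", 1 + i * 1000, 100 + i * 1000, 0.5) for i in range(5)]
        grid = TargetGrid(regions)
        obs = make_profile(np.full(10, -1.0), grid=grid)
        model = init_model()
        model.variance = 0.04
        path = viterbi(model, obs)
        calls = decode_to_segments(path, grid, obs, min_targets=3)
        assert [(c.chrom, c.copy_number, c.n_targets) for c in calls] == [
            ("chr1", 1, 5),
            ("chr2", 1, 5),
        ]


class TestEmFit:
    def make_model_data(self, seed=7, n=5000, var=0.04):
        rng = np.random.default_rng(seed)
        model = init_model()
        a = model.transition
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(5, p=model.initial)
        for t in range(1, n):
            states[t] = rng.choice(5, p=a[states[t - 1]])
        x = model.means[states] + rng.normal(0, np.sqrt(var), n)
        return model, make_profile(x)

    def test_variance_recovery(self):
        model, obs = self.make_model_data()
        fitted = em_fit(model, obs)
        assert fitted.variance == pytest.approx(0.04, rel=0.2)

    def test_offset_recovery_on_shifted_diploid(self):
        rng = np.random.default_rng(41)
        x = 0.3 + rng.normal(0, 0.2, 5000)
        fitted = em_fit(init_model(), make_profile(x))
        offset = fitted.means[fitted.copy_numbers.index(2)]
        assert offset == pytest.approx(0.3, abs=0.05)

    def test_loglik_monotone(self):
        model, obs = self.make_model_data(seed=9)
        fitted = em_fit(model, obs)
        hist = np.asarray(fitted.em_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) >= -1e-7 * np.abs(hist[:-1]))

    def test_infinite_tol_single_update(self):
        model, obs = self.make_model_data(seed=13, n=500)
        initial_ll = forward_backward(model, obs).loglik
        fitted = em_fit(model, obs, tol=np.inf)
        assert forward_backward(fitted, obs).loglik >= initial_ll

    def test_needs_enough_targets(self):
        with pytest.raises(ValidationError, match="50"):
            em_fit(init_model(), make_profile(np.zeros(10)))


class TestDecodeToSegments:
    def grid(self, n=6):
        return uniform_grid(n)

    def obs(self, n=6, grid=None):
        return make_profile(np.zeros(n), grid=grid or self.grid(n))

    def test_loss_run_becomes_call(self):
        grid = self.grid()
        path = np.array([2, 2, 1, 1, 1, 2])
        calls = decode_to_segments(path, grid, self.obs(grid=grid), min_targets=3)
        assert len(calls) == 1
        c = calls[0]
        assert (c.copy_number, c.first_target, c.last_target, c.n_targets) == (1, 2, 4, 3)
        assert c.start == grid.starts[2] and c.end == grid.ends[4]
        assert c.gain_loss == "loss"

    def test_short_run_discarded(self):
        grid = self.grid(5)
        path = np.array([2, 2, 3, 3, 2])
        assert decode_to_segments(path, grid, self.obs(5, grid), min_targets=3) == []

    def test_diploid_never_called(self):
        grid = self.grid()
        path = np.full(6, 2)
        assert decode_to_segments(path, grid, self.obs(grid=grid)) == []


class TestScoreAndFilter:
    def make_posterior(self, probs, cn=1):
        from wescnv.hmm_caller import PosteriorMatrix

        cns = (0, 1, 2, 3, 4)
        gamma = np.zeros((len(probs), 5))
        gamma[:, cns.index(cn)] = probs
        gamma[:, 2] = 1.0 - np.asarray(probs)
        return PosteriorMatrix(gamma=gamma, loglik=0.0, copy_numbers=cns)

    def call(self, first, last):
        return CNVCall("p", "chr1", 1, 10, 1, first_target=first, last_target=last)

    @pytest.mark.parametrize(
        "probs, expected",
        [([1.0, 1.0, 1.0], 100.0), ([0.9, 0.8, 0.7], 80.0), ([0.5], 50.0)],
    )
    def test_score_is_mean_posterior(self, probs, expected):
        scored = score_call(self.call(0, len(probs) - 1), self.make_posterior(probs))
        assert scored.score == expected

    def test_filter_is_strict(self):
        calls = [
            CNVCall("p", "chr1", 1, 10, 1, score=s) for s in (95.0, 80.0, 79.0)
        ]
        kept = filter_calls(calls, threshold=80)
        assert [c.score for c in kept] == [95.0]

    def test_filter_zero_threshold(self):
        calls = [CNVCall("p", "chr1", 1, 10, 1, score=s) for s in (0.0, 0.1)]
        assert [c.score for c in filter_calls(calls, threshold=0)] == [0.1]

    def test_filter_empty(self):
        assert filter_calls([]) == []

    def test_filter_threshold_range(self):
        with pytest.raises(ParameterError):
            filter_calls([], threshold=101)


class TestCallSample:
    def test_patient_equal_to_scaled_reference_yields_no_calls(self):
        grid = uniform_grid(300)
        base = np.arange(1, 301) * 3
        ref = build_reference([SampleCounts("c", base)])
        calls = call_sample(SampleCounts("p", base * 2), ref, grid)
        assert calls == []

    def test_single_deletion_recovered(self):
        rng = np.random.default_rng(17)
        grid = uniform_grid(400)
        depth = 2000.0  # low-noise regime
        control = rng.poisson(depth, 400)
        patient = rng.poisson(depth, 400)
        patient[100:120] = rng.poisson(depth / 2, 20)  # 20-target hemizygous loss
        ref = build_reference([SampleCounts("c", control)])
        calls = call_sample(SampleCounts("p", patient), ref, grid)
        assert len(calls) == 1
        c = calls[0]
        assert c.copy_number == 1 and c.gain_loss == "loss"
        assert c.first_target <= 100 and c.last_target >= 119

    def test_deterministic(self):
        from wescnv.simulation import SimConfig, simulate_cohort

        bundle, _ = simulate_cohort(SimConfig(n_targets=1000, n_patients=1,
                                              n_controls=3, seed=5))
        ref = build_reference(bundle.controls)
        a = call_sample(bundle.patients[0], ref, bundle.grid)
        b = call_sample(bundle.patients[0], ref, bundle.grid)
        assert a == b

    def test_noise_free_copy_numbers_exact(self):
        """At near-zero noise every called segment's copy number equals truth."""
        from wescnv.simulation import SimConfig, simulate_cohort, _recip_overlap

        cfg = SimConfig(n_targets=3000, n_patients=2, n_controls=4,
                        dispersion=1e6, depth_mean=500, seed=3)
        bundle, truth = simulate_cohort(cfg)
        ref = build_reference(bundle.controls)
        for p in bundle.patients:
            calls = call_sample(p, ref, bundle.grid)
            assert calls, "expected calls at near-zero noise"
            for c in calls:
                match = max(
                    (t for t in truth.records if t.sample_id == p.sample_id),
                    key=lambda t: _recip_overlap(c, t),
                )
                assert c.copy_number == match.copy_number
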