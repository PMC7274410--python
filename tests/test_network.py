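"""Pair fitting, R² scoring, sign rules and network-level recovery."""

import numpy as np
import pytest

from crosstol.network import (
    FitOptions,
    IdentifiabilityError,
    ZeroVarianceError,
    classify_sign,
    filter_candidates,
    fit_all_pairs,
    fit_pair,
    infer_network,
    r_squared,
    summarize_network,
)
from crosstol.ssystem import SSystemParams, Trajectory

from oracles import r_squared_direct

FAST_OPTIONS = FitOptions(g_starts=(-1.0, 1.0), rate_scale_starts=(1.0,))


class TestRSquared:
    def test_perfect_fit(self):
        x = np.array([1.0, 2.0, 3.0])
        assert r_squared(x, x) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_res = 1, SS_tot = 5 -> R² = 0.8
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.8)

    def test_matches_direct_formula_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 20)
            obs = rng.normal(size=n)
            pred = obs + rng.normal(scale=0.5, size=n)
            assert r_squared(obs, pred) == pytest.approx(
                r_squared_direct(obs, pred), rel=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestClassifySign:
    @pytest.mark.parametrize(
        "g,expected",
        [(0.8, "promotive"), (-1.2, "inhibitive"), (0.0, "none"),
         (0.04, "none"), (-0.04, "none")],
    )
    def test_sign_rule(self, g, expected):
        assert classify_sign(SSystemParams(1.0, 1.0, g)) == expected


class TestFitPair:
    def test_refits_known_edge_noiselessly(self, pulse_regulator,
                                           known_edge_target):
        """A target simulated from known kinetics refits with near-perfect
        R² and parameters within 10%."""
        true_params, target = known_edge_target
        cand = fit_pair(pulse_regulator, target)
        assert cand.converged
        assert cand.r_squared >= 0.999
        assert cand.sign == "promotive"
        assert cand.params.alpha == pytest.approx(true_params.alpha, rel=0.1)
        assert cand.params.beta == pytest.approx(true_params.beta, rel=0.1)
        assert cand.params.g == pytest.approx(true_params.g, rel=0.1)
        # RMSE implied by R² (SS_res = (1-R²)·SS_tot on the normalized
        # scale) must stay within 1% of the target's range
        norm = target.values / target.values.mean()
        ss_tot = np.sum((norm - norm.mean()) ** 2)
        rmse = np.sqrt((1 - cand.r_squared) * ss_tot / len(target))
        rmse_raw = rmse * target.values.mean()
        target_range = target.values.max() - target.values.min()
        assert rmse_raw <= 0.01 * target_range

    def test_constant_target_rejected(self, pulse_regulator, times8):
        flat = Trajectory("B", times8, np.full(8, 3.0))
        with pytest.raises(ZeroVarianceError):
            fit_pair(pulse_regulator, flat)

    def test_permuted_regulator_fits_worse(self, pulse_regulator,
                                           known_edge_target, times8):
        """Destroying the regulator's time order degrades the fit in at
        least 90% of 100 seeded permutations (permutation null)."""
        _, target = known_edge_target
        reference = fit_pair(pulse_regulator, target, FAST_OPTIONS).r_squared
        rng = np.random.default_rng(99)
        worse = 0
        for _ in range(100):
            perm = rng.permutation(len(times8))
            shuffled = Trajectory("A*", times8,
                                  pulse_regulator.values[perm])
            r2 = fit_pair(shuffled, target, FAST_OPTIONS).r_squared
            if r2 < reference:
                worse += 1
        assert worse >= 90

    def test_too_few_points_rejected(self):
        times = np.linspace(0.0, 21.0, 4)
        reg = Trajectory("A", times, np.array([1.0, 2.0, 3.0, 4.0]))
        tgt = Trajectory("B", times, np.array([1.0, 1.5, 2.5, 3.0]))
        with pytest.raises(IdentifiabilityError):
            fit_pair(reg, tgt)


class TestInferNetwork:
    def test_single_planted_edge_recovered_exactly(self, pulse_regulator,
                                                   known_edge_target, times8):
        """In a 3-protein system with one planted edge, only that edge
        survives the 0.9 threshold: the unrelated monotone profile is
        explained by a regulator-free fit (sign none) and reverse/cross
        fits mistime the pulse."""
        _, target = known_edge_target
        ramp = Trajectory("C", times8, np.linspace(1.0, 2.5, 8))
        edges = infer_network([pulse_regulator, target, ramp], threshold=0.9)
        assert {(e.regulator_id, e.target_id) for e in edges} == {("A", "B")}

    def test_threshold_one_yields_empty_set(self, pulse_regulator,
                                            known_edge_target, times8):
        _, target = known_edge_target
        ramp = Trajectory("C", times8, np.linspace(1.0, 2.5, 8))
        assert infer_network(
            [pulse_regulator, target, ramp], threshold=1.0
        ) == []

    def test_parallel_sweep_matches_serial(self, pulse_regulator,
                                           known_edge_target, times8):
        """Worker count must not change results: the 2-process sweep is
        identical to the serial one."""
        _, target = known_edge_target
        ramp = Trajectory("C", times8, np.linspace(1.0, 2.5, 8))
        profiles = [pulse_regulator, target, ramp]
        serial = fit_all_pairs(profiles, FAST_OPTIONS)
        parallel = fit_all_pairs(profiles, FAST_OPTIONS, n_jobs=2)
        assert [(c.regulator_id, c.target_id, c.r_squared, c.params)
                for c in serial] == \
               [(c.regulator_id, c.target_id, c.r_squared, c.params)
                for c in parallel]

    def test_identifiability_guard_refuses_short_courses(self, times8):
        times4 = times8[::2][:4]
        profiles = [
            Trajectory("A", times4, np.array([1.0, 2.0, 2.5, 2.0])),
            Trajectory("B", times4, np.array([1.0, 1.5, 2.5, 3.0])),
        ]
        with pytest.raises(IdentifiabilityError):
            infer_network(profiles)


class TestBenchmarkRecovery:
    """Properties of the standing 10-node / 12-edge noisy benchmark."""

    def test_recall_and_score_separation(self, benchmark_sweep):
        network, _, candidates = benchmark_sweep
        true_edges = network.edge_set
        retained = {
            (c.regulator_id, c.target_id)
            for c in filter_candidates(candidates, 0.9)
        }
        recall = len(retained & true_edges) / len(true_edges)
        assert recall >= 0.7
        r2_true = [c.r_squared for c in candidates
                   if (c.regulator_id, c.target_id) in true_edges]
        r2_non = [c.r_squared for c in candidates
                  if (c.regulator_id, c.target_id) not in true_edges]
        assert np.median(r2_true) > np.median(r2_non)

    def test_edge_set_monotone_in_threshold(self, benchmark_sweep):
        _, _, candidates = benchmark_sweep
        previous = None
        for threshold in (0.8, 0.9, 0.95, 0.99):
            edges = {
                (c.regulator_id, c.target_id)
                for c in filter_candidates(candidates, threshold)
            }
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_r_squared_never_exceeds_one(self, benchmark_sweep):
        _, _, candidates = benchmark_sweep
        assert all(c.r_squared <= 1.0 for c in candidates)

    def test_sweep_is_deterministic(self, benchmark_sweep, times8):
        """Refitting a pair from the sweep reproduces its result exactly."""
        network, trajectories, candidates = benchmark_sweep
        by_id = {t.protein_id: t for t in trajectories}
        sample = candidates[:3]
        for cand in sample:
            again = fit_pair(by_id[cand.regulator_id], by_id[cand.target_id])
            assert again.r_squared == cand.r_squared
            assert again.params == cand.params


class TestSummarize:
    def test_counts_by_category(self):
        from crosstol.network import InteractionCandidate

        edges = [
            InteractionCandidate("A", "B", SSystemParams(1, 1, 1.0),
                                 0.95, "promotive", True),
            InteractionCandidate("A", "C", SSystemParams(1, 1, -1.0),
                                 0.95, "inhibitive", True),
        ]
        summary = summarize_network(
            edges,
            {"A": "metabolism", "B": "response-to-heat", "C": "metabolism"},
        )
        assert (summary.n_promotive, summary.n_inhibitive) == (1, 1)
        assert summary.n_interacting_proteins == 3
        assert summary.per_category_counts == {"metabolism": (1, 1)}

    def test_empty_candidates(self):
        summary = summarize_network([], {})
        assert summary.n_promotive == 0
        assert summary.n_inhibitive == 0
        assert summary.n_interacting_proteins == 0
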