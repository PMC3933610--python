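"""Conditional-entropy estimator: Shannon/CE estimates, selection, NCI, CR."""

import math

import numpy as np
import pytest

from cvcausal import (
    EmbeddingSpec,
    LaggedComponent,
    SelectionTrace,
    conditional_entropy,
    cr_ce,
    default_tolerance,
    forward_select_ce,
    full_embedding,
    nci_ce,
    shannon_entropy,
    subset_embedding,
)
from cvcausal.exceptions import DegenerateInputError
from cvcausal.synthetic import CouplingSpec, simulate_coupled
from conftest import make_universe


def brute_force_ce(X, target, eps, k, exclusion):
    """Independent pair-loop CE implementation (no vectorization).

    For every row: exhaustive max-norm k-NN scan with (distance, index)
    ordering, then -ln of the within-eps fraction over all unordered
    distinct image pairs, floored at 1/(pair count).
    """
    n, q = X.shape
    total = 0.0
    for row in range(n):
        cands = []
        for m in range(n):
            if abs(m - row) <= exclusion:
                continue
            d = 0.0
            for c in range(q):
                d = max(d, abs(X[m, c] - X[row, c]))
            cands.append((d, m))
        cands.sort()
        images = [target[m] for _, m in cands[:k]]
        n_pairs = k * (k - 1) // 2
        within = sum(
            1 for a in range(k) for b in range(a + 1, k)
            if abs(images[a] - images[b]) <= eps
        )
        prob = max(within / n_pairs, 1.0 / n_pairs)
        total += -math.log(prob)
    return total / n


class TestShannonEntropy:
    def test_constant_series_zero_entropy(self):
        assert shannon_entropy([3.0, 3.0, 3.0], 0.5) == 0.0

    def test_flooring_when_no_close_pair(self):
        assert shannon_entropy([0.0, 10.0, 20.0], 1.0) == pytest.approx(math.log(3))

    def test_percentile_tolerance_rule(self, rng):
        v = rng.normal(size=4096)
        eps = default_tolerance(v)
        assert eps == pytest.approx(0.1 * (np.percentile(v, 84) - np.percentile(v, 16)))
        # roughly 0.2 SD for a Gaussian
        assert 0.15 < eps < 0.25

    def test_stable_across_seeds(self):
        ests = []
        for seed in range(20):
            v = np.random.default_rng(seed).normal(size=4096)
            ests.append(shannon_entropy(v, default_tolerance(v)))
        assert np.std(ests) < 0.05 * np.mean(ests)


class TestConditionalEntropy:
    def test_constant_target_zero(self, rng):
        from cvcausal.embedding import EmbeddingMatrix

        X = rng.normal(size=(64, 2))
        m = EmbeddingMatrix(X, np.full(64, 2.0),
                            (LaggedComponent(0, 1), LaggedComponent(0, 2)), 0, 2)
        assert conditional_entropy(m, eps=0.1, k=5, exclusion=0) == 0.0

    def test_empty_embedding_equals_unconditional(self, rng):
        u = make_universe(rng.normal(size=(100, 1)))
        m = full_embedding(u, EmbeddingSpec(0, (1,), 2))
        empty = subset_embedding(m, [])
        eps = default_tolerance(m.target)
        assert conditional_entropy(empty, eps) == shannon_entropy(m.target, eps)

    def test_conditioning_collapses_autoregressive_uncertainty(self):
        # on a normalized AR(1) the conditional residual fraction is
        # sqrt(1 - a^2) whatever the innovation scale; a = 0.99 leaves
        # ~14% residual spread, collapsing CE well below the entropy
        spec = CouplingSpec(n=2048, self_coeffs=((0.99,),), couplings=(),
                            noise_sd=(0.1,))
        data, _ = simulate_coupled(spec, seed=0)
        u = make_universe(data)
        m = full_embedding(u, EmbeddingSpec(0, (1,), 1))
        eps = default_tolerance(u.series[0].values)
        se = shannon_entropy(m.target, eps)
        ce = conditional_entropy(m, eps, k=30, exclusion=1)
        assert ce < 0.25 * se

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_loop_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 140))
        u = make_universe(rng.normal(size=(n, 2)), ["x", "y"])
        m = full_embedding(u, EmbeddingSpec(0, (1, 0), 2))
        eps = default_tolerance(m.target)
        k, T = 7, 2
        expected = brute_force_ce(m.X, m.target, eps, k, T)
        assert conditional_entropy(m, eps, k=k, exclusion=T) == pytest.approx(
            expected, abs=1e-10
        )


class TestForwardSelectCe:
    def test_autocorrelated_effect_selects_self_lag_first(self):
        hits = 0
        for seed in range(50):
            spec = CouplingSpec(n=256, self_coeffs=((0.9,),), couplings=(),
                                noise_sd=(0.3,))
            data, _ = simulate_coupled(spec, seed=seed)
            u = make_universe(data)
            trace = forward_select_ce(u, EmbeddingSpec(0, (1,), 8))
            hits += trace.components[0] == LaggedComponent(0, 1)
        assert hits >= 45  # >= 90%

    def test_white_noise_keeps_most_information(self):
        ratios = []
        for seed in range(5):
            u = make_universe(np.random.default_rng(seed).normal(size=(256, 1)))
            trace = forward_select_ce(u, EmbeddingSpec(0, (1,), 8))
            ratios.append(trace.optimal_value / trace.criterion[0])
        assert min(ratios) >= 0.8

    def test_pruning_shared_with_lp(self, rng):
        u = make_universe(rng.normal(size=(256, 2)), ["x", "y"])
        trace = forward_select_ce(u, EmbeddingSpec(0, (1, 0), 4))
        for source in (0, 1):
            lags = [c.lag for c in trace.components if c.source == source]
            assert lags == sorted(lags) and len(lags) == len(set(lags))


class TestNciCe:
    def test_no_reduction_gives_one(self):
        trace = SelectionTrace((LaggedComponent(0, 1),), (1.5, 1.5), maximize=False)
        assert nci_ce(trace).nci == 1.0

    def test_full_reduction_gives_zero(self):
        trace = SelectionTrace((LaggedComponent(0, 1),), (1.5, 0.0), maximize=False)
        assert nci_ce(trace).nci == 0.0

    def test_zero_unconditional_entropy_degenerate(self):
        trace = SelectionTrace((), (0.0,), maximize=False)
        with pytest.raises(DegenerateInputError):
            nci_ce(trace)

    def test_monotone_in_predictability(self):
        # stronger autoregression leaves less residual information
        wins = 0
        for seed in range(10):
            res = {}
            for a in (0.9, 0.2):
                spec = CouplingSpec(n=1024, self_coeffs=((a,),), couplings=(),
                                    noise_sd=(1.0,))
                data, _ = simulate_coupled(spec, seed=seed)
                u = make_universe(data)
                trace = forward_select_ce(u, EmbeddingSpec(0, (1,), 8))
                res[a] = nci_ce(trace).nci
            wins += res[0.9] < res[0.2]
        assert wins >= 9


class TestCrCe:
    def test_zero_rule_exact(self, rng):
        u = make_universe(rng.normal(size=(200, 2)), ["x", "y"])
        spec = EmbeddingSpec(0, (1, 0), 3)
        trace = SelectionTrace(
            (LaggedComponent(0, 1),), (1.4, 1.1), maximize=False
        )
        res = cr_ce(u, spec, cause=1, trace=trace)
        assert res.cr == 0.0

    def test_linear_coupling_detected(self):
        from cvcausal import Coupling

        det, rev_ok = 0, 0
        for seed in range(8):
            spec = CouplingSpec(
                n=1024, self_coeffs=((0.0,), (0.0,)),
                couplings=(Coupling(0, 1, 1, 0.9),),
                noise_sd=(1.0, 0.5),
            )
            data, _ = simulate_coupled(spec, seed=seed)
            u = make_universe(data, ["x", "y"])
            fwd = cr_ce(u, EmbeddingSpec(1, (1, 1), 8), cause=0)
            rev = cr_ce(u, EmbeddingSpec(0, (1, 1), 8), cause=1)
            det += fwd.cr < 0
            rev_ok += rev.cr == 0.0 or rev.cr > -0.05
        assert det >= 6  # >= 75%
        assert rev_ok >= 6

    def test_independent_series_near_zero(self):
        crs = []
        for seed in range(6):
            u = make_universe(
                np.random.default_rng(seed).normal(size=(512, 2)), ["x", "y"]
            )
            crs.append(cr_ce(u, EmbeddingSpec(0, (1, 0), 8), cause=1).cr)
        assert -0.05 <= np.median(crs) <= 0.0
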