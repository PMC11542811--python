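import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastinet.network import UpdateProposal
from plastinet.strategies import (
    StrategySpec,
    _topk_flat_mask,
    _topk_row_mask,
    init_strategy,
    restrict_proposal,
)

SHAPES = ((4, 6), (3, 5))  # N_h=4, n_in=5, n_out=3


def proposal(rng, shapes=SHAPES):
    return UpdateProposal(rng.normal(size=shapes[0]), rng.normal(size=shapes[1]), 0.01)


class TestInitStrategy:
    def test_full_density_masks_are_all_ones(self, rng):
        spec = StrategySpec(variant="fixed_synapse_mask", f0=1.0, f1=1.0)
        state = init_strategy(spec, SHAPES, rng)
        assert state.fixed_mask_in.all() and state.fixed_mask_out.all()

    def test_mask_density_binomial_ci(self):
        spec = StrategySpec(variant="fixed_synapse_mask", f0=0.3, f1=0.7)
        shapes = ((100, 200), (10, 101))
        state = init_strategy(spec, shapes, np.random.default_rng(0))
        n = 100 * 200
        observed = state.fixed_mask_in.sum()
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(observed - 0.3 * n) < 2.58 * sd

    def test_subnet_full_size(self, rng):
        spec = StrategySpec(variant="subnet", subnet_size=4)
        state = init_strategy(spec, SHAPES, rng)
        np.testing.assert_array_equal(state.plastic_neuron_set, np.arange(4))

    def test_subnet_too_large(self, rng):
        with pytest.raises(ValueError):
            init_strategy(StrategySpec(variant="subnet", subnet_size=5), SHAPES, rng)

    def test_deterministic_given_seed(self):
        spec = StrategySpec(variant="fixed_synapse_mask", f0=0.5, f1=0.5)
        a = init_strategy(spec, SHAPES, np.random.default_rng(42))
        b = init_strategy(spec, SHAPES, np.random.default_rng(42))
        np.testing.assert_array_equal(a.fixed_mask_in, b.fixed_mask_in)


class TestSpecValidation:
    def test_bad_variant(self):
        with pytest.raises(ValueError):
            StrategySpec(variant="nope")

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            StrategySpec(f0=0.0)
        with pytest.raises(ValueError):
            StrategySpec(topk_fraction=1.5)


class TestRestrict:
    def test_full_is_identity(self, rng):
        p = proposal(rng)
        orig = p.dW_in.copy()
        state = init_strategy(StrategySpec(), SHAPES, rng)
        out = restrict_proposal(state, p)
        np.testing.assert_array_equal(out.dW_in, orig)

    def test_fixed_synapse_mask_projects(self, rng):
        spec = StrategySpec(variant="fixed_synapse_mask", f0=0.5, f1=0.5)
        state = init_strategy(spec, SHAPES, rng)
        p = proposal(rng)
        once = restrict_proposal(state, p)
        snap_in, snap_out = once.dW_in.copy(), once.dW_out.copy()
        twice = restrict_proposal(state, once)
        np.testing.assert_array_equal(twice.dW_in, snap_in)
        np.testing.assert_array_equal(twice.dW_out, snap_out)
        # zeroed set equals mask complement
        np.testing.assert_array_equal(once.dW_in == 0, state.fixed_mask_in == 0)

    def test_neuron_mask_zeroes_rows_only(self, rng):
        spec = StrategySpec(variant="fixed_neuron_mask", subnet_size=2)
        state = init_strategy(spec, SHAPES, rng)
        p = proposal(rng)
        out_before = p.dW_out.copy()
        restrict_proposal(state, p)
        frozen = np.setdiff1d(np.arange(4), state.plastic_neuron_set)
        assert not p.dW_in[frozen].any()
        assert p.dW_in[state.plastic_neuron_set].all()
        np.testing.assert_array_equal(p.dW_out, out_before)  # outgoing untouched

    def test_subnet_two_unit_example(self, rng):
        shapes = ((2, 4), (3, 3))
        spec = StrategySpec(variant="subnet", subnet_size=1)
        state = init_strategy(spec, shapes, rng)
        state.plastic_neuron_set = np.array([0])
        p = UpdateProposal(np.ones(shapes[0]), np.ones(shapes[1]), 0.01)
        restrict_proposal(state, p)
        assert not p.dW_in[1].any()
        assert not p.dW_out[:, 1].any()
        assert p.dW_in[0].all()
        assert p.dW_out[:, 0].all() and p.dW_out[:, 2].all()  # output bias column stays plastic

    def test_dropconnect_fresh_mask_each_call(self, rng):
        spec = StrategySpec(variant="dropconnect", f0=0.5)
        state = init_strategy(spec, SHAPES, rng)
        zero_patterns = set()
        for _ in range(8):
            p = UpdateProposal(np.ones(SHAPES[0]), np.ones(SHAPES[1]), 0.01)
            restrict_proposal(state, p)
            zero_patterns.add(p.dW_in.tobytes())
        assert len(zero_patterns) > 1

    def test_dropconnect_per_class_mask_persistent(self, rng):
        spec = StrategySpec(variant="dropconnect", f0=0.5, per_class=True)
        state = init_strategy(spec, SHAPES, rng)
        outs = []
        for _ in range(2):
            p = UpdateProposal(np.ones(SHAPES[0]), np.ones(SHAPES[1]), 0.01)
            restrict_proposal(state, p, sample_label=3)
            outs.append(p.dW_in.copy())
        np.testing.assert_array_equal(outs[0], outs[1])
        with pytest.raises(ValueError):
            restrict_proposal(state, proposal(rng))  # label required


class TestTopK:
    def test_sort_oracle_example(self, rng):
        state = init_strategy(StrategySpec(variant="topk", topk_fraction=0.5), ((1, 4), (3, 2)), rng)
        p = UpdateProposal(np.array([[0.3, -0.5, 0.1, -0.05]]), np.ones((3, 2)), 0.01)
        restrict_proposal(state, p)
        np.testing.assert_allclose(p.dW_in, [[0.3, -0.5, 0.0, 0.0]])
        assert p.dW_out.all()  # output layer always updated

    def test_fraction_one_is_identity(self, rng):
        state = init_strategy(StrategySpec(variant="topk", topk_fraction=1.0), SHAPES, rng)
        p = proposal(rng)
        orig = p.dW_in.copy()
        restrict_proposal(state, p)
        np.testing.assert_array_equal(p.dW_in, orig)

    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_exact_count_no_ties(self, seed, fraction):
        rng = np.random.default_rng(seed)
        state = init_strategy(StrategySpec(variant="topk", topk_fraction=fraction), SHAPES, rng)
        p = proposal(rng)
        restrict_proposal(state, p)
        expected = int(np.ceil(fraction * SHAPES[0][0] * SHAPES[0][1]))
        assert np.count_nonzero(p.dW_in) == expected

    def test_tie_break_lowest_flat_index(self):
        vals = np.array([[0.5, -0.5, 0.5, 0.1]])
        keep = _topk_flat_mask(np.abs(vals), 2)
        np.testing.assert_array_equal(keep, [[True, True, False, False]])

    def test_row_scope_counts(self, rng):
        state = init_strategy(
            StrategySpec(variant="topk", topk_fraction=0.5, topk_scope="neuron"), SHAPES, rng
        )
        p = proposal(rng)
        restrict_proposal(state, p)
        np.testing.assert_array_equal(np.count_nonzero(p.dW_in, axis=1), np.full(4, 3))

    def test_row_mask_tie_break(self):
        a = np.array([[1.0, 1.0, 1.0, 0.5], [0.1, 0.2, 0.3, 0.4]])
        keep = _topk_row_mask(a, 2)
        np.testing.assert_array_equal(keep, [[True, True, False, False], [False, False, True, True]])

    def test_topk_within_subnet(self, rng):
        shapes = ((6, 5), (3, 7))
        spec = StrategySpec(variant="topk", topk_fraction=0.5, subnet_size=2)
        state = init_strategy(spec, shapes, rng)
        p = UpdateProposal(rng.normal(size=shapes[0]), rng.normal(size=shapes[1]), 0.01)
        restrict_proposal(state, p)
        frozen = np.setdiff1d(np.arange(6), state.plastic_neuron_set)
        assert not p.dW_in[frozen].any()
        assert not p.dW_out[:, frozen].any()
        assert p.dW_out[:, -1].all()  # bias column plastic
        assert np.count_nonzero(p.dW_in) == int(np.ceil(0.5 * 2 * 5))

    def test_neuron_error_metric(self, rng):
        spec = StrategySpec(variant="topk", topk_fraction=0.5, selection_metric="neuron_error")
        state = init_strategy(spec, SHAPES, rng)
        p = proposal(rng)
        errs = np.array([0.1, -2.0, 0.05, 1.5])
        restrict_proposal(state, p, hidden_errors=errs)
        assert p.dW_in[1].all() and p.dW_in[3].all()
        assert not p.dW_in[0].any() and not p.dW_in[2].any()

    def test_neuron_activity_metric_needs_values(self, rng):
        spec = StrategySpec(variant="topk", topk_fraction=0.5, selection_metric="neuron_activity")
        state = init_strategy(spec, SHAPES, rng)
        with pytest.raises(ValueError):
            restrict_proposal(state, proposal(rng))


def test_fixed_variants_constant_zero_set(small_synthetic):
    """The zeroed coordinate set of fixed-mask training never changes across a run."""
    from plastinet.experiments import train_to_criterion
    from plastinet.network import TrainingConfig

    train, valid = small_synthetic
    spec = StrategySpec(variant="fixed_synapse_mask", f0=0.5, f1=0.8)
    cfg = TrainingConfig(seed=1, eval_every=200, max_epochs=3)
    rec = train_to_criterion(train, valid, 10, cfg, spec, count_windows=((0, 10**9),))
    counts = rec.update_counts[0]
    # reconstruct the mask drawn inside the run: the weights draw consumes the rng first
    rng = np.random.default_rng(cfg.seed)
    rng.normal(size=rec.weights.W_in.shape)
    rng.normal(size=rec.weights.W_out.shape)
    state = init_strategy(spec, (rec.weights.W_in.shape, rec.weights.W_out.shape), rng)
    np.testing.assert_array_equal(counts > 0, state.fixed_mask_in.astype(bool))
    assert set(np.unique(counts[state.fixed_mask_in.astype(bool)])) == {rec.T}


def test_update_diversity_topk_exceeds_fixed_support(small_synthetic):
    """Top-k spreads updates over far more synapses than a same-size fixed support."""
    from plastinet.experiments import count_update_window, update_probability_q
    from plastinet.network import TrainingConfig, init_weights

    train, _ = small_synthetic
    frac = 0.02
    rng = np.random.default_rng(0)
    weights = init_weights(train.n_features, 50, train.n_classes, rng=rng)
    spec = StrategySpec(variant="topk", topk_fraction=frac)
    counts = count_update_window(train, weights, TrainingConfig(seed=0), spec, n_samples=1500, seed=1)
    q = update_probability_q(counts)
    assert q > 5 * frac
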