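import math

import numpy as np
import pytest

from ngn.config import TrainingConfig
from ngn.errors import DataError, StateError
from ngn.network import (
    OUTPUT_KEY,
    apply_updates,
    assemble,
    backprop,
    feedforward,
    init_library,
    library_layout,
    predict,
    train,
    zero_library,
)
from ngn.parse import parse_string
from ngn.synthetic import sample_string

from conftest import ISOPENTANOL


def finite_difference_check(lib, net, target, step=1e-5, abs_floor=1e-10):
    """Central-finite-difference oracle for every weight and bias delta.

    Returns the worst relative disagreement, ignoring discrepancies below
    ``abs_floor`` in absolute terms (central differences carry ~1e-12 of
    rounding noise, which dominates the ratio on near-zero derivatives).
    """
    eta = lib.config.eta
    feedforward(net)
    grads = backprop(net, target)

    def loss():
        return 0.5 * (target - feedforward(net)) ** 2

    worst = 0.0
    for key, groups in grads.per_key.items():
        dw = sum(g[0] for g in groups)
        db = sum(g[1] for g in groups)
        layer = lib[key]
        for arr, ana in ((layer.w, dw), (layer.b, db)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + step
                ep = loss()
                arr[idx] = orig - step
                em = loss()
                arr[idx] = orig
                numeric = -(ep - em) / (2 * step)  # descent direction
                analytic = ana[idx] / eta
                diff = abs(analytic - numeric)
                if abs(numeric) > 1e-8 and diff > abs_floor:
                    worst = max(worst, diff / abs(numeric))
    return worst


class TestInitLibrary:
    def test_magnitudes_in_configured_bands(self, subset):
        cfg = TrainingConfig()  # classification bands [1.0, 1.6]
        lib = init_library(subset, cfg, seed=5)
        for key in lib.key_order:
            for arr in (lib[key].w, lib[key].b):
                mags = np.abs(arr)
                assert np.all((mags >= 1.0) & (mags <= 1.6))
            assert np.all(lib[key].dw_prev == 0)
            assert np.all(lib[key].db_prev == 0)

    def test_same_seed_bit_identical(self, subset):
        cfg = TrainingConfig(seed=9)
        a, b = init_library(subset, cfg), init_library(subset, cfg)
        for key in a.key_order:
            assert np.array_equal(a[key].w, b[key].w)
            assert np.array_equal(a[key].b, b[key].b)

    def test_band_sign_is_equiprobable(self, subset):
        cfg = TrainingConfig(hidden_size=100)  # (chain, chain) layer alone is 1e4
        lib = init_library(subset, cfg, seed=13)
        weights = np.concatenate([lib[k].w.ravel() for k in lib.key_order])
        assert weights.size >= 10_000
        frac_pos = np.mean(weights > 0)
        assert abs(frac_pos - 0.5) < 0.02

    def test_library_size_depends_only_on_grammar(self, subset):
        cfg = TrainingConfig()
        assert len(library_layout(subset, cfg)) == len(init_library(subset, cfg).layers)


class TestAssemble:
    def test_instantiation_counts_match_rule_usage(self, subset, isopentanol_tree):
        cfg = TrainingConfig(hidden_size=4, sharing_mode="per_rule")
        lib = init_library(subset, cfg, seed=0)
        net = assemble(isopentanol_tree, lib)
        counts = net.instantiation_counts()
        usage = isopentanol_tree.rule_usage_counts()
        # every per-rule layer occurs exactly as often as its rule is applied
        for key, n in counts.items():
            if key[0] == "rule":
                assert n == usage[key[1]]
        assert usage[2] == 2 and usage[3] == 3 and usage[5] == 5

    def test_atom_token_slot_instantiated_six_times(self, subset, isopentanol_tree):
        cfg = TrainingConfig(hidden_size=4)
        lib = init_library(subset, cfg, seed=0)
        counts = assemble(isopentanol_tree, lib).instantiation_counts()
        assert counts[("sym", "atom", 1)] == 6  # five C leaves plus one O leaf

    def test_single_atom_network_depth(self, subset):
        cfg = TrainingConfig(hidden_size=4)
        lib = init_library(subset, cfg, seed=0)
        net = assemble(parse_string("C", subset), lib)
        assert len(net.layers) == 4  # leaf, atom, chain, smiles
        assert net.output_layer is not None

    def test_rule3_node_zero_flushes_nbranch_slot(self, subset):
        cfg = TrainingConfig(hidden_size=4)
        lib = init_library(subset, cfg, seed=0)
        net = assemble(parse_string("CC", subset), lib)
        # derivation [1,3,5,2,5]: the rule-3 chain node lacks the Nbranch slot
        sig = {s.symbol.name: s.index for s in subset.child_signature("chain")}
        assert any(key == ("sym", "chain", sig["Nbranch"]) for _, key in net.zero_slots)

    def test_leaf_one_hot_uses_merged_token_index(self, subset):
        cfg = TrainingConfig(hidden_size=4)
        lib = init_library(subset, cfg, seed=0)
        net = assemble(parse_string("O", subset), lib)
        leaf = next(l for l in net.layers if l.kind == "input")
        assert list(leaf.activation) == [0.0, 1.0]  # (C, O) one-hot


class TestFeedforward:
    def test_zero_library_gives_half_everywhere(self, subset, isopentanol_tree):
        lib = zero_library(subset, TrainingConfig(hidden_size=4))
        net = assemble(isopentanol_tree, lib)
        out = feedforward(net)
        assert out == 0.5
        for layer in net.layers:
            if layer.kind == "hidden":
                assert np.all(layer.activation == 0.5)

    def test_hand_computed_logistic_chain(self, subset):
        """Oracle: for 'C' with one unit everywhere the network is a fixed
        three-step logistic chain plus the output head."""
        cfg = TrainingConfig(hidden_size=1)
        lib = zero_library(subset, cfg)
        lib[("sym", "atom", 1)].w[:] = [[0.7, -0.3]]
        lib[("sym", "atom", 1)].b[:] = [0.1]
        lib[("sym", "chain", 1)].w[:] = [[-1.2]]
        lib[("sym", "chain", 1)].b[:] = [0.4]
        lib[("sym", "smiles", 1)].w[:] = [[2.0]]
        lib[("sym", "smiles", 1)].b[:] = [-0.5]
        lib[OUTPUT_KEY].w[:] = [[1.5]]
        lib[OUTPUT_KEY].b[:] = [0.2]

        L = lambda x: 1.0 / (1.0 + math.exp(-x))
        a_atom = L(0.7 * 1.0 + 0.1)        # C is the first merged token
        a_chain = L(-1.2 * a_atom + 0.4)
        a_smiles = L(2.0 * a_chain - 0.5)
        expected = L(1.5 * a_smiles + 0.2)

        out = feedforward(assemble(parse_string("C", subset), lib))
        assert out == pytest.approx(expected, abs=1e-12)

    def test_repeated_calls_are_pure(self, subset, isopentanol_tree):
        lib = init_library(subset, TrainingConfig(hidden_size=4), seed=2)
        net = assemble(isopentanol_tree, lib)
        assert feedforward(net) == feedforward(net)

    def test_activations_strictly_inside_unit_interval(self, subset):
        lib = init_library(subset, TrainingConfig(hidden_size=8), seed=3)
        for s in ["C", "CC(C)CCO", "C(C(O)C)CO"]:
            net = assemble(parse_string(s, subset), lib)
            out = feedforward(net)
            assert 0.0 < out < 1.0
            for layer in net.layers:
                if layer.kind == "hidden":
                    assert np.all((layer.activation > 0) & (layer.activation < 1))


class TestBackprop:
    def test_requires_feedforward_first(self, subset):
        lib = init_library(subset, TrainingConfig(hidden_size=2), seed=0)
        net = assemble(parse_string("C", subset), lib)
        with pytest.raises(StateError):
            backprop(net, 0.5)

    def test_zero_error_means_zero_deltas(self, subset, isopentanol_tree):
        lib = init_library(subset, TrainingConfig(hidden_size=4), seed=1)
        net = assemble(isopentanol_tree, lib)
        out = feedforward(net)
        grads = backprop(net, out)
        for groups in grads.per_key.values():
            for dw, db in groups:
                assert np.all(dw == 0) and np.all(db == 0)

    def test_gradients_match_finite_differences(self, subset):
        cfg = TrainingConfig(hidden_size=3, eta=0.6)
        rng = np.random.default_rng(21)
        for trial in range(4):
            s = sample_string(subset, max_depth=8, seed=rng)
            lib = init_library(subset, cfg, seed=100 + trial)
            net = assemble(parse_string(s, subset), lib)
            worst = finite_difference_check(lib, net, target=0.73)
            assert worst < 1e-4, (s, worst)

    def test_shared_key_carries_one_group_per_occurrence(
        self, subset, isopentanol_tree
    ):
        lib = init_library(subset, TrainingConfig(hidden_size=4), seed=5)
        net = assemble(isopentanol_tree, lib)
        feedforward(net)
        grads = backprop(net, 0.3)
        counts = net.instantiation_counts()
        for key, groups in grads.per_key.items():
            assert len(groups) == counts[key]
        # chain->atom binding: rules 2 and 3 and 4 all feed slot 1 of chain
        assert len(grads.per_key[("sym", "chain", 1)]) == 6


class TestApplyUpdates:
    def test_summed_update_equals_sum_of_instantiations(self, subset):
        cfg = TrainingConfig(hidden_size=4, momentum_alpha=0.0)
        lib = init_library(subset, cfg, seed=8)
        net = assemble(parse_string("CC", subset), lib)
        feedforward(net)
        grads = backprop(net, 0.25)
        key = ("sym", "chain", 1)
        assert len(grads.per_key[key]) == 2
        expected = sum(g[0] for g in grads.per_key[key])
        before = lib[key].w.copy()
        apply_updates(lib, grads, cfg)
        assert np.array_equal(lib[key].dw_prev, expected)
        assert np.allclose(lib[key].w, before + expected, atol=1e-15)

    def test_first_update_has_no_momentum_contribution(self, subset):
        cfg = TrainingConfig(hidden_size=4, momentum_alpha=0.9)
        lib = init_library(subset, cfg, seed=8)
        net = assemble(parse_string("C", subset), lib)
        feedforward(net)
        grads = backprop(net, 0.25)
        key = ("sym", "chain", 1)
        raw = sum(g[0] for g in grads.per_key[key])
        apply_updates(lib, grads, cfg)
        assert np.array_equal(lib[key].dw_prev, raw)  # buffers started at zero

    def test_unused_keys_untouched(self, subset):
        cfg = TrainingConfig(hidden_size=4)
        lib = init_library(subset, cfg, seed=8)
        branch_key = ("sym", "branch", 1)
        before_w = lib[branch_key].w.copy()
        net = assemble(parse_string("CC", subset), lib)  # no branches
        feedforward(net)
        apply_updates(lib, backprop(net, 0.7), cfg)
        assert np.array_equal(lib[branch_key].w, before_w)
        assert np.all(lib[branch_key].dw_prev == 0)


class TestTrain:
    def test_single_exemplar_fit_converges(self, subset, small_cfg):
        lib, res = train([("CC(C)CCO", 0.7)], subset, small_cfg)
        assert res.converged
        assert res.final_rmse < small_cfg.rmse_threshold
        assert abs(predict(lib, "CC(C)CCO", subset) - 0.7) < 0.05

    def test_contradictory_exemplars_exhaust_restarts(self, subset):
        cfg = TrainingConfig(hidden_size=3, max_epochs=30, max_restarts=2)
        lib, res = train([("CC", 0.2), ("CC", 0.8)], subset, cfg)
        assert not res.converged
        assert res.restarts == 2
        assert res.final_rmse >= 0.3 - 0.05

    def test_unparseable_exemplar_names_string(self, subset, small_cfg):
        with pytest.raises(DataError, match="CN"):
            train([("CN", 0.5)], subset, small_cfg)

    def test_targets_outside_scale_rejected(self, subset, small_cfg):
        with pytest.raises(DataError):
            train([("CC", 0.95)], subset, small_cfg)

    def test_identical_runs_identical_library(self, subset, small_cfg):
        ds = [("CC", 0.3), ("CO", 0.7), ("CC(C)O", 0.5)]
        lib1, r1 = train(ds, subset, small_cfg, seed=4)
        lib2, r2 = train(ds, subset, small_cfg, seed=4)
        assert r1.epochs == r2.epochs
        for key in lib1.key_order:
            assert np.array_equal(lib1[key].w, lib2[key].w)
            assert np.array_equal(lib1[key].b, lib2[key].b)

    def test_fast_and_reference_engines_agree(self, subset):
        cfg = TrainingConfig(hidden_size=4, max_epochs=5, max_restarts=0)
        ds = [("CC(C)CCO", 0.7), ("CO", 0.3), ("C(C)O", 0.5)]
        lib_f, _ = train(ds, subset, cfg, seed=11, engine="fast")
        lib_r, _ = train(ds, subset, cfg, seed=11, engine="reference")
        for key in lib_f.key_order:
            np.testing.assert_allclose(lib_f[key].w, lib_r[key].w, atol=1e-10)
            np.testing.assert_allclose(lib_f[key].b, lib_r[key].b, atol=1e-10)
            np.testing.assert_allclose(
                lib_f[key].dw_prev, lib_r[key].dw_prev, atol=1e-10
            )

    def test_per_rule_sharing_mode_trains(self, subset):
        cfg = TrainingConfig(hidden_size=3, max_epochs=200, max_restarts=0,
                             sharing_mode="per_rule")
        lib, res = train([("CC", 0.3), ("CO", 0.7)], subset, cfg, seed=1)
        assert res.converged

    def test_update_invariant_to_instantiation_order(self, subset):
        """Summing instantiation deltas is order-independent (a sum)."""
        cfg = TrainingConfig(hidden_size=4, momentum_alpha=0.0)
        lib = init_library(subset, cfg, seed=3)
        net = assemble(parse_string("CCC", subset), lib)
        feedforward(net)
        grads = backprop(net, 0.4)
        key = ("sym", "chain", 1)
        groups = grads.per_key[key]
        fwd = sum(g[0] for g in groups)
        rev = sum(g[0] for g in reversed(groups))
        np.testing.assert_allclose(fwd, rev, atol=1e-15)


class TestPredict:
    def test_zeroed_library_predicts_half(self, subset):
        lib = zero_library(subset, TrainingConfig(hidden_size=4))
        assert predict(lib, ISOPENTANOL, subset) == 0.5

    def test_predict_is_deterministic_and_pure(self, subset):
        lib = init_library(subset, TrainingConfig(hidden_size=4), seed=6)
        p1 = predict(lib, ISOPENTANOL, subset)
        p2 = predict(lib, ISOPENTANOL, subset)
        assert p1 == p2
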