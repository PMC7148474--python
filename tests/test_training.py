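"""Contrastive loss, pair validation, and the Siamese training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafsiam.model import build_embedding_network, embed
from leafsiam.training import (
    TrainingConfig,
    contrastive_loss,
    contrastive_loss_grad,
    margin_sweep,
    pair_accuracy,
    train_csn,
    validate_pairs,
)

from conftest import TINY_SPEC, tiny_class_index


class TestContrastiveLoss:
    @pytest.mark.parametrize("d,y,m,expected", [
        (0.0, 1, 1.0, 0.0),        # identical positive pair costs nothing
        (1.5, 0, 1.0, 0.0),        # negatives beyond the margin cost nothing
        (1.0, 0, 1.0, 0.0),        # ...including exactly at the margin
        (0.0, 0, 1.0, 0.5),        # coincident negatives cost m^2/2
        (2.0, 1, 1.0, 2.0),        # positives cost d^2/2
        (0.5, 0, 2.0, 1.125),      # (m-d)^2/2 = 1.5^2/2
        (0.3, 1, 0.7, 0.045),
    ])
    def test_hand_derived_grid(self, d, y, m, expected):
        assert contrastive_loss(d, y, m) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_distance_and_margin(self):
        with pytest.raises(ValueError):
            contrastive_loss(-0.1, 1, 1.0)
        with pytest.raises(ValueError):
            contrastive_loss(0.5, 1, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0, 10), st.integers(0, 1), st.floats(0.01, 5))
    def test_nonnegative_everywhere(self, d, y, m):
        assert contrastive_loss(d, y, m) >= 0

    def test_monotonicity_in_distance(self):
        d = np.linspace(0, 3, 301)
        pos = contrastive_loss(d, np.ones_like(d), 1.0)
        neg = contrastive_loss(d, np.zeros_like(d), 1.0)
        assert np.all(np.diff(pos) > 0)           # strictly increasing for y=1
        assert np.all(np.diff(neg) <= 0)          # non-increasing for y=0
        assert np.all(neg[d >= 1.0] == 0)

    def test_analytic_derivative_matches_finite_differences(self):
        eps = 1e-7
        for d in [0.1, 0.5, 0.99, 1.5, 2.5]:
            for y in (0, 1):
                fd = (contrastive_loss(d + eps, y, 1.0)
                      - contrastive_loss(d - eps, y, 1.0)) / (2 * eps)
                assert contrastive_loss_grad(d, y, 1.0) == pytest.approx(fd, abs=1e-6)

    def test_smooth_hinge_at_margin(self):
        # the y=0 branch meets zero with zero slope at d = m
        assert contrastive_loss(1.0, 0, 1.0) == 0.0
        assert contrastive_loss_grad(1.0, 0, 1.0) == 0.0

    def test_1d_minimization_drives_distances_to_targets(self):
        # gradient descent on d alone: positives to 0, negatives to >= m
        for y, target_check in [(1, lambda d: d < 1e-3),
                                (0, lambda d: d >= 1.0 - 1e-6)]:
            d = 0.5
            for _ in range(2000):
                d = max(0.0, d - 0.01 * contrastive_loss_grad(d, y, 1.0))
            assert target_check(d)


class TestValidatePairs:
    def test_manual_recount_on_fixed_lists(self):
        # labels (1,0,1,0) with distances (0.1,0.9,0.8,0.2) at tol 0.5:
        # predictions (1,0,0,1) -> 2 of 4 correct
        assert pair_accuracy([0.1, 0.9, 0.8, 0.2], [1, 0, 1, 0], 0.5) == 0.5
        assert pair_accuracy([0.0, 0.0], [1, 1], 0.5) == 1.0
        assert pair_accuracy([0.9, 0.7], [1, 1], 0.5) == 0.0
        with pytest.raises(ValueError):
            pair_accuracy([], [], 0.5)

    def test_equals_brute_force_recount_through_network(self, tiny_net, rng):
        index = tiny_class_index(3, 4)
        tol = 0.5

        # brute force: re-draw the same batches and recount by hand
        from leafsiam.pairs import SamplingConfig, make_pair_batch
        from leafsiam.model import distance

        acc = validate_pairs(tiny_net, index, tol, n_batches=3,
                             rng=np.random.default_rng(42), batch_size=8)
        rng2 = np.random.default_rng(42)
        correct = total = 0
        for _ in range(3):
            for p in make_pair_batch(index, SamplingConfig(batch_size=8), rng2):
                d = distance(embed(tiny_net, p.x1), embed(tiny_net, p.x2))
                correct += int((d <= tol) == bool(p.y))
                total += 1
        assert acc == pytest.approx(correct / total)

    def test_empty_validation_set_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            validate_pairs(tiny_net, {}, 0.5, 1, np.random.default_rng(0))


def _fast_cfg(**kw):
    kw.setdefault("epochs", 2)
    kw.setdefault("learning_rate", 1e-3)
    kw.setdefault("batch_size", 8)
    kw.setdefault("batches_per_epoch", 2)
    kw.setdefault("validation_batches", 2)
    return TrainingConfig(**kw)


class TestTrainCsn:
    def test_zero_epochs_is_a_no_op(self, tiny_net):
        before = [p.copy() for p in tiny_net.trunk.params()]
        _, hist = train_csn(tiny_net, tiny_class_index(3, 4),
                            tiny_class_index(3, 2, seed=9), _fast_cfg(epochs=0))
        assert hist.train_loss == [] and hist.val_accuracy == []
        for p, b in zip(tiny_net.trunk.params(), before):
            assert np.array_equal(p, b)

    def test_identical_seeds_give_identical_loss_curves(self):
        train = tiny_class_index(3, 4)
        val = tiny_class_index(3, 2, seed=9)
        runs = []
        for _ in range(2):
            net = build_embedding_network(TINY_SPEC, seed=3)
            _, hist = train_csn(net, train, val, _fast_cfg(seed=11))
            runs.append((hist.train_loss, hist.val_accuracy))
        assert runs[0] == runs[1]

    def test_metric_separates_heldout_pairs_on_two_species(self):
        # well-separated prototypes at reduced resolution: after a short run
        # held-out positive pairs must sit closer than negative pairs
        from leafsiam.pairs import SamplingConfig, make_pair_batch
        from leafsiam.synthetic_leaves import GeneratorConfig, generate_samples
        from leafsiam.training import pair_distances

        gen = GeneratorConfig(n_species=2, images_per_species=12,
                              image_size=20, seed=3)
        samples = generate_samples(gen)
        by_sp = {}
        for s in samples:
            by_sp.setdefault(s.species_id, []).append(s.image)
        train = {k: v[:8] for k, v in by_sp.items()}
        val = {k: v[8:10] for k, v in by_sp.items()}
        held = {k: v[10:] for k, v in by_sp.items()}
        net = build_embedding_network(TINY_SPEC, seed=0)
        _, hist = train_csn(net, train, val, _fast_cfg(epochs=10, seed=0))
        assert len(hist.train_loss) == 10
        b = make_pair_batch(held, SamplingConfig(batch_size=64, p_same=0.5),
                            np.random.default_rng(5))
        d, y, _ = pair_distances(net, b)
        assert d[y == 1].mean() < d[y == 0].mean()

    def test_weight_updates_are_shared_between_twins(self, tiny_net):
        ids_before = [id(p) for p in tiny_net.trunk.params()]
        train_csn(tiny_net, tiny_class_index(3, 4), tiny_class_index(3, 2, seed=9),
                  _fast_cfg(epochs=1))
        assert [id(p) for p in tiny_net.trunk.params()] == ids_before


class TestMarginSweep:
    def test_single_candidate_is_selected(self):
        train = tiny_class_index(3, 4)
        val = tiny_class_index(3, 2, seed=9)
        best, table = margin_sweep([0.75], train, val, epochs=1, cfg=_fast_cfg(),
                                   builder=lambda: build_embedding_network(TINY_SPEC, seed=0))
        assert best == 0.75
        assert len(table) == 1 and table[0][0] == 0.75

    def test_ties_break_toward_smaller_margin(self, monkeypatch):
        import leafsiam.training as training_mod

        from leafsiam.training import TrainingHistory

        def fake_train(net, train_set, val_set, cfg):
            hist = TrainingHistory(val_accuracy=[0.9], val_epochs=[0])
            return net, hist

        monkeypatch.setattr(training_mod, "train_csn", fake_train)
        best, table = training_mod.margin_sweep(
            [2.0, 1.0, 1.5], None, None, epochs=1, cfg=_fast_cfg(),
            builder=lambda: None)
        assert best == 1.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            margin_sweep([], None, None, 1, _fast_cfg(), builder=lambda: None)
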