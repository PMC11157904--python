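"""Losses, PRC-AUC, ligand-grouped splitting, the training loop and tuning."""

import numpy as np
import pytest

from sparsepocket.losses import (
    dice_loss,
    dice_loss_with_grad,
    f1_at_threshold,
    focal_loss,
    focal_loss_with_grad,
    prc_auc,
)
from sparsepocket.network import NetworkSpec, SparseUNet
from sparsepocket.synthetic import SyntheticSpec, generate_complex
from sparsepocket.tensorize import tensorize_structure
from sparsepocket.training import (
    RandomSampler,
    SearchSpace,
    TrainingConfig,
    grouped_split,
    train,
    tune,
)


def brute_force_prc_auc(scores, labels):
    """Step-wise PR integration over descending unique thresholds."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels, dtype=float)[order]
    scores = np.asarray(scores, dtype=float)[order]
    tp = fp = 0
    total_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        assert dice_loss(np.ones(6), np.ones(6)) == pytest.approx(0.0, abs=0.08)

    def test_hand_value_total_miss(self):
        # probs all 0, labels all 1, smooth 1, n=4 → 1 − 1/5
        assert dice_loss(np.zeros(4), np.ones(4)) == pytest.approx(0.8)

    def test_symmetric(self, rng):
        p = rng.random(20)
        l = (rng.random(20) < 0.3).astype(float)
        assert dice_loss(p, l) == pytest.approx(dice_loss(l, p))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.ones(3), np.ones(4))


class TestFocalLoss:
    def test_reduces_to_half_bce_at_gamma0_alpha_half(self, rng):
        p = rng.uniform(0.05, 0.95, size=50)
        l = (rng.random(50) < 0.3).astype(float)
        bce = -np.mean(l * np.log(p) + (1 - l) * np.log(1 - p))
        assert focal_loss(p, l, gamma=0.0, alpha=0.5) == pytest.approx(0.5 * bce, abs=1e-9)

    def test_hand_value_single_atom(self):
        # p=0.9, label 1, γ=2, α=0.25 → 0.25·0.01·(−ln 0.9)
        expected = 0.25 * 0.1**2 * -np.log(0.9)
        assert focal_loss([0.9], [1], gamma=2.0, alpha=0.25) == pytest.approx(expected, rel=1e-9)

    def test_confident_correct_predictions_vanish(self):
        assert focal_loss([1 - 1e-9, 1e-9], [1, 0], 1.0, 0.15) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            focal_loss([0.5], [1], gamma=-1.0, alpha=0.5)
        with pytest.raises(ValueError):
            focal_loss([0.5], [1], gamma=1.0, alpha=1.5)

    @pytest.mark.parametrize("loss_name", ["focal", "dice"])
    def test_moving_wrong_prediction_toward_label_never_increases(self, rng, loss_name):
        p = rng.uniform(0.1, 0.9, size=30)
        l = (rng.random(30) < 0.3).astype(float)
        if loss_name == "focal":
            fn = lambda q: focal_loss(q, l, 1.0, 0.15)
        else:
            fn = lambda q: dice_loss(q, l)
        base = fn(p)
        for i in range(30):
            q = p.copy()
            q[i] += (0.05 if l[i] == 1 else -0.05)
            assert fn(q) <= base + 1e-12

    def test_gradients_match_finite_difference(self, rng):
        z = rng.normal(size=12)
        y = (rng.random(12) < 0.4).astype(float)
        for fn, kw in (
            (focal_loss_with_grad, {"gamma": 1.0, "alpha": 0.15}),
            (focal_loss_with_grad, {"gamma": 2.0, "alpha": 0.25}),
            (dice_loss_with_grad, {}),
        ):
            _, g = fn(z, y, **kw)
            eps = 1e-6
            for i in range(len(z)):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                fd = (fn(zp, y, **kw)[0] - fn(zm, y, **kw)[0]) / (2 * eps)
                assert g[i] == pytest.approx(fd, abs=1e-5)


class TestPrcAuc:
    def test_perfect_separation(self):
        assert prc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self, rng):
        n = 20000
        labels = (rng.random(n) < 0.1).astype(float)
        scores = rng.random(n)
        assert prc_auc(scores, labels) == pytest.approx(0.1, abs=0.02)

    def test_four_point_hand_case(self):
        scores = [0.9, 0.7, 0.6, 0.2]
        labels = [1, 0, 1, 0]
        assert prc_auc(scores, labels) == pytest.approx(
            brute_force_prc_auc(scores, labels)
        )

    def test_matches_brute_force_small_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 65))
            labels = (rng.random(n) < 0.4).astype(float)
            if labels.sum() == 0:
                labels[0] = 1.0
            scores = np.round(rng.random(n), 2)  # force ties
            assert prc_auc(scores, labels) == pytest.approx(
                brute_force_prc_auc(scores, labels), abs=1e-12
            )


class TestGroupedSplit:
    def test_same_ligand_structures_colocated(self):
        for seed in range(10):
            train_ids, val_ids = grouped_split(
                {"A": ["HEM"], "B": ["HEM"], "C": ["ADP"], "D": ["ATP"],
                 "E": ["NAD"], "F": ["FMN"]},
                fraction=0.8,
                seed=seed,
            )
            same_side = ("A" in train_ids) == ("B" in train_ids)
            assert same_side
            assert sorted(train_ids + val_ids) == ["A", "B", "C", "D", "E", "F"]
            assert not set(train_ids) & set(val_ids)

    def test_all_distinct_ligands_splits_80_20(self):
        ids = {f"s{i}": [f"L{i}"] for i in range(10)}
        train_ids, val_ids = grouped_split(ids, fraction=0.8, seed=3)
        assert len(train_ids) == 8 and len(val_ids) == 2

    def test_deterministic_given_seed(self):
        ids = {f"s{i}": [f"L{i % 4}"] for i in range(12)}
        a = grouped_split(ids, seed=5)
        b = grouped_split(ids, seed=5)
        assert a == b

    def test_group_exclusivity_for_every_seed(self):
        ids = {f"s{i}": [f"L{i // 3}", f"M{i // 3}"] for i in range(15)}
        for seed in range(20):
            train_ids, val_ids = grouped_split(ids, seed=seed)
            train_ligs = {l for s in train_ids for l in ids[s]}
            val_ligs = {l for s in val_ids for l in ids[s]}
            assert not train_ligs & val_ligs
            assert sorted(train_ids + val_ids) == sorted(ids)

    def test_single_group_unsplittable(self):
        with pytest.raises(ValueError):
            grouped_split({"A": ["X"], "B": ["X"]}, seed=0)


def _small_dataset(n=2, n_atoms=210, start_seed=100, n_pockets=1):
    tensors = []
    for i in range(n):
        s, l = generate_complex(
            SyntheticSpec(seed=start_seed + i, n_atoms=n_atoms, n_pockets=n_pockets)
        )
        tensors.append(tensorize_structure(s, l, t=i))
    return tensors


class TestTrainLoop:
    def test_loss_decreases_and_history_schema(self):
        tensors = _small_dataset(2)
        net = SparseUNet(NetworkSpec.reduced(width=8), seed=0)
        cfg = TrainingConfig(batch_size=2, learning_rate=3e-3, max_epochs=8,
                             patience=8, seed=0)
        result = train(net, tensors, tensors, cfg)
        h = result.history
        assert list(h.columns) == ["epoch", "train_loss", "val_loss", "val_prc_auc", "val_f1"]
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_early_stopping_on_plateau(self):
        tensors = _small_dataset(2)
        net = SparseUNet(NetworkSpec.reduced(width=8), seed=0)
        # zero learning rate: validation loss can never improve after epoch 1
        cfg = TrainingConfig(batch_size=2, learning_rate=0.0, max_epochs=50,
                             patience=3, seed=0)
        result = train(net, tensors, tensors, cfg)
        assert len(result.history) <= 1 + 3

    def test_rerun_same_seed_reproduces_history_exactly(self):
        tensors = _small_dataset(2)
        histories = []
        for _ in range(2):
            net = SparseUNet(NetworkSpec.reduced(width=8), seed=4)
            cfg = TrainingConfig(batch_size=1, learning_rate=2e-3, max_epochs=4,
                                 patience=4, seed=4)
            histories.append(train(net, tensors, tensors, cfg).history)
        assert histories[0].equals(histories[1])

    def test_empty_train_set_raises(self):
        net = SparseUNet(NetworkSpec.reduced(width=8))
        with pytest.raises(ValueError):
            train(net, [], _small_dataset(1), TrainingConfig())

    def test_invalid_loss_name_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(loss="hinge")


class TestTune:
    def test_single_trial_returns_its_config(self):
        tensors = _small_dataset(2, n_atoms=120)
        space = SearchSpace(batch_sizes=(1,), widths=(8,), block_counts=(1,),
                            losses=("focal",))
        best, log = tune(space, tensors, tensors, trials=1, epochs_per_trial=2, seed=0)
        assert len(log) == 1
        assert best == {k: v for k, v in log.iloc[0].items()
                        if k not in ("trial", "val_prc_auc")}

    def test_trial_log_bounded_by_trials(self):
        tensors = _small_dataset(2, n_atoms=120)
        space = SearchSpace(batch_sizes=(1,), widths=(8,), block_counts=(1,))
        _, log = tune(space, tensors, tensors, trials=2, epochs_per_trial=1, seed=0)
        assert len(log) <= 2

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            tune(SearchSpace(), [], [], trials=0)

    def test_dominant_config_wins(self):
        """A config allowed to learn beats one frozen at learning rate ~0."""
        tensors = _small_dataset(2, n_atoms=210)

        class TwoPointSampler:
            def __init__(self):
                self.configs = [
                    {"batch_size": 2, "learning_rate": 1e-12, "width": 8,
                     "blocks": 1, "loss": "focal", "focal_gamma": 1.0,
                     "focal_alpha": 0.15},
                    {"batch_size": 2, "learning_rate": 3e-3, "width": 8,
                     "blocks": 1, "loss": "focal", "focal_gamma": 1.0,
                     "focal_alpha": 0.15},
                ]

            def suggest(self, i, space):
                return self.configs[i]

            def report(self, i, config, objective):
                pass

        best, log = tune(
            SearchSpace(), tensors, tensors, trials=2,
            sampler=TwoPointSampler(), epochs_per_trial=8, seed=0,
        )
        assert best["learning_rate"] == pytest.approx(3e-3)

    def test_random_sampler_deterministic(self):
        a = RandomSampler(seed=2).suggest(0, SearchSpace())
        b = RandomSampler(seed=2).suggest(0, SearchSpace())
        assert a == b
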