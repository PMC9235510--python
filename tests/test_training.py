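"""Training engine: dedup splitting, early stopping, multi-round cycling,
sweep ranking and ensembling."""

import numpy as np
import pytest

from molpotency.chem import parse_smiles
from molpotency.model import PredictorModel
from molpotency.training import (
    EnsembleModel,
    LabeledSet,
    TrainConfig,
    build_ensemble,
    dedup_split,
    multi_round_pretrain,
    sweep,
    train_phase,
)

HIDDEN = (16, 16, 8, 8, 8)


def toy_set(n=80, dim=10, seed=0, binary=False):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, dim)).astype(np.float32)
    w = rng.standard_normal(dim)
    y = X @ w
    if binary:
        y = (y > 0).astype(float)
    return LabeledSet([f"m{i}" for i in range(n)], X, y)


class TestDedupSplit:
    def test_duplicate_spellings_land_in_one_fold(self):
        mols = [
            parse_smiles("CCO", "a"),
            parse_smiles("OCC", "b"),
            parse_smiles("c1ccccc1", "c"),
            parse_smiles("CCN", "d"),
        ]
        plan = dedup_split(mols, k=2, seed=0)
        assert plan.folds["a"] == plan.folds["b"]

    def test_zero_canonical_overlap_between_folds(self, random_molecules):
        # seed the pool with duplicate spellings of existing structures
        mols = list(random_molecules)
        extra = [
            parse_smiles(m.smiles, f"dup_{m.id}") for m in random_molecules[:20]
        ]
        plan = dedup_split(mols + extra, k=3, seed=4)
        by_fold = {}
        canon = {m.id: m.canonical_smiles for m in mols + extra}
        for mid, fold in plan.folds.items():
            by_fold.setdefault(fold, set()).add(canon[mid])
        folds = list(by_fold.values())
        for i in range(len(folds)):
            for j in range(i + 1, len(folds)):
                assert not folds[i] & folds[j]

    def test_fold_group_counts_near_equal(self, random_molecules):
        plan = dedup_split(random_molecules, k=3, seed=0)
        canon = {m.id: m.canonical_smiles for m in random_molecules}
        group_counts = [
            len({canon[i] for i in plan.ids_in_fold(f)}) for f in range(3)
        ]
        assert max(group_counts) - min(group_counts) <= 1

    def test_seeded_determinism(self, random_molecules):
        p1 = dedup_split(random_molecules, k=3, seed=9)
        p2 = dedup_split(random_molecules, k=3, seed=9)
        assert p1.folds == p2.folds

    def test_fewer_groups_than_folds_errors(self):
        mols = [parse_smiles("CCO", "a"), parse_smiles("OCC", "b")]
        with pytest.raises(ValueError):
            dedup_split(mols, k=2, seed=0)


class TestTrainPhase:
    def test_early_stop_restores_best_checkpoint(self):
        # with patience 1 and a validation set engineered to degrade, the
        # returned weights must reproduce the best recorded validation loss
        data = toy_set(seed=1)
        val = toy_set(n=30, seed=2)
        model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=0)
        cfg = TrainConfig(patience=1, max_epochs=50, lr=1e-2)
        _, hist = train_phase(model, data, "carc", cfg, val, np.random.default_rng(0))
        assert len(hist.val_loss) <= 50
        best = min(hist.val_loss)
        assert hist.val_loss[hist.best_epoch] == best
        from molpotency import nn

        pred = model.forward_logits(val.X, "carc", train=False)
        loss, _ = nn.mse_loss(pred, val.y.astype(np.float32))
        assert loss == pytest.approx(best, rel=1e-5)

    def test_linearly_separable_mutagenicity_converges(self):
        full = toy_set(n=260, seed=3, binary=True)
        data, val = full.subset(range(200)), full.subset(range(200, 260))
        model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=0)
        cfg = TrainConfig(patience=20, max_epochs=150, lr=3e-3)
        train_phase(model, data, "mut", cfg, val, np.random.default_rng(0))
        pred = model.forward(data.X, head="mut", mode="eval")
        acc = np.mean((pred > 0.5) == data.y.astype(bool))
        assert acc > 0.95

    def test_fixed_seed_reproduces_loss_history(self):
        data, val = toy_set(seed=5), toy_set(n=20, seed=6)
        histories = []
        for _ in range(2):
            model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=3)
            _, h = train_phase(
                model, data, "carc", TrainConfig(max_epochs=10, patience=10),
                val, np.random.default_rng(3),
            )
            histories.append(h.train_loss)
        assert histories[0] == histories[1]

    def test_empty_sets_error(self):
        data = toy_set()
        empty = LabeledSet([], np.empty((0, 10), dtype=np.float32), np.empty(0))
        model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=0)
        with pytest.raises(ValueError):
            train_phase(model, empty, "carc", TrainConfig(), data)
        with pytest.raises(ValueError):
            train_phase(model, data, "carc", TrainConfig(), empty)


class TestMultiRound:
    def test_r0_is_plain_carcinogenicity_training(self):
        mut, carc = toy_set(seed=7, binary=True), toy_set(seed=8)
        model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=0)
        cfg = TrainConfig(rounds=0, max_epochs=5, patience=5)
        _, hist = multi_round_pretrain(model, mut, carc, cfg)
        assert [h.objective for h in hist] == ["carc"]

    def test_r3_executes_six_phases_alternating(self):
        mut, carc = toy_set(seed=7, binary=True), toy_set(seed=8)
        model = PredictorModel(input_dim=10, hidden=HIDDEN, seed=0)
        cfg = TrainConfig(rounds=3, max_epochs=3, patience=3)
        _, hist = multi_round_pretrain(model, mut, carc, cfg)
        assert [h.objective for h in hist] == ["mut", "carc"] * 3


@pytest.fixture(scope="module")
def carc_data(random_molecules):
    from molpotency.model import featurize_molecules

    mols = random_molecules[:90]
    X = featurize_molecules(mols, None)
    rng = np.random.default_rng(0)
    w = rng.standard_normal(X.shape[1]) * 0.05
    y = X @ w + 0.1 * rng.standard_normal(len(mols))
    return mols, LabeledSet([m.id for m in mols], X, y)


class TestSweepAndEnsemble:
    def test_single_config_grid(self, carc_data):
        mols, data = carc_data
        grid = [{"hidden": HIDDEN, "lr": 1e-3, "max_epochs": 5, "patience": 5}]
        ranked = sweep(grid, mols, data, k=3, seed=0)
        assert len(ranked) == 1
        assert ranked[0].mean_score == pytest.approx(
            np.mean(ranked[0].fold_scores)
        )

    def test_broken_lr_ranks_below_sane_config(self, carc_data):
        mols, data = carc_data
        grid = [
            {"hidden": HIDDEN, "lr": 0.0, "max_epochs": 8, "patience": 8},
            {"hidden": HIDDEN, "lr": 1e-3, "max_epochs": 8, "patience": 8},
        ]
        ranked = sweep(grid, mols, data, k=3, seed=0)
        assert ranked[0].config["lr"] == 1e-3

    def test_ensemble_prediction_is_member_mean(self):
        members = []
        for offset in (1.0, 2.0, 3.0):
            m = PredictorModel(input_dim=4, hidden=HIDDEN, seed=0)
            m.carc_head.W[...] = 0
            m.carc_head.b[...] = offset
            # freeze batch-norm at identity so the constant passes through
            members.append(m)
        ens = EnsembleModel(members=members)
        X = np.zeros((3, 4), dtype=np.float32)
        np.testing.assert_allclose(ens.forward(X), 2.0, atol=1e-6)

    def test_identical_members_equal_single_member(self):
        m = PredictorModel(input_dim=4, hidden=HIDDEN, seed=1)
        X = np.random.default_rng(0).standard_normal((5, 4)).astype(np.float32)
        ens = EnsembleModel(members=[m, m.clone(), m.clone()])
        np.testing.assert_allclose(ens.forward(X), m.forward(X, mode="eval"), atol=1e-6)

    def test_ensemble_mse_at_most_worst_member(self, carc_data):
        mols, data = carc_data
        grid = [
            {"hidden": HIDDEN, "lr": 1e-3, "max_epochs": 6, "patience": 6},
            {"hidden": HIDDEN, "lr": 3e-4, "max_epochs": 6, "patience": 6},
            {"hidden": HIDDEN, "lr": 3e-3, "max_epochs": 6, "patience": 6},
        ]
        ranked = sweep(grid, mols, data, k=3, seed=0)
        ens = build_ensemble(ranked, data, k=3, seed=0)
        from molpotency.metrics import mse

        ens_mse = mse(ens.forward(data.X), data.y)
        member_mses = [
            mse(m.forward(data.X, head="carc", mode="eval"), data.y)
            for m in ens.members
        ]
        assert ens_mse <= max(member_mses) + 1e-9

    def test_fewer_than_three_configs_errors(self, carc_data):
        mols, data = carc_data
        grid = [{"hidden": HIDDEN, "lr": 1e-3, "max_epochs": 3, "patience": 3}]
        ranked = sweep(grid, mols, data, k=3, seed=0)
        with pytest.raises(ValueError):
            build_ensemble(ranked, data, k=3)
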