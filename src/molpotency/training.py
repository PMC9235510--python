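"""Training engine: leakage-free splitting, early-stopped phase training,
multi-round mutagenicity/carcinogenicity alternation, a threefold-CV
hyperparameter sweep, and top-3 ensembling.

Multi-round pre-training alternates early-stopped training phases between
the abundant-but-noisy binary mutagenicity objective and the scarce
continuous carcinogenicity objective for a fixed number of cycles (three by
default), ending on carcinogenicity.  Model weights carry across phase
boundaries; optimizer state does not.  The cycling lets the shared trunk
keep signal common to both tasks while task-specific noise is overwritten
each time the objective switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .chem import Molecule
from .metrics import UndefinedMetricError, pearson
from .model import PredictorModel


@dataclass(frozen=True)
class SplitPlan:
    """Canonical-SMILES-deduplicated fold assignment."""

    folds: dict[str, int]  # molecule_id -> fold index
    k: int

    def ids_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.folds.items() if f == fold]


@dataclass
class TrainConfig:
    rounds: int = 3
    patience: int = 10
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class LabeledSet:
    """Feature matrix with aligned ids and targets for one objective."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        if not (len(self.ids) == self.X.shape[0] == self.y.shape[0]):
            raise ValueError("ids, X and y must align")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "LabeledSet":
        idx = np.asarray(idx)
        return LabeledSet(
            ids=[self.ids[i] for i in idx], X=self.X[idx], y=self.y[idx]
        )


def dedup_split(molecules: list[Molecule], k: int, seed: int = 0) -> SplitPlan:
    """Assign canonical-SMILES groups to k folds, round-robin after shuffle.

    Duplicate structures (identical canonical SMILES) always land in the
    same fold, so no structure straddles a split boundary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups: dict[str, list[str]] = {}
    for m in molecules:
        groups.setdefault(m.canonical_smiles, []).append(m.id)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} unique structures for {k} folds")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    folds = {}
    for idx, key in enumerate(keys):
        for mid in groups[key]:
            folds[mid] = idx % k
    return SplitPlan(folds=folds, k=k)


@dataclass
class PhaseHistory:
    objective: str
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_phase(
    model: PredictorModel,
    data: LabeledSet,
    objective: str,
    cfg: TrainConfig,
    val: LabeledSet,
    rng: np.random.Generator | None = None,
) -> tuple[PredictorModel, PhaseHistory]:
    """One early-stopped training phase on a single objective.

    Minibatch Adam on MSE (``carc``) or binary cross-entropy (``mut``);
    stops once validation loss has not improved for ``patience`` epochs and
    restores the best-validation checkpoint.  A fresh optimizer is built
    here, so optimizer state never leaks across phases.
    """
    if data.n == 0 or val.n == 0:
        raise ValueError("empty training or validation set")
    if objective not in ("carc", "mut"):
        raise ValueError(f"unknown objective {objective!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    loss_fn = nn.mse_loss if objective == "carc" else nn.bce_with_logits_loss
    opt = nn.Adam(model.params(objective), lr=cfg.lr)
    history = PhaseHistory(objective=objective)
    best_state = model.state()
    best_val = np.inf
    stale = 0
    y = data.y.astype(nn.DTYPE)
    y_val = val.y.astype(nn.DTYPE)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(data.n)
        epoch_loss = 0.0
        for start in range(0, data.n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward_logits(data.X[idx], objective, train=True, rng=rng)
            loss, dlogits = loss_fn(logits, y[idx])
            model.backward(dlogits, objective)
            opt.step(model.grads(objective))
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / data.n)
        val_logits = model.forward_logits(val.X, objective, train=False)
        val_loss, _ = loss_fn(val_logits, y_val)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state(best_state)
    return model, history


def holdout_split(n: int, frac: float, rng: np.random.Generator):
    """Random index split (train_idx, held_idx) with at least 1 held out."""
    n_held = max(1, int(round(frac * n)))
    perm = rng.permutation(n)
    return perm[n_held:], perm[:n_held]


def multi_round_pretrain(
    model: PredictorModel,
    mut_data: LabeledSet,
    carc_data: LabeledSet,
    cfg: TrainConfig,
    mut_val: LabeledSet | None = None,
    carc_val: LabeledSet | None = None,
) -> tuple[PredictorModel, list[PhaseHistory]]:
    """R cycles of (mutagenicity phase -> carcinogenicity phase).

    With ``cfg.rounds = 0`` this degenerates to a single plain
    carcinogenicity phase.  The final phase is always carcinogenicity.
    """
    if mut_data.n == 0 or carc_data.n == 0:
        raise ValueError("both datasets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    if mut_val is None:
        tr, va = holdout_split(mut_data.n, 0.15, rng)
        mut_data, mut_val = mut_data.subset(tr), mut_data.subset(va)
    if carc_val is None:
        tr, va = holdout_split(carc_data.n, 0.15, rng)
        carc_data, carc_val = carc_data.subset(tr), carc_data.subset(va)
    histories: list[PhaseHistory] = []
    if cfg.rounds == 0:
        _, h = train_phase(model, carc_data, "carc", cfg, carc_val, rng)
        return model, [h]
    for _ in range(cfg.rounds):
        _, h_mut = train_phase(model, mut_data, "mut", cfg, mut_val, rng)
        _, h_carc = train_phase(model, carc_data, "carc", cfg, carc_val, rng)
        histories += [h_mut, h_carc]
    return model, histories


# -- hyperparameter sweep and ensembling -------------------------------------


@dataclass
class RankedConfig:
    config: dict
    fold_scores: list[float]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))


def _build_model(input_dim: int, config: dict, seed: int) -> PredictorModel:
    return PredictorModel(
        input_dim=input_dim,
        hidden=tuple(config.get("hidden", PredictorModel.__dataclass_fields__["hidden"].default)),
        seed=seed,
    )


def _score_or_neginf(pred, y) -> float:
    try:
        return pearson(pred, y)
    except UndefinedMetricError:
        return float("-inf")


def sweep(
    grid: list[dict],
    molecules: list[Molecule],
    data: LabeledSet,
    k: int = 3,
    seed: int = 0,
) -> list[RankedConfig]:
    """Threefold CV over a finite config grid, ranked by mean validation
    Pearson on the carcinogenicity objective (highest first)."""
    if not grid:
        raise ValueError("empty grid")
    plan = dedup_split(molecules, k=k, seed=seed)
    pos_of = {mid: i for i, mid in enumerate(data.ids)}
    ranked = []
    for config in grid:
        cfg = TrainConfig(
            rounds=0,
            lr=config.get("lr", 1e-3),
            batch_size=config.get("batch_size", 64),
            patience=config.get("patience", 10),
            max_epochs=config.get("max_epochs", 200),
            seed=seed,
        )
        fold_scores = []
        for fold in range(k):
            val_idx = [pos_of[i] for i in plan.ids_in_fold(fold) if i in pos_of]
            train_idx = [
                pos_of[i]
                for f in range(k)
                if f != fold
                for i in plan.ids_in_fold(f)
                if i in pos_of
            ]
            model = _build_model(data.X.shape[1], config, seed=seed + fold)
            train_set, val_set = data.subset(train_idx), data.subset(val_idx)
            train_phase(model, train_set, "carc", cfg, val_set,
                        np.random.default_rng(seed + fold))
            pred = model.forward(val_set.X, head="carc", mode="eval")
            fold_scores.append(_score_or_neginf(pred, val_set.y))
        ranked.append(RankedConfig(config=config, fold_scores=fold_scores))
    ranked.sort(key=lambda r: r.mean_score, reverse=True)
    return ranked


@dataclass
class EnsembleModel:
    """Top-k model ensemble; prediction = arithmetic mean of members."""

    members: list[PredictorModel]

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")

    def forward(self, X: np.ndarray, head: str = "carc") -> np.ndarray:
        return np.mean(
            [m.forward(X, head=head, mode="eval") for m in self.members], axis=0
        )


def build_ensemble(
    ranked: list[RankedConfig],
    data: LabeledSet,
    k: int = 3,
    seed: int = 0,
) -> EnsembleModel:
    """Retrain the top-k ranked configs on the full data and average them."""
    if len(ranked) < k:
        raise ValueError(f"need at least {k} ranked configs, got {len(ranked)}")
    rng = np.random.default_rng(seed)
    tr, va = holdout_split(data.n, 0.15, rng)
    train_set, val_set = data.subset(tr), data.subset(va)
    members = []
    for i, rc in enumerate(ranked[:k]):
        cfg = TrainConfig(
            rounds=0,
            lr=rc.config.get("lr", 1e-3),
            batch_size=rc.config.get("batch_size", 64),
            patience=rc.config.get("patience", 10),
            max_epochs=rc.config.get("max_epochs", 200),
            seed=seed + i,
        )
        model = _build_model(data.X.shape[1], rc.config, seed=seed + i)
        train_phase(model, train_set, "carc", cfg, val_set,
                    np.random.default_rng(seed + i))
        members.append(model)
    return EnsembleModel(members=members)


# -- ablation experiment ------------------------------------------------------

ABLATION_VARIANTS = (
    "fingerprint",
    "fingerprint+encoder",
    "fingerprint+encoder+single_pretrain",
    "fingerprint+encoder+multi_round",
)


def run_ablation(
    X_carc_fp: np.ndarray,
    X_carc_full: np.ndarray,
    y_carc: np.ndarray,
    X_mut_full: np.ndarray,
    y_mut: np.ndarray,
    carc_ids: list[str],
    molecules: list[Molecule],
    seeds: list[int],
    cfg: TrainConfig,
    hidden: tuple[int, ...],
    variants=ABLATION_VARIANTS,
    split_seed: int = 0,
) -> dict[str, list[float]]:
    """Held-out Pearson per seed for each architecture/pretraining variant.

    The carcinogenicity set is split once (dedup-aware, 3 folds: train /
    validation / held-out test) and kept fixed across seeds; seeds vary
    weight initialization, dropout and minibatch order only.
    """
    plan = dedup_split(molecules, k=3, seed=split_seed)
    pos_of = {mid: i for i, mid in enumerate(carc_ids)}
    fold_idx = [
        np.array([pos_of[i] for i in plan.ids_in_fold(f) if i in pos_of])
        for f in range(3)
    ]
    tr_idx = np.concatenate([fold_idx[0], fold_idx[1][: len(fold_idx[1]) // 2]])
    va_idx = fold_idx[1][len(fold_idx[1]) // 2 :]
    te_idx = fold_idx[2]

    results: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        for variant in variants:
            X = X_carc_fp if variant == "fingerprint" else X_carc_full
            carc_tr = LabeledSet([carc_ids[i] for i in tr_idx], X[tr_idx], y_carc[tr_idx])
            carc_va = LabeledSet([carc_ids[i] for i in va_idx], X[va_idx], y_carc[va_idx])
            model = PredictorModel(input_dim=X.shape[1], hidden=hidden, seed=seed)
            if variant == "fingerprint+encoder+multi_round":
                rounds = cfg.rounds
            elif variant == "fingerprint+encoder+single_pretrain":
                rounds = 1
            else:
                rounds = 0
            run_cfg = replace(cfg, rounds=rounds, seed=seed)
            if rounds > 0:
                mut_set = LabeledSet(
                    [f"mut{i}" for i in range(X_mut_full.shape[0])], X_mut_full, y_mut
                )
                multi_round_pretrain(model, mut_set, carc_tr, run_cfg, carc_val=carc_va)
            else:
                train_phase(model, carc_tr, "carc", run_cfg, carc_va,
                            np.random.default_rng(seed))
            pred = model.forward(X[te_idx], head="carc", mode="eval")
            results[variant].append(_score_or_neginf(pred, y_carc[te_idx]))
    return results
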