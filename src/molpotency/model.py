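"""The carcinogenicity predictor: an MLP over feature blocks with two heads.

A shared five-layer trunk (dense -> batch-norm -> ReLU -> dropout 0.1 at
every layer) reads the concatenated fingerprint + graph-embedding vector.
Two output heads branch from the trunk: ``carc`` is a single linear unit on
the continuous log-potency scale; ``mut`` is a single linear unit with a
logistic link producing a mutagenicity probability.  Sharing the trunk is
what lets alternating mutagenicity/carcinogenicity training move biological
signal between the two tasks.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .chem import FINGERPRINT_BLOCK_BITS, Molecule, fingerprint_block
from .encoder import EmbeddingProvider

TRUNK_DEPTH = 5
DROPOUT_P = 0.1
DEFAULT_HIDDEN = (1024, 512, 256, 128, 64)


class ConfigurationError(ValueError):
    pass


@dataclass
class PredictorModel:
    """Five-layer MLP trunk with carcinogenicity and mutagenicity heads."""

    input_dim: int
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    seed: int = 0
    trunk: nn.Sequential = field(init=False, repr=False)
    carc_head: nn.Dense = field(init=False, repr=False)
    mut_head: nn.Dense = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.hidden) != TRUNK_DEPTH:
            raise ConfigurationError(
                f"trunk must have {TRUNK_DEPTH} layers, got {len(self.hidden)}"
            )
        rng = np.random.default_rng(self.seed)
        layers: list[nn.Layer] = []
        n_in = self.input_dim
        for width in self.hidden:
            layers += [
                nn.Dense(n_in, width, rng),
                nn.BatchNorm(width),
                nn.ReLU(),
                nn.Dropout(DROPOUT_P),
            ]
            n_in = width
        self.trunk = nn.Sequential(layers)
        self.carc_head = nn.Dense(n_in, 1, rng)
        self.mut_head = nn.Dense(n_in, 1, rng)

    # -- forward / backward -------------------------------------------------

    def forward(
        self, X: np.ndarray, head: str = "carc", mode: str = "eval", rng=None
    ) -> np.ndarray:
        """Predictions for a (n, input_dim) batch.

        ``carc`` returns unbounded log-potency values; ``mut`` returns
        probabilities in [0, 1].  Eval mode is deterministic (dropout off,
        batch-norm running statistics), so predictions do not depend on
        batch composition.
        """
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ConfigurationError(
                f"feature width {X.shape[1]} != model input width {self.input_dim}"
            )
        train = mode == "train"
        if train and rng is None:
            raise ValueError("train-mode forward requires an rng for dropout")
        z = self.trunk.forward(X, train, rng)
        if head == "carc":
            return self.carc_head.forward(z, train)[:, 0]
        if head == "mut":
            logits = self.mut_head.forward(z, train)[:, 0]
            return nn.sigmoid(logits)
        raise ValueError(f"unknown head {head!r}")

    def forward_logits(self, X: np.ndarray, head: str, train: bool, rng=None) -> np.ndarray:
        """Pre-link outputs (identical to forward for carc) for training."""
        z = self.trunk.forward(np.asarray(X, dtype=nn.DTYPE), train, rng)
        h = self.carc_head if head == "carc" else self.mut_head
        return h.forward(z, train)[:, 0]

    def backward(self, dout: np.ndarray, head: str) -> None:
        h = self.carc_head if head == "carc" else self.mut_head
        self.trunk.backward(h.backward(dout[:, None].astype(nn.DTYPE)))

    def params(self, head: str) -> list[np.ndarray]:
        h = self.carc_head if head == "carc" else self.mut_head
        return self.trunk.params() + h.params()

    def grads(self, head: str) -> list[np.ndarray]:
        h = self.carc_head if head == "carc" else self.mut_head
        return self.trunk.grads() + h.grads()

    def state(self) -> list[np.ndarray]:
        """Deep copy of all weights and batch-norm running statistics."""
        arrays = self.trunk.params() + self.carc_head.params() + self.mut_head.params()
        for layer in self.trunk.layers:
            if isinstance(layer, nn.BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
        return [a.copy() for a in arrays]

    def load_state(self, state: list[np.ndarray]) -> None:
        arrays = self.trunk.params() + self.carc_head.params() + self.mut_head.params()
        for layer in self.trunk.layers:
            if isinstance(layer, nn.BatchNorm):
                arrays += [layer.running_mean, layer.running_var]
        if len(arrays) != len(state):
            raise ConfigurationError("checkpoint does not match model architecture")
        for dst, src in zip(arrays, state):
            dst[...] = src

    def clone(self) -> "PredictorModel":
        other = PredictorModel(input_dim=self.input_dim, hidden=self.hidden, seed=self.seed)
        other.load_state(self.state())
        return other


# -- featurization glue ------------------------------------------------------


def featurize_molecules(
    molecules: list[Molecule],
    encoder: EmbeddingProvider | None,
    radius: int = 2,
) -> np.ndarray:
    """Feature matrix: fingerprint block, plus graph embedding if provided."""
    rows = []
    for m in molecules:
        fp = fingerprint_block(m, radius=radius).astype(np.float64)
        if encoder is not None:
            fp = np.concatenate([fp, encoder(m)])
        rows.append(fp)
    return np.asarray(rows, dtype=nn.DTYPE)


def input_dim_for(encoder: EmbeddingProvider | None) -> int:
    return FINGERPRINT_BLOCK_BITS + (encoder.dim if encoder is not None else 0)


def predict_batch(
    model: PredictorModel,
    molecules: list[Molecule],
    encoder: EmbeddingProvider | None = None,
    head: str = "carc",
) -> np.ndarray:
    """Eval-mode predictions for a list of molecules, in input order."""
    X = featurize_molecules(molecules, encoder)
    return model.forward(X, head=head, mode="eval")


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(model: PredictorModel, path, extra_config: dict | None = None) -> None:
    """Single-archive checkpoint: weights + architecture + featurization config."""
    config = {
        "input_dim": model.input_dim,
        "hidden": list(model.hidden),
        "seed": model.seed,
        "fingerprint": {
            "schemes": ["circular", "path", "structural_key"],
            "radius": 2,
            "n_bits": 2048,
        },
    }
    if extra_config:
        config.update(extra_config)
    state = model.state()
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8),
        **{f"arr_{i}": a for i, a in enumerate(state)},
    )


def load_checkpoint(path) -> tuple[PredictorModel, dict]:
    with np.load(path) as archive:
        config = json.loads(bytes(archive["__config__"]).decode())
        state = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
    model = PredictorModel(
        input_dim=config["input_dim"], hidden=tuple(config["hidden"]), seed=config["seed"]
    )
    model.load_state(state)
    return model, config
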