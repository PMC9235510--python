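"""Reference synthetic study: fixed conditions for the ablation experiment.

One place defines the benchmark everyone runs — the synthetic bundle
(1500 carcinogenicity training molecules with multi-experiment TD50s, 3000
binary mutagenicity molecules at 70% concordance, a 400-molecule
extreme-sampled external test set, planted toxicophore effect weight 2 log
units) and the scaled-down model configuration used on it (a frozen
32-dimensional graph encoder and a five-layer trunk of widths
128/64/32/32/16 trained with minibatch Adam and early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderEmbeddingProvider, EncoderParams
from .model import featurize_molecules
from .synthetic import SyntheticBundle, SyntheticConfig, make_benchmark
from .training import ABLATION_VARIANTS, TrainConfig, run_ablation

N_TRAIN = 1500
N_MUT = 3000
N_TEST = 400
REFERENCE_HIDDEN = (128, 64, 32, 32, 16)
ENCODER_DIM = 32
N_ABLATION_SEEDS = 20


def reference_train_config() -> TrainConfig:
    return TrainConfig(rounds=3, patience=3, lr=1e-3, batch_size=128, max_epochs=30)


def reference_bundle(seed: int = 1) -> SyntheticBundle:
    return make_benchmark(
        SyntheticConfig(seed=seed), n_train=N_TRAIN, n_mut=N_MUT, n_test=N_TEST
    )


@dataclass
class ReferenceFeatures:
    """Featurized views of a bundle: fingerprint-only and full blocks."""

    X_carc_fp: np.ndarray
    X_carc_full: np.ndarray
    X_mut_full: np.ndarray
    X_test_full: np.ndarray
    encoder: EncoderEmbeddingProvider


def featurize_bundle(bundle: SyntheticBundle, encoder_seed: int = 1) -> ReferenceFeatures:
    encoder = EncoderEmbeddingProvider(
        EncoderParams(L=3, hidden_dim=ENCODER_DIM, d=ENCODER_DIM, seed=encoder_seed)
    )
    return ReferenceFeatures(
        X_carc_fp=featurize_molecules(bundle.train_molecules, None),
        X_carc_full=featurize_molecules(bundle.train_molecules, encoder),
        X_mut_full=featurize_molecules(bundle.mut_molecules, encoder),
        X_test_full=featurize_molecules(bundle.test_molecules, encoder),
        encoder=encoder,
    )


def reference_ablation(
    bundle: SyntheticBundle,
    feats: ReferenceFeatures,
    seeds: list[int] | None = None,
    variants=ABLATION_VARIANTS,
) -> dict[str, list[float]]:
    """Held-out Pearson per seed and variant under the reference conditions."""
    if seeds is None:
        seeds = list(range(N_ABLATION_SEEDS))
    return run_ablation(
        X_carc_fp=feats.X_carc_fp,
        X_carc_full=feats.X_carc_full,
        y_carc=bundle.train_y,
        X_mut_full=feats.X_mut_full,
        y_mut=bundle.mut_labels.astype(float),
        carc_ids=[m.id for m in bundle.train_molecules],
        molecules=bundle.train_molecules,
        seeds=seeds,
        cfg=reference_train_config(),
        hidden=REFERENCE_HIDDEN,
        variants=variants,
        split_seed=1,
    )
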