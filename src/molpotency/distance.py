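"""Dataset distances over binary fingerprints.

Tanimoto similarity T(x, y) = <x, y> / (|x|^2 + |y|^2 - <x, y>) between
molecules (the set formulation |x ∩ y| / |x ∪ y| on binary vectors); mean
pairwise Tanimoto distance as a within-dataset diversity measure; and the
unbiased empirical maximum mean discrepancy with the Tanimoto kernel as a
distance between dataset partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DatasetPartition:
    """A named set of binary fingerprints (circular scheme by convention)."""

    name: str
    fingerprints: np.ndarray  # (n, n_bits) 0/1

    def __post_init__(self):
        fp = np.asarray(self.fingerprints)
        if fp.ndim != 2:
            raise ValueError("fingerprints must be a 2-D array")
        if not np.isin(fp, (0, 1)).all():
            raise ValueError("fingerprints must be binary")

    @property
    def n(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise MMD values between named partitions.

    The diagonal is Eq.-style self-MMD of each partition with itself (not
    forced to zero: the unbiased estimator is not exactly zero for X = X).
    """

    names: tuple[str, ...]
    values: np.ndarray


def tanimoto(x, y) -> float:
    """Tanimoto similarity of two binary vectors; errors if both all-zero."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0:
        raise ValueError("Tanimoto undefined for two all-zero vectors")
    return dot / denom


def tanimoto_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between fingerprint rows of X and Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    dot = X @ Y.T
    nx = (X * X).sum(axis=1)[:, None]
    ny = (Y * Y).sum(axis=1)[None, :]
    denom = nx + ny - dot
    if (denom == 0).any():
        raise ValueError("Tanimoto undefined: all-zero fingerprint pair")
    return dot / denom


def diversity(p: DatasetPartition) -> float:
    """Mean Tanimoto distance (1 - T) over all unordered distinct pairs."""
    if p.n < 2:
        raise ValueError("diversity needs at least 2 fingerprints")
    K = tanimoto_kernel(p.fingerprints, p.fingerprints)
    iu = np.triu_indices(p.n, k=1)
    return float(np.mean(1.0 - K[iu]))


def mmd(px: DatasetPartition, py: DatasetPartition) -> float:
    """Unbiased empirical MMD with the Tanimoto kernel.

    Off-diagonal within-set kernel means (divisors n(n-1) and m(m-1)) minus
    twice the cross mean (divisor nm).  Can be slightly negative for close
    distributions; values are reported as-is.
    """
    if px.n < 2 or py.n < 2:
        raise ValueError("MMD needs at least 2 fingerprints per partition")
    if px.n_bits != py.n_bits:
        raise ValueError("partitions must share fingerprint width")
    X, Y = px.fingerprints, py.fingerprints
    n, m = px.n, py.n
    Kxx = tanimoto_kernel(X, X)
    Kyy = tanimoto_kernel(Y, Y)
    Kxy = tanimoto_kernel(X, Y)
    term_x = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
    term_y = (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
    term_xy = 2.0 * Kxy.sum() / (n * m)
    return float(term_x + term_y - term_xy)


def partition_matrix(partitions: list[DatasetPartition]) -> DistanceMatrix:
    """All pairwise MMDs between the given partitions (symmetric)."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    k = len(partitions)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            values[i, j] = values[j, i] = mmd(partitions[i], partitions[j])
    return DistanceMatrix(names=tuple(p.name for p in partitions), values=values)


def plot_partition_heatmap(matrix: DistanceMatrix, path) -> None:
    """Render the distance matrix as an annotated heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.names) + 2,) * 2)
    im = ax.imshow(matrix.values, cmap="viridis")
    ax.set_xticks(range(len(matrix.names)), matrix.names, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.names)), matrix.names)
    for i in range(len(matrix.names)):
        for j in range(len(matrix.names)):
            ax.text(j, i, f"{matrix.values[i, j]:.3f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="MMD (Tanimoto kernel)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
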