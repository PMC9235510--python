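"""Graph encoder: message passing plus node-wise self-attention.

The encoder maps a molecular graph to a fixed-length embedding in three
stages:

1. a learned linear map of raw atom features into a hidden state h^(0);
2. L rounds of message passing, where node i aggregates
   m_i = sum_{j in N(i)} (W_msg h_j + W_edge e_ij) over its one-hop
   neighborhood and updates h_i = sigma(W m_i + b);
3. one multi-head scaled-dot-product attention block over *all* nodes
   (attention ignores graph edges, widening the receptive field beyond the
   L-hop neighborhood), followed by mean pooling over nodes.

The module is forward-only NumPy; in the full predictor the encoder is used
frozen, as a structural-embedding provider concatenated with fingerprints,
and a table of externally precomputed embeddings can stand in for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import ATOM_FEATURE_NAMES, BOND_FEATURE_NAMES, MolGraph


def _relu(x):
    return np.maximum(x, 0.0)


def _identity(x):
    return x


_ACTIVATIONS = {"relu": _relu, "identity": _identity}


@dataclass
class EncoderParams:
    """Weights and hyperparameters of the graph encoder.

    ``attn_scale`` selects the attention logit scaling: ``"sqrt_d"`` (the
    standard scaled dot product, default) or ``"d"`` (divide by the full
    embedding width).
    """

    L: int = 3
    hidden_dim: int = 128
    d: int = 128
    n_heads: int = 4
    activation: str = "relu"
    attn_scale: str = "sqrt_d"
    seed: int = 0
    n_atom_features: int = len(ATOM_FEATURE_NAMES)
    n_bond_features: int = len(BOND_FEATURE_NAMES)
    weights: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.L < 0:
            raise ValueError("L must be >= 0")
        if self.d % self.n_heads:
            raise ValueError("d must be divisible by n_heads")
        if self.attn_scale not in ("sqrt_d", "d"):
            raise ValueError(f"unknown attn_scale {self.attn_scale!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not self.weights:
            self.weights = self._init_weights()

    def _init_weights(self) -> dict:
        rng = np.random.default_rng(self.seed)
        h, d = self.hidden_dim, self.d

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        w = {"W_in": glorot(self.n_atom_features, h), "b_in": np.zeros(h)}
        for l in range(self.L):
            w[f"W_msg_{l}"] = glorot(h, h)
            w[f"W_edge_{l}"] = glorot(self.n_bond_features, h)
            w[f"W_{l}"] = glorot(h, h)
            w[f"b_{l}"] = np.zeros(h)
        w["W_q"] = glorot(h, d)
        w["W_k"] = glorot(h, d)
        w["W_v"] = glorot(h, d)
        return w

    @property
    def sigma(self):
        return _ACTIVATIONS[self.activation]


@dataclass
class NodeStates:
    """Per-node hidden states h_i and message aggregates m_i."""

    h: np.ndarray  # (n_nodes, hidden_dim)
    m: np.ndarray | None = None


@dataclass
class AttentionOutput:
    """Attended node vectors A(i) and the attention distributions."""

    A: np.ndarray            # (n_nodes, d)
    attn_weights: np.ndarray  # (n_heads, n_nodes, n_nodes), rows sum to 1


def init_states(g: MolGraph, p: EncoderParams) -> NodeStates:
    """h^(0): linear map of raw atom features into the hidden width."""
    if g.nodes.shape[1] != p.n_atom_features:
        raise ValueError(
            f"graph has {g.nodes.shape[1]} atom features, encoder expects {p.n_atom_features}"
        )
    return NodeStates(h=g.nodes @ p.weights["W_in"] + p.weights["b_in"])


def message_step(g: MolGraph, s: NodeStates, layer: int, p: EncoderParams) -> NodeStates:
    """One message-passing round: h_i = sigma(W m_i + b) with summed messages.

    The message from j to i is an edge-conditioned linear map
    W_msg h_j + W_edge e_ij; nodes with no neighbors get m_i = 0, so their
    update is the closed form sigma(b).
    """
    if not 0 <= layer < max(p.L, 1):
        raise ValueError(f"layer {layer} out of range for L={p.L}")
    w = p.weights
    m = np.zeros((g.n_nodes, p.hidden_dim))
    if g.edges.size:
        src = g.edges[:, 1]  # message flows j -> i along edge (i, j)
        dst = g.edges[:, 0]
        msgs = s.h[src] @ w[f"W_msg_{layer}"] + g.edge_features @ w[f"W_edge_{layer}"]
        np.add.at(m, dst, msgs)
    h = p.sigma(m @ w[f"W_{layer}"] + w[f"b_{layer}"])
    return NodeStates(h=h, m=m)


def attend(s: NodeStates, p: EncoderParams) -> AttentionOutput:
    """Multi-head scaled-dot-product attention over all nodes.

    Queries, keys and values are linear projections of the final node
    states; the softmax runs over every node in the graph, so attention is
    independent of the bond topology.
    """
    w = p.weights
    q, k, v = s.h @ w["W_q"], s.h @ w["W_k"], s.h @ w["W_v"]
    n = q.shape[0]
    dh = p.d // p.n_heads
    scale = np.sqrt(p.d) if p.attn_scale == "sqrt_d" else float(p.d)
    A = np.empty((n, p.d))
    weights = np.empty((p.n_heads, n, n))
    for head in range(p.n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        logits = q[:, sl] @ k[:, sl].T / scale
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        attn = e / e.sum(axis=1, keepdims=True)
        weights[head] = attn
        A[:, sl] = attn @ v[:, sl]
    return AttentionOutput(A=A, attn_weights=weights)


def encode_graph(g: MolGraph, p: EncoderParams) -> np.ndarray:
    """Full forward pass: init -> L message rounds -> attention -> mean pool.

    Returns a length-``d`` embedding.  Permutation-invariant: relabeling the
    atoms changes the result only by floating-point round-off.
    """
    s = init_states(g, p)
    for layer in range(p.L):
        s = message_step(g, s, layer, p)
    out = attend(s, p)
    return out.A.mean(axis=0)


class EmbeddingProvider:
    """Maps molecule ids to graph embeddings.

    Either computed on the fly from an :class:`EncoderParams` (frozen
    encoder) or looked up from an external table of precomputed vectors.
    """

    def __init__(self, dim: int):
        self.dim = dim

    def __call__(self, molecule) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class EncoderEmbeddingProvider(EmbeddingProvider):
    def __init__(self, params: EncoderParams):
        super().__init__(dim=params.d)
        self.params = params
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, molecule) -> np.ndarray:
        from .chem import mol_to_graph

        key = molecule.canonical_smiles
        emb = self._cache.get(key)
        if emb is None:
            emb = self._cache[key] = encode_graph(mol_to_graph(molecule), self.params)
        return emb


class TableEmbeddingProvider(EmbeddingProvider):
    """Precomputed per-molecule embeddings, looked up by id."""

    def __init__(self, table: dict[str, np.ndarray]):
        if not table:
            raise ValueError("empty embedding table")
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        super().__init__(dim=dims.pop())
        self.table = {k: np.asarray(v, dtype=np.float64) for k, v in table.items()}

    def __call__(self, molecule) -> np.ndarray:
        mol_id = molecule if isinstance(molecule, str) else molecule.id
        if mol_id not in self.table:
            raise KeyError(f"no precomputed embedding for molecule id {mol_id!r}")
        return self.table[mol_id]


def load_external_embeddings(path) -> TableEmbeddingProvider:
    """Load a CSV embedding table: columns id, e0 ... e_{dim-1}."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str})
    cols = [c for c in df.columns if c != "id"]
    return TableEmbeddingProvider(
        {row.id: np.asarray([getattr(row, c) for c in cols]) for row in df.itertuples(index=False)}
    )
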