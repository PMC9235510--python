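"""Molecule parsing, canonicalization and featurization.

Molecules enter the pipeline as SMILES strings and are converted into the
two representations the predictor consumes: binary substructure fingerprints
(circular/Morgan, path/RDKit, structural-key/MACCS) and a node-edge molecular
graph with per-atom and per-bond feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.error")

#: Fixed fingerprint widths. Circular and path fingerprints are hashed into
#: 2048 bits; the structural-key scheme is the published 166-key catalogue
#: plus one padding bit (bit 0 is never set).
N_BITS_HASHED = 2048
N_BITS_STRUCTURAL_KEY = 167

#: Total width of the three concatenated fingerprint schemes.
FINGERPRINT_BLOCK_BITS = 2 * N_BITS_HASHED + N_BITS_STRUCTURAL_KEY

ATOM_FEATURE_NAMES = ("atomic_num", "mass", "formal_charge", "degree", "aromatic", "in_ring")
BOND_FEATURE_NAMES = ("order", "aromatic", "in_ring")


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""

    def __init__(self, smiles: str, reason: str = "unparsable or valence-violating SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule with its canonical SMILES form.

    ``canonical_smiles`` is a fixed point of canonicalization: feeding it back
    through the parser reproduces the identical string, so canonical equality
    is structure equality (within one toolkit version).
    """

    id: str
    smiles: str
    canonical_smiles: str
    _mol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol

    @property
    def n_heavy_atoms(self) -> int:
        return self._mol.GetNumAtoms()


@dataclass(frozen=True)
class MolGraph:
    """Node-edge graph of a molecule: G = (V, E).

    ``nodes`` is an (n_nodes, 6) array of atom features (atomic number, mass,
    formal charge, degree, aromatic flag, ring flag); ``edges`` holds both
    directions of every bond as (i, j) index pairs aligned with
    ``edge_features`` rows (bond order, aromatic flag, ring flag).
    """

    nodes: np.ndarray
    edges: np.ndarray        # (n_edges, 2) int, symmetric: (i,j) and (j,i)
    edge_features: np.ndarray  # (n_edges, 3) float
    n_nodes: int

    def __post_init__(self):
        if self.edges.size and self.edges.max() >= self.n_nodes:
            raise ValueError("edge index out of range")


@dataclass(frozen=True)
class FingerprintVector:
    """A binary substructure descriptor vector under a named scheme."""

    bits: np.ndarray
    scheme: str  # circular | path | structural_key

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])


@dataclass(frozen=True)
class FeatureBlock:
    """Concatenation [circular | path | structural_key | graph_embedding].

    ``layout`` maps each segment name to its (start, stop) offsets; the
    offsets partition ``vector`` exactly.
    """

    vector: np.ndarray
    layout: dict

    def segment(self, name: str) -> np.ndarray:
        start, stop = self.layout[name]
        return self.vector[start:stop]


def parse_smiles(s: str, id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises :class:`InvalidMoleculeError` for unparsable or valence-violating
    input (RDKit sanitization is the validity authority).
    """
    if not s:
        raise InvalidMoleculeError(s, "empty SMILES")
    mol = Chem.MolFromSmiles(s)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidMoleculeError(s)
    return Molecule(id=id, smiles=s, canonical_smiles=Chem.MolToSmiles(mol), _mol=mol)


def canonicalize(m: Molecule) -> str:
    """Canonical SMILES of ``m``; equal structures map to equal strings.

    Idempotent: canonicalizing the canonical string returns it unchanged.
    Strings are implementation-defined — stable within one toolkit version,
    not across toolkits.
    """
    return m.canonical_smiles


_MORGAN_GENERATORS: dict = {}
_RDKIT_GENERATORS: dict = {}


def circular_fingerprint(m: Molecule, radius: int = 2, n_bits: int = N_BITS_HASHED) -> FingerprintVector:
    """Hashed circular (Morgan/ECFP-style) fingerprint of radius ``radius``."""
    key = (radius, n_bits)
    gen = _MORGAN_GENERATORS.get(key)
    if gen is None:
        gen = _MORGAN_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(gen.GetFingerprint(m.rdkit_mol).GetOnBits())] = 1
    return FingerprintVector(bits=bits, scheme="circular")


def path_fingerprint(m: Molecule, n_bits: int = N_BITS_HASHED) -> FingerprintVector:
    """Hashed path-based (RDKit topological) fingerprint, path lengths 1-7."""
    gen = _RDKIT_GENERATORS.get(n_bits)
    if gen is None:
        gen = _RDKIT_GENERATORS[n_bits] = rdFingerprintGenerator.GetRDKitFPGenerator(
            minPath=1, maxPath=7, fpSize=n_bits
        )
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(gen.GetFingerprint(m.rdkit_mol).GetOnBits())] = 1
    return FingerprintVector(bits=bits, scheme="path")


def structural_key_fingerprint(m: Molecule) -> FingerprintVector:
    """166-key structural-key (MACCS) fingerprint plus one padding bit."""
    bits = np.zeros(N_BITS_STRUCTURAL_KEY, dtype=np.uint8)
    bits[list(MACCSkeys.GenMACCSKeys(m.rdkit_mol).GetOnBits())] = 1
    return FingerprintVector(bits=bits, scheme="structural_key")


def fingerprint_block(m: Molecule, radius: int = 2) -> np.ndarray:
    """The three schemes concatenated: circular | path | structural_key."""
    return np.concatenate(
        [
            circular_fingerprint(m, radius=radius).bits,
            path_fingerprint(m).bits,
            structural_key_fingerprint(m).bits,
        ]
    )


def mol_to_graph(m: Molecule) -> MolGraph:
    """Convert a molecule into its heavy-atom node-edge graph.

    One node per heavy atom; each bond contributes both directed edges so
    message passing can treat the edge list as an inbox per node.
    """
    mol = m.rdkit_mol
    n = mol.GetNumAtoms()
    nodes = np.zeros((n, len(ATOM_FEATURE_NAMES)), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        nodes[i] = (
            atom.GetAtomicNum(),
            atom.GetMass(),
            atom.GetFormalCharge(),
            atom.GetDegree(),
            float(atom.GetIsAromatic()),
            float(atom.IsInRing()),
        )
    edges = []
    efeat = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = (bond.GetBondTypeAsDouble(), float(bond.GetIsAromatic()), float(bond.IsInRing()))
        edges.append((i, j))
        efeat.append(f)
        edges.append((j, i))
        efeat.append(f)
    edges_arr = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    efeat_arr = np.asarray(efeat, dtype=np.float64).reshape(-1, len(BOND_FEATURE_NAMES))
    return MolGraph(nodes=nodes, edges=edges_arr, edge_features=efeat_arr, n_nodes=n)


def build_feature_block(
    m: Molecule, graph_embedding: np.ndarray, radius: int = 2
) -> FeatureBlock:
    """Assemble the model input: fingerprints plus the graph embedding.

    Raises ``ValueError`` if the embedding is not a 1-D vector (its length
    defines the ``graph_embedding`` segment of the layout).
    """
    emb = np.asarray(graph_embedding, dtype=np.float64).ravel()
    if emb.ndim != 1:
        raise ValueError("graph_embedding must be a vector")
    fp = fingerprint_block(m, radius=radius)
    vector = np.concatenate([fp.astype(np.float64), emb])
    c, p, s = N_BITS_HASHED, N_BITS_HASHED, N_BITS_STRUCTURAL_KEY
    layout = {
        "circular": (0, c),
        "path": (c, c + p),
        "structural_key": (c + p, c + p + s),
        "graph_embedding": (c + p + s, c + p + s + emb.shape[0]),
    }
    return FeatureBlock(vector=vector, layout=layout)
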