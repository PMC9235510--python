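"""Counterfactual interpretability: local chemical-subspace sampling,
threshold-based counterfactual selection, and toxicophore enrichment.

To explain a prediction we sample the chemical neighborhood of a molecule
by applying small random edits to its molecular graph (atom substitutions,
fragment attachments, terminal-atom deletions, bond-order changes), keep
the chemically valid, structurally distinct results, and score them with
the model.  A *positive counterfactual* is the closest sampled molecule (by
Tanimoto distance) whose prediction exceeds an upper threshold; a *negative
counterfactual* the closest one below a lower threshold.  Aggregating over
a test set, we compare the frequency of known toxicophore substructures
(SMARTS catalogues) in positive/negative counterfactuals against the
original molecules: a model that has learned real structure-toxicity
relationships enriches positives and depletes negatives for toxicophores.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .chem import InvalidMoleculeError, Molecule, circular_fingerprint, parse_smiles
from .distance import tanimoto


@dataclass(frozen=True)
class ToxicophoreDef:
    """A named toxicophore: a molecule matches iff >= 1 SMARTS pattern hits."""

    name: str
    patterns: tuple[str, ...]
    queries: tuple = ()

    def __post_init__(self):
        compiled = []
        for p in self.patterns:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise ValueError(f"toxicophore {self.name!r}: bad SMARTS {p!r}")
            compiled.append(q)
        object.__setattr__(self, "queries", tuple(compiled))

    def matches(self, m: Molecule) -> bool:
        return any(m.rdkit_mol.HasSubstructMatch(q) for q in self.queries)


def load_toxicophore_catalogue(path=None) -> list[ToxicophoreDef]:
    """Load a TSV catalogue (name, comma-separated SMARTS).

    Without a path, loads the packaged seven-entry catalogue of classic
    structural alerts (nitroso, aliphatic halide, aromatic nitro, aromatic
    amine, three-membered heterocycle, azo, heteroatom-bonded heteroatom).
    """
    if path is None:
        ref = importlib.resources.files("molpotency") / "data" / "toxicophores.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        ToxicophoreDef(
            name=row.name_, patterns=tuple(s.strip() for s in row.smarts.split(","))
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def match_toxicophores(m: Molecule, defs: list[ToxicophoreDef]) -> dict[str, bool]:
    return {d.name: d.matches(m) for d in defs}


# -- subspace sampling -------------------------------------------------------

_ELEMENTS = (6, 7, 8, 9, 16, 17, 35, 53)
_FRAGMENTS = (
    "C", "CC", "O", "OC", "N", "Cl", "F", "Br", "I",
    "N=O", "[N+](=O)[O-]", "C=O", "C#N", "S", "NN", "NO",
)


@dataclass
class MutationConfig:
    max_mutations: int = 3
    max_attempt_factor: int = 20


@dataclass(frozen=True)
class CounterfactualSample:
    smiles: str
    tanimoto_distance: float
    prediction: float | None = None


@dataclass(frozen=True)
class CounterfactualPair:
    base: Molecule
    base_prediction: float
    positive: CounterfactualSample | None
    negative: CounterfactualSample | None


def _substitute_atom(rw: Chem.RWMol, rng) -> bool:
    idx = int(rng.integers(rw.GetNumAtoms()))
    atom = rw.GetAtomWithIdx(idx)
    choices = [z for z in _ELEMENTS if z != atom.GetAtomicNum()]
    atom.SetAtomicNum(int(choices[rng.integers(len(choices))]))
    atom.SetFormalCharge(0)
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    return True


def _add_fragment(rw: Chem.RWMol, rng) -> bool:
    sites = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not sites:
        return False
    site = int(sites[rng.integers(len(sites))])
    frag = Chem.MolFromSmiles(_FRAGMENTS[rng.integers(len(_FRAGMENTS))])
    offset = rw.GetNumAtoms()
    for atom in frag.GetAtoms():
        rw.AddAtom(atom)
    for bond in frag.GetBonds():
        rw.AddBond(offset + bond.GetBeginAtomIdx(), offset + bond.GetEndAtomIdx(),
                   bond.GetBondType())
    rw.AddBond(site, offset, Chem.BondType.SINGLE)
    return True


def _delete_atom(rw: Chem.RWMol, rng) -> bool:
    if rw.GetNumAtoms() < 2:
        return False
    terminals = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
    if not terminals:
        return False
    rw.RemoveAtom(int(terminals[rng.integers(len(terminals))]))
    return True


def _change_bond(rw: Chem.RWMol, rng) -> bool:
    bonds = [
        b for b in rw.GetBonds()
        if not b.GetIsAromatic()
        and b.GetBondType() in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE)
    ]
    if not bonds:
        return False
    bond = bonds[int(rng.integers(len(bonds)))]
    new = (Chem.BondType.DOUBLE if bond.GetBondType() == Chem.BondType.SINGLE
           else Chem.BondType.SINGLE)
    bond.SetBondType(new)
    return True


_MUTATIONS = (_substitute_atom, _add_fragment, _delete_atom, _change_bond)


def _mutate(mol: Chem.Mol, n_edits: int, rng) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    for _ in range(n_edits):
        op = _MUTATIONS[int(rng.integers(len(_MUTATIONS)))]
        if not op(rw, rng):
            return None
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out if out.GetNumAtoms() >= 1 else None


def sample_subspace(
    base: Molecule,
    n_samples: int = 2000,
    mutation_cfg: MutationConfig | None = None,
    seed: int = 0,
) -> list[CounterfactualSample]:
    """Sample the local chemical subspace of ``base`` by random graph edits.

    Each sample applies 1..max_mutations random edits, keeps only valid
    structures, and deduplicates by canonical SMILES; the base structure
    itself is excluded.  The returned list can be shorter than
    ``n_samples`` when validity filtering is aggressive.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = mutation_cfg or MutationConfig()
    rng = np.random.default_rng(seed)
    base_fp = circular_fingerprint(base).bits
    seen = {base.canonical_smiles}
    out: list[CounterfactualSample] = []
    for _ in range(cfg.max_attempt_factor * n_samples):
        if len(out) >= n_samples:
            break
        n_edits = int(rng.integers(1, cfg.max_mutations + 1))
        mutant = _mutate(base.rdkit_mol, n_edits, rng)
        if mutant is None:
            continue
        smiles = Chem.MolToSmiles(mutant)
        if smiles in seen:
            continue
        seen.add(smiles)
        try:
            mol = parse_smiles(smiles)
        except InvalidMoleculeError:
            continue
        dist = 1.0 - tanimoto(base_fp, circular_fingerprint(mol).bits)
        out.append(CounterfactualSample(smiles=smiles, tanimoto_distance=dist))
    return out


def select_counterfactuals(
    base: Molecule,
    base_pred: float,
    samples: list[CounterfactualSample],
    upper: float,
    lower: float,
) -> CounterfactualPair:
    """Minimal-distance samples crossing the prediction thresholds.

    ``positive``: closest sample with prediction >= upper; ``negative``:
    closest with prediction <= lower; either may be absent.  Requires
    ``upper > base_pred > lower``.
    """
    if not upper > base_pred > lower:
        raise ValueError(
            f"threshold ordering violated: need upper ({upper}) > base "
            f"({base_pred}) > lower ({lower})"
        )
    scored = [s for s in samples if s.prediction is not None]
    pos = [s for s in scored if s.prediction >= upper]
    neg = [s for s in scored if s.prediction <= lower]
    key = lambda s: s.tanimoto_distance
    return CounterfactualPair(
        base=base,
        base_prediction=base_pred,
        positive=min(pos, key=key) if pos else None,
        negative=min(neg, key=key) if neg else None,
    )


# -- enrichment statistics ---------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def frequency_ratio(freq_group_pct: float, freq_orig_pct: float) -> float:
    """Group frequency divided by originals frequency; NaN when undefined."""
    if freq_orig_pct <= 0:
        return float("nan")
    return freq_group_pct / freq_orig_pct


def enrichment_table(
    originals: list[Molecule],
    positives: list[Molecule],
    negatives: list[Molecule],
    defs: list[ToxicophoreDef],
) -> pd.DataFrame:
    """Per-toxicophore frequency comparison of counterfactuals vs originals.

    For each definition: match counts and frequencies (%) in the three
    groups; the frequency ratio of each counterfactual group versus
    originals (the parenthetical reported alongside the percentages) plus
    the cross-product odds ratio; a two-sided Fisher exact p-value on the
    2x2 matched/unmatched x group/originals table; and Benjamini-Hochberg
    adjusted q-values across definitions within each group.
    """
    if not (originals and positives and negatives):
        raise ValueError("all three molecule lists must be nonempty")
    rows = []
    for d in defs:
        counts = {}
        for label, group in (("orig", originals), ("pos", positives), ("neg", negatives)):
            counts[label] = sum(d.matches(m) for m in group)
        n_o, n_p, n_n = len(originals), len(positives), len(negatives)
        f_o = 100.0 * counts["orig"] / n_o
        f_p = 100.0 * counts["pos"] / n_p
        f_n = 100.0 * counts["neg"] / n_n
        row = {
            "toxicophore": d.name,
            "n_originals": n_o, "n_positives": n_p, "n_negatives": n_n,
            "count_originals": counts["orig"],
            "count_positives": counts["pos"],
            "count_negatives": counts["neg"],
            "freq_originals_pct": f_o,
            "freq_positives_pct": f_p,
            "freq_negatives_pct": f_n,
            "ratio_positives": frequency_ratio(f_p, f_o),
            "ratio_negatives": frequency_ratio(f_n, f_o),
        }
        for label, n_g in (("positives", n_p), ("negatives", n_n)):
            k_g = counts[label[:3]]
            table = [[k_g, n_g - k_g], [counts["orig"], n_o - counts["orig"]]]
            odds, p = fisher_exact(table, alternative="two-sided")
            row[f"odds_ratio_{label}"] = odds
            row[f"p_{label}"] = p
        rows.append(row)
    df = pd.DataFrame(rows)
    df["q_positives"] = bh_adjust(df["p_positives"].to_numpy())
    df["q_negatives"] = bh_adjust(df["p_negatives"].to_numpy())
    return df


def default_thresholds(base_pred: float, train_pred_sd: float) -> tuple[float, float]:
    """Upper/lower counterfactual thresholds: base prediction +/- 1 SD of
    the model's training-set predictions."""
    return base_pred + train_pred_sd, base_pred - train_pred_sd


def counterfactual_analysis(
    predict,
    originals: list[Molecule],
    defs: list[ToxicophoreDef],
    n_samples: int = 300,
    seed: int = 0,
    upper: float | None = None,
    lower: float | None = None,
    pred_sd: float | None = None,
    mutation_cfg: MutationConfig | None = None,
) -> tuple[list[CounterfactualPair], pd.DataFrame]:
    """End-to-end pipeline: sample, score, select, tabulate enrichment.

    ``predict`` maps a list of molecules to an array of predictions.
    Thresholds are either absolute (``upper``/``lower``) or derived per
    molecule as base +/- ``pred_sd``.  Molecules whose base prediction
    falls outside the absolute threshold band are skipped (no admissible
    counterfactual direction exists on that side for them).
    """
    if (upper is None or lower is None) and pred_sd is None:
        raise ValueError("provide absolute thresholds or pred_sd")
    base_preds = np.asarray(predict(originals), dtype=float)
    pairs: list[CounterfactualPair] = []
    rng = np.random.default_rng(seed)
    for m, bp in zip(originals, base_preds):
        up, lo = (upper, lower) if pred_sd is None else default_thresholds(bp, pred_sd)
        if not up > bp > lo:
            continue
        samples = sample_subspace(
            m, n_samples=n_samples, mutation_cfg=mutation_cfg,
            seed=int(rng.integers(2**31 - 1)),
        )
        if not samples:
            continue
        mols = [parse_smiles(s.smiles) for s in samples]
        preds = np.asarray(predict(mols), dtype=float)
        scored = [
            CounterfactualSample(s.smiles, s.tanimoto_distance, float(p))
            for s, p in zip(samples, preds)
        ]
        pairs.append(select_counterfactuals(m, float(bp), scored, up, lo))
    positives = [parse_smiles(p.positive.smiles) for p in pairs if p.positive]
    negatives = [parse_smiles(p.negative.smiles) for p in pairs if p.negative]
    bases = [p.base for p in pairs]
    if not (bases and positives and negatives):
        return pairs, pd.DataFrame()
    return pairs, enrichment_table(bases, positives, negatives, defs)
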