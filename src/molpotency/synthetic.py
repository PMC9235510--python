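"""Synthetic benchmark generator with planted toxicophore-driven potency.

Emulates the three dataset roles the pipeline consumes, without external
downloads:

* a multi-experiment TD50 potency table (continuous training labels, with a
  sentinel cluster of molecules whose experiments all came back negative);
* a larger binary mutagenicity set whose labels agree with binarized
  carcinogenicity only at a configurable concordance (default 70%);
* a binary external-style test set drawn from the extremes of the latent
  potency spectrum, the way an expert-panel database over-represents clear
  positives and clear negatives.

Molecules are assembled from a scaffold library with random decorations; a
configurable fraction carries a planted toxicophore fragment whose effect
weight (log-potency units) drives the ground-truth latent potency
z = baseline + scaffold/decoration shifts + sum(w * indicator) + noise.
Per experiment, TD50 = 10^(-z) with lognormal noise, and experiments go
non-carcinogenic (no finite TD50) with probability logistic in -z.

An optional hazards mode simulates tumor-incidence counts under
lambda(t, d) = (1 + beta*d) * lambda0(t) on a dose grid and recovers TD50 as
log(2)/beta-hat by binomial maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.optimize import minimize
from scipy.special import expit

from .chem import Molecule, parse_smiles
from .labels import (
    SENTINEL_LOG_POTENCY,
    PotencyLabel,
    PotencyRecord,
    binarize_labels,
    labels_from_records,
)

# Scaffold library with fixed log-potency shifts (structured baseline:
# potency depends mildly on the core ring system, not only on planted
# fragments, so the learning problem is not a single-bit lookup).
SCAFFOLDS: list[tuple[str, float]] = [
    ("CCCCCC", 0.0),
    ("CCCCCCCC", -0.1),
    ("C1CCCCC1", -0.1),
    ("C1CCCC1", 0.0),
    ("c1ccccc1", 0.2),
    ("c1ccncc1", 0.3),
    ("c1ccsc1", 0.4),
    ("c1ccoc1", 0.3),
    ("C1CCOC1", -0.2),
    ("CCOCC", -0.3),
    ("c1ccc2ccccc2c1", 0.5),
    ("CC(C)CC", -0.1),
]

# Decoration fragments (attached by a single bond) with small shifts.
DECORATIONS: list[tuple[str, float]] = [
    ("C", 0.0),
    ("CC", 0.0),
    ("O", -0.1),
    ("OC", -0.1),
    ("N", 0.15),
    ("Cl", 0.25),
    ("F", 0.1),
    ("C(=O)O", -0.2),
    ("C#N", 0.2),
    ("S", 0.1),
]

# Plantable toxicophore fragments: (fragment SMILES, needs aromatic site).
PLANT_FRAGMENTS: dict[str, tuple[str, bool]] = {
    "nitroso": ("N=O", False),
    "aromatic_nitro": ("[N+](=O)[O-]", True),
}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark."""

    n_molecules: int = 1000
    planted_fraction: float = 0.4
    effect_weights: dict[str, float] = field(
        default_factory=lambda: {"nitroso": 2.0, "aromatic_nitro": 2.0}
    )
    baseline_mean: float = 0.0
    baseline_sd: float = 0.5          # molecule-level log-potency noise
    experiment_noise_sd: float = 0.3  # per-experiment log10 TD50 noise
    min_experiments: int = 1
    max_experiments: int = 3
    #: probability an experiment is non-carcinogenic:
    #: expit((nc_midpoint - z) / nc_scale)
    nc_midpoint: float = 1.0
    nc_scale: float = 0.5
    concordance: float = 0.70
    sentinel: float = SENTINEL_LOG_POTENCY
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0.5 < self.concordance <= 1:
            raise ValueError("concordance must be in (0.5, 1]")
        unknown = set(self.effect_weights) - set(PLANT_FRAGMENTS)
        if unknown:
            raise ValueError(f"unknown planted toxicophores: {sorted(unknown)}")


@dataclass
class SyntheticBundle:
    """Generated datasets plus the ground truth they were generated from."""

    train_molecules: list[Molecule]
    train_records: list[PotencyRecord]
    train_labels: list[PotencyLabel]
    mut_molecules: list[Molecule]
    mut_labels: np.ndarray          # binary mutagenicity
    test_molecules: list[Molecule]
    test_labels: np.ndarray         # binary carcinogenicity, extreme sampling
    truth: pd.DataFrame             # id, z, planted_*, split, carc_binary

    @property
    def train_y(self) -> np.ndarray:
        order = {l.molecule_id: l for l in self.train_labels}
        return np.array([order[m.id].y for m in self.train_molecules])


def _graft(mol: Chem.Mol, fragment: str, site_idx: int) -> Chem.Mol | None:
    """Attach ``fragment`` (atom 0) to heavy atom ``site_idx`` by a single bond."""
    frag = Chem.MolFromSmiles(fragment)
    if frag is None:
        return None
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(site_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _carbon_sites(mol: Chem.Mol, aromatic: bool | None = None) -> list[int]:
    """Carbons with at least one hydrogen to give up for a new single bond."""
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() < 1:
            continue
        if aromatic is not None and atom.GetIsAromatic() != aromatic:
            continue
        sites.append(atom.GetIdx())
    return sites


def generate_molecules(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[list[Molecule], pd.DataFrame]:
    """Assemble molecules and return them with ground-truth structure info.

    The truth frame holds, per molecule, the structural log-potency shift
    (scaffold + decorations) and one planted_<name> indicator column per
    toxicophore in the effect-weight catalogue.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    defs = sorted(cfg.effect_weights)
    molecules: list[Molecule] = []
    rows = []
    for i in range(cfg.n_molecules):
        scaffold_smiles, shift = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        mol = Chem.MolFromSmiles(scaffold_smiles)
        struct_shift = shift
        for _ in range(int(rng.integers(0, 4))):
            frag, dshift = DECORATIONS[rng.integers(len(DECORATIONS))]
            sites = _carbon_sites(mol)
            if not sites:
                continue
            grafted = _graft(mol, frag, int(sites[rng.integers(len(sites))]))
            if grafted is not None:
                mol = grafted
                struct_shift += dshift
        planted = {name: False for name in defs}
        if rng.random() < cfg.planted_fraction:
            order = list(rng.permutation(defs))
            for name in order:
                frag, needs_aromatic = PLANT_FRAGMENTS[name]
                sites = _carbon_sites(mol, aromatic=True if needs_aromatic else None)
                if not sites:
                    continue
                grafted = _graft(mol, frag, int(sites[rng.integers(len(sites))]))
                if grafted is not None:
                    mol = grafted
                    planted[name] = True
                    break
        mid = f"syn{i:06d}"
        molecules.append(parse_smiles(Chem.MolToSmiles(mol), id=mid))
        rows.append({"id": mid, "struct_shift": struct_shift,
                     **{f"planted_{k}": v for k, v in planted.items()}})
    return molecules, pd.DataFrame(rows).set_index("id")


def latent_potency(cfg: SyntheticConfig, truth: pd.DataFrame, rng) -> np.ndarray:
    """z = baseline + structural shift + planted effects + molecule noise."""
    z = cfg.baseline_mean + truth["struct_shift"].to_numpy(dtype=float)
    for name, w in cfg.effect_weights.items():
        z = z + w * truth[f"planted_{name}"].to_numpy(dtype=float)
    return z + rng.normal(0.0, cfg.baseline_sd, size=len(truth))


def simulate_potency(
    molecules: list[Molecule], cfg: SyntheticConfig, seed: int | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[list[PotencyRecord], pd.DataFrame]:
    """Per-experiment TD50 records driven by the latent potency z.

    Returns the records and the truth frame extended with a ``z`` column.
    Each experiment yields TD50 = 10^(-z) with lognormal (log10-normal)
    noise, or a non-carcinogenic outcome with probability
    expit((nc_midpoint - z) / nc_scale) — the beta = 0 case.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    if truth is None:
        truth = pd.DataFrame(
            {"struct_shift": np.zeros(len(molecules)),
             **{f"planted_{k}": False for k in cfg.effect_weights}},
            index=pd.Index([m.id for m in molecules], name="id"),
        )
    truth = truth.copy()
    truth["z"] = latent_potency(cfg, truth, rng)
    records: list[PotencyRecord] = []
    for m, z in zip(molecules, truth["z"].to_numpy()):
        n_exp = int(rng.integers(cfg.min_experiments, cfg.max_experiments + 1))
        p_nc = float(expit((cfg.nc_midpoint - z) / cfg.nc_scale))
        for e in range(n_exp):
            if rng.random() < p_nc:
                td50 = None
            else:
                td50 = 10.0 ** (-z + rng.normal(0.0, cfg.experiment_noise_sd))
            records.append(PotencyRecord(molecule_id=m.id, experiment_id=f"{m.id}_e{e}", td50=td50))
    return records, truth


def simulate_mutagenicity(
    binary_truth: np.ndarray, cfg: SyntheticConfig, seed: int | None = None
) -> np.ndarray:
    """Binary mutagenicity labels: truth flipped with probability 1 - c."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    truth = np.asarray(binary_truth, dtype=int)
    flips = rng.random(truth.shape) > cfg.concordance
    return np.where(flips, 1 - truth, truth)


def make_benchmark(
    cfg: SyntheticConfig,
    n_train: int = 1500,
    n_mut: int = 3000,
    n_test: int = 400,
    test_pool_factor: int = 3,
) -> SyntheticBundle:
    """Compose a full benchmark bundle from one molecule pool.

    Canonical-SMILES groups are assigned wholesale to the train, mutagenicity
    or external-test pools, so train and test are disjoint after dedup.  The
    external test set takes the ``n_test/2`` highest and lowest latent
    potencies from its pool (labels 1 and 0 respectively), mimicking an
    expert-curated set drawn from either end of the potency spectrum.
    """
    n_pool = n_train + n_mut + test_pool_factor * n_test
    pool_cfg = SyntheticConfig(**{**cfg.__dict__, "n_molecules": n_pool})
    molecules, truth = generate_molecules(pool_cfg)
    records_all, truth = simulate_potency(molecules, pool_cfg, truth=truth)

    by_id = {m.id: m for m in molecules}
    rec_by_id: dict[str, list[PotencyRecord]] = {}
    for r in records_all:
        rec_by_id.setdefault(r.molecule_id, []).append(r)
    labels_all = {l.molecule_id: l for l in labels_from_records(records_all, sentinel=cfg.sentinel)}
    truth["carc_binary"] = [
        0 if labels_all[m.id].is_sentinel else 1 for m in molecules
    ]

    rng = np.random.default_rng(pool_cfg.seed + 3)
    groups: dict[str, list[str]] = {}
    for m in molecules:
        groups.setdefault(m.canonical_smiles, []).append(m.id)
    group_keys = sorted(groups)
    rng.shuffle(group_keys)

    split_of: dict[str, str] = {}
    counts = {"train": 0, "mut": 0, "test_pool": 0}
    quota = {"train": n_train, "mut": n_mut, "test_pool": test_pool_factor * n_test}
    order = ["train", "mut", "test_pool"]
    for key in group_keys:
        ids = groups[key]
        target = next((s for s in order if counts[s] < quota[s]), "test_pool")
        for mid in ids:
            split_of[mid] = target
        counts[target] += len(ids)
    truth["split"] = [split_of[m.id] for m in molecules]

    train_ids = [m.id for m in molecules if split_of[m.id] == "train"]
    mut_ids = [m.id for m in molecules if split_of[m.id] == "mut"]
    pool_ids = [m.id for m in molecules if split_of[m.id] == "test_pool"]

    train_molecules = [by_id[i] for i in train_ids]
    train_records = [r for i in train_ids for r in rec_by_id[i]]
    train_labels = [labels_all[i] for i in train_ids]

    mut_molecules = [by_id[i] for i in mut_ids]
    mut_truth = np.array([truth.loc[i, "carc_binary"] for i in mut_ids])
    mut_labels = simulate_mutagenicity(mut_truth, pool_cfg)

    pool_z = np.array([truth.loc[i, "z"] for i in pool_ids])
    order_z = np.argsort(pool_z)
    half = n_test // 2
    lo = [pool_ids[i] for i in order_z[:half]]
    hi = [pool_ids[i] for i in order_z[-half:]]
    test_molecules = [by_id[i] for i in lo + hi]
    test_labels = np.array([0] * len(lo) + [1] * len(hi))

    return SyntheticBundle(
        train_molecules=train_molecules,
        train_records=train_records,
        train_labels=train_labels,
        mut_molecules=mut_molecules,
        mut_labels=mut_labels,
        test_molecules=test_molecules,
        test_labels=test_labels,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as the CSV dialects the pipeline reads."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"id": [m.id for m in bundle.train_molecules],
         "smiles": [m.smiles for m in bundle.train_molecules]}
    ).to_csv(outdir / "train_molecules.csv", index=False)
    pd.DataFrame(
        {"molecule_id": [r.molecule_id for r in bundle.train_records],
         "experiment_id": [r.experiment_id for r in bundle.train_records],
         "td50": [r.td50 for r in bundle.train_records]}
    ).to_csv(outdir / "train_potency.csv", index=False)
    pd.DataFrame(
        {"id": [m.id for m in bundle.mut_molecules],
         "smiles": [m.smiles for m in bundle.mut_molecules],
         "mutagenic": bundle.mut_labels}
    ).to_csv(outdir / "mutagenicity.csv", index=False)
    pd.DataFrame(
        {"id": [m.id for m in bundle.test_molecules],
         "smiles": [m.smiles for m in bundle.test_molecules],
         "carcinogenic": bundle.test_labels}
    ).to_csv(outdir / "external_test.csv", index=False)
    bundle.truth.to_csv(outdir / "ground_truth.csv")


# -- optional hazards-based TD50 simulator -----------------------------------


def simulate_tumor_assay(
    beta: float,
    doses: np.ndarray,
    n_animals: int,
    baseline_cum_hazard: float = 0.105,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial tumor counts under the proportional-hazards dose model.

    P(tumor by end of study at dose d) = 1 - exp(-Lambda0 * (1 + beta*d)),
    where Lambda0 is the baseline cumulative hazard over the study window.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    p = 1.0 - np.exp(-baseline_cum_hazard * (1.0 + beta * doses))
    tumors = rng.binomial(n_animals, p)
    return pd.DataFrame({"dose": doses, "n_animals": n_animals, "n_tumors": tumors})


def estimate_beta(assay: pd.DataFrame) -> tuple[float, float]:
    """Joint MLE of (Lambda0, beta) from dose-group tumor counts."""
    d = assay["dose"].to_numpy(dtype=float)
    n = assay["n_animals"].to_numpy(dtype=float)
    k = assay["n_tumors"].to_numpy(dtype=float)

    def nll(log_params):
        lam0, beta = np.exp(log_params)
        p = 1.0 - np.exp(-lam0 * (1.0 + beta * d))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    res = minimize(nll, x0=np.log([0.1, 0.01]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
    lam0, beta = np.exp(res.x)
    return float(lam0), float(beta)


def recover_td50_hazards(
    beta_true: float,
    doses=(0.0, 5.0, 10.0, 25.0, 50.0),
    n_animals: int = 500,
    seed: int = 0,
) -> float:
    """Simulate an assay at a known beta and recover TD50 = log(2)/beta-hat."""
    assay = simulate_tumor_assay(beta_true, np.asarray(doses), n_animals, seed=seed)
    _, beta_hat = estimate_beta(assay)
    return math.log(2) / beta_hat
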