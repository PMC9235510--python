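# molpotency

Continuous carcinogenic-potency prediction from molecular structure.

Carcinogenicity data is scarce and expensive: each label comes from a
long-term animal bioassay, and most datasets reduce the result to a binary
call, discarding how potent the compound actually is. `molpotency` instead
models the continuous potency scale. Bioassay collections summarize potency
as **TD50** — the dose-rate (mg/kg body weight/day) estimated to halve the
probability of remaining tumor-free, computed as `TD50 = log(2) / β̂` under
the proportional-hazards dose model `λ(t, d) = (1 + βd)·λ₀(t)`. Per-molecule
experiments are aggregated with a **harmonic mean** (biasing toward the
experiments that did demonstrate carcinogenicity) and trained on the
log-reciprocal scale `y = log₁₀(1/TD50)`; molecules whose experiments all
came back negative receive a sentinel target of −1.62 log units.

The predictor is a five-layer MLP (dropout 0.1, batch normalization, ReLU)
over a concatenation of:

* 2048-bit circular (Morgan), 2048-bit path (RDKit) and 167-bit
  structural-key (MACCS) fingerprints, and
* a fixed-length embedding from a graph encoder — L rounds of message
  passing `hᵢ⁽ˡ⁾ = σ(W⁽ˡ⁾ mᵢ⁽ˡ⁾ + b⁽ˡ⁾)` followed by multi-head
  scaled-dot-product attention over all atoms and mean pooling — or,
  interchangeably, a table of precomputed per-molecule embeddings.

Two output heads share the trunk: continuous carcinogenicity regression and
binary mutagenicity classification. **Multi-round pre-training** alternates
early-stopped training phases between the abundant-but-noisy mutagenicity
objective and the scarce carcinogenicity objective for three cycles, which
measurably improves held-out potency correlation over single-phase training.

The package also implements the two companion analyses:

* **Dataset distances** — Tanimoto similarity
  `T(x, y) = ⟨x,y⟩ / (‖x‖² + ‖y‖² − ⟨x,y⟩)`, within-set diversity, and the
  unbiased Tanimoto-kernel maximum mean discrepancy (MMD) between labeled
  dataset partitions.
* **Counterfactual interpretability** — local chemical-subspace sampling by
  random molecular-graph edits, threshold-crossing counterfactual selection,
  and toxicophore (SMARTS structural-alert) enrichment statistics with
  Fisher exact tests and Benjamini–Hochberg correction.

A synthetic-data module generates the full study setup — multi-experiment
TD50 records, a 70%-concordant binary mutagenicity set, and an
extreme-sampled binary external test set — with potency driven by planted
toxicophore substructures, so the entire pipeline is testable without
external databases.

## Worked example

```python
import numpy as np
from molpotency.benchmark import (
    featurize_bundle, reference_bundle, reference_train_config, REFERENCE_HIDDEN,
)
from molpotency.metrics import pearson, roc_auc
from molpotency.model import PredictorModel
from molpotency.training import LabeledSet, multi_round_pretrain

bundle = reference_bundle(seed=1)          # 1500 train / 3000 mut / 400 test
feats = featurize_bundle(bundle, encoder_seed=1)

model = PredictorModel(input_dim=feats.X_carc_full.shape[1],
                       hidden=REFERENCE_HIDDEN, seed=0)
carc = LabeledSet([m.id for m in bundle.train_molecules],
                  feats.X_carc_full, bundle.train_y)
mut = LabeledSet([m.id for m in bundle.mut_molecules],
                 feats.X_mut_full, bundle.mut_labels.astype(float))
multi_round_pretrain(model, mut, carc, reference_train_config())

scores = model.forward(feats.X_test_full, head="carc", mode="eval")
print(f"external-test ROC AUC: {roc_auc(scores, bundle.test_labels):.3f}")
```

```
external-test ROC AUC: 0.998
```

The model was trained on continuous log-reciprocal TD50 targets only; the
external test set is binary, so the raw continuous predictions are used as
ranking scores. The high AUC reflects the synthetic benchmark's design:
the external set is drawn from the extremes of the latent potency spectrum,
the way expert-curated databases over-represent clear positives and clear
negatives.

On the same benchmark, the 20-seed ablation orders the variants
(mean held-out Pearson): multi-round pre-training 0.77 > single pre-train
0.75 > fingerprint+encoder 0.72 ≳ fingerprint-only 0.72.

## Command line

```bash
molpotency simulate --seed 7 --outdir bundle/
molpotency featurize --input bundle/train_molecules.csv --out fp.npz
molpotency labels --potency bundle/train_potency.csv --out labels.csv
molpotency train --mols bundle/train_molecules.csv --carc bundle/train_potency.csv \
    --mut bundle/mutagenicity.csv --rounds 3 --out model.npz
molpotency evaluate --model model.npz --test bundle/external_test.csv \
    --labels binary --report report.json
molpotency distance --a setA.csv --b setB.csv --out mmd.json
molpotency counterfactual --model model.npz --mols test.csv --out enrichment.csv
```

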