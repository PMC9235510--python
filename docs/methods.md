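# Methods

## The prediction problem

Carcinogenic potency is modeled as a graph-level regression task. The label
source is the TD50 summary of long-term animal bioassays: under the
proportional-hazards dose model

    λ(t, d) = (1 + β·d) · λ₀(t)

where λ₀(t) is the baseline tumor incidence and d the administered dose-rate,
the potency estimate is TD50 = log(2)/β̂ in mg/kg body weight/day (β = 0
means no dose-tumor relationship, i.e. no finite TD50). A molecule typically
has several experiments; the per-molecule aggregate is the **harmonic mean**
of the finite TD50s — deliberately biased toward the low (potent)
observations, since a single positive experiment is evidence the compound is
carcinogenic under some conditions. Non-carcinogenic experiments are excluded
from both the numerator and the count of the harmonic mean.

The training target is y = log₁₀(1/TD50): dimensionless log units,
increasing with potency, strictly decreasing in TD50. Molecules whose
experiments all came back negative get a **sentinel** y = −1.62 (the value
at which the negative cluster sits in the continuous label distribution;
configurable). Sentinel-labeled molecules are kept in regression training —
the model must learn to push inactive compounds toward that floor — and the
sentinel flag also defines the binary view of the data (positive ⇔ not
sentinel), used for mutagenicity concordance and binary external evaluation.

Base-10 logarithms are used throughout label engineering; the base is a
config parameter and changes y only by a multiplicative constant.

## Model

**Features.** Each molecule contributes a 4263-bit fingerprint block —
2048-bit circular (Morgan, radius 2, ECFP4-equivalent), 2048-bit path
(RDKit topological, path lengths 1–7) and 167-bit structural-key (MACCS;
the published 166 keys plus a padding bit, kept at its native width rather
than hashed up to 2048) — concatenated with a graph embedding. Feature-block
layout offsets are explicit and partition the vector exactly.

**Graph encoder.** Atom features (atomic number, mass, formal charge,
degree, aromatic flag, ring flag) are linearly mapped to a hidden state
h⁽⁰⁾. L rounds of message passing follow:

    mᵢ⁽ˡ⁾ = Σ_{j∈N(i)} ( W_msg⁽ˡ⁾ h_j + W_edge⁽ˡ⁾ e_ij ),
    hᵢ⁽ˡ⁾ = σ( W⁽ˡ⁾ mᵢ⁽ˡ⁾ + b⁽ˡ⁾ )

with sum aggregation over one-hop neighbors and an edge-conditioned linear
message (bond order, aromatic flag, ring flag); a node without neighbors
reduces to the closed form σ(b). After round L, one multi-head
scaled-dot-product attention block runs over **all** nodes — attention
deliberately ignores bond topology, extending the receptive field beyond
L hops — followed by mean pooling into a d-dimensional embedding. Defaults:
L = 3, hidden = d = 128, 4 heads, ReLU. The attention logits divide by √d;
an `attn_scale="d"` option divides by d instead (both are exposed because
the two conventions appear in the literature; √d is the standard one).
The encoder is used frozen, as a structural-embedding provider; a CSV table
of precomputed per-molecule embeddings can substitute for it through the
same provider interface, which is also the plug-in slot for embeddings from
large pre-trained graph models.

**Predictor.** A five-layer MLP trunk (dense → batch-norm → ReLU → dropout
0.1 at every layer; default widths 1024/512/256/128/64) with two
single-unit heads: carcinogenicity (linear, log-potency scale, MSE loss)
and mutagenicity (logistic link, binary cross-entropy). The heads share the
entire trunk — that shared trunk is what multi-round pre-training exploits.
Separate output layers per task keep the task-specific calibration apart.
Eval mode is deterministic (dropout off, batch-norm running statistics), so
predictions are independent of batch composition; this is asserted in tests
to 1e-6.

The whole stack is NumPy: dense, batch-norm and inverted-dropout layers
with hand-written reverse-mode gradients, float32 arithmetic, and Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999). Every random draw (init, dropout, minibatch
order) flows through explicit seeded generators, making full training runs
bit-reproducible.

## Training procedure

**Leakage-free splitting.** Folds are assigned to canonical-SMILES groups,
not rows: duplicate spellings of one structure always land in the same
fold. Group counts per fold differ by at most one (round-robin after a
seeded shuffle).

**Phase training.** Minibatch Adam with early stopping: training stops once
validation loss has not improved for `patience` epochs and the
best-validation checkpoint (weights and batch-norm statistics) is restored.

**Multi-round pre-training.** R cycles of (mutagenicity phase →
carcinogenicity phase), R = 3 by default, always ending on carcinogenicity;
R = 0 degenerates to plain carcinogenicity training. Model weights carry
across phase boundaries; optimizer state is reset at each boundary — the
cycling is the point, not a continuous optimization trajectory. The working
hypothesis: alternation keeps trunk features that serve both tasks while
each switch overwrites task-specific noise.

**Model selection.** A finite hyperparameter grid is evaluated by threefold
deduplicated cross-validation, ranked by mean validation Pearson on the
carcinogenicity objective; the top three configs are retrained and averaged
into an ensemble (arithmetic mean of member predictions, which can never
have a worse MSE than the worst member, by convexity).

## Statistics

Pearson and MSE for the continuous task; ROC AUC and PR AUC (step-wise,
non-interpolated, to avoid the optimistic bias of linear interpolation) for
binary evaluation, with raw continuous predictions as ranking scores —
no threshold is ever chosen. Uncertainty is the SD of the metric over
B = 1000 paired bootstrap resamples; resamples on which a metric is
undefined (e.g. single-class AUC) are redrawn. Paired ROC AUC comparisons
use the one-sided DeLong test with the structural-components variance
estimator; identical score vectors return p = 0.5, and a nonzero AUC
difference with exactly zero component variance (perfect vs anti-perfect
separation) returns the infinite-z limit rather than erroring. Cross-seed
ablation comparisons use a two-sided two-sample t-test. Null calibration of
both tests is verified by simulation in the test suite.

Dataset distances use the Tanimoto coefficient
T(x, y) = ⟨x,y⟩/(‖x‖² + ‖y‖² − ⟨x,y⟩) on binary circular fingerprints
(equivalent to |x∩y|/|x∪y|), within-set diversity = mean pairwise (1 − T),
and the unbiased empirical MMD with Tanimoto kernel: off-diagonal
within-set means (divisors n(n−1), m(m−1)) minus twice the cross mean
(divisor nm). The estimator may be slightly negative for close
distributions and is reported unclamped; the self-distance diagonal of a
partition matrix is likewise not forced to zero.

## Counterfactual analysis

The local chemical subspace of a molecule is sampled by 1–3 random edits to
its molecular graph — atom-element substitution, single-bond fragment
attachment (from a small alphabet of common functional groups, including
nitroso and nitro), terminal-atom deletion, and single↔double bond toggling
— with RDKit sanitization as the validity filter and canonical-SMILES
deduplication. This is a graph-edit sampler: validity is enforced by the
sanitizer rather than by a string grammar, and invalid proposals are simply
discarded (sample lists may come back short).

A positive counterfactual is the minimal-Tanimoto-distance sample whose
prediction crosses an upper threshold; negative likewise for a lower
threshold; either may be absent. Default thresholds are base prediction
± 1 SD of the model's training-set predictions; absolute thresholds are
supported. Enrichment is tabulated per toxicophore (a catalogue of seven
classic SMARTS structural alerts ships with the package — nitroso,
aliphatic halide, aromatic nitro, aromatic amine, three-membered
heterocycle, azo, heteroatom-bonded heteroatom; a molecule matches a
definition if any of its patterns hits): match frequencies (%) per group,
the frequency ratio of each counterfactual group versus the originals
(undefined when the original frequency is zero), the cross-product odds
ratio alongside it, two-sided Fisher exact p-values on the 2×2
matched/unmatched × group/originals table, and Benjamini–Hochberg q-values
across definitions within each group. The frequency ratio — not the
cross-product odds ratio — is the quantity conventionally printed next to
the percentages, so both are emitted and labeled.

## Synthetic benchmark

The generator emulates the three dataset roles at desk scale:

* **Structures**: a 12-scaffold library (alkanes, cycloalkanes, benzene,
  simple heterocycles, naphthalene) with 0–3 random single-bond decorations
  from a 10-fragment alphabet; each scaffold and decoration carries a small
  fixed log-potency shift so that potency is not a single-bit lookup.
  A fraction f of molecules (default 0.4) additionally receives a planted
  toxicophore fragment — nitroso at any C–H site, aromatic nitro at an
  aromatic C–H site — grafted by a single bond, which guarantees validity
  without a general chemistry engine.
* **Potency**: latent z = baseline + structural shifts + Σ w·indicator +
  N(0, σ_mol), with effect weight w = 2 log units per planted def and
  σ_mol = 0.5 by default. Each of 1–3 experiments yields
  TD50 = 10^(−z) with log10-normal noise (σ_exp = 0.3), or a
  non-carcinogenic outcome with probability expit((1 − z)/0.5) — the β = 0
  case, which populates the sentinel cluster and makes binary ground truth
  (≥ 1 positive experiment) stochastic near the decision region.
* **Mutagenicity**: binarized carcinogenicity ground truth flipped
  independently with probability 1 − c, c = 0.70 — matching the limited
  concordance between bacterial mutagenicity assays and animal
  carcinogenicity data.
* **External test**: from a held-out pool (canonically disjoint from
  training after dedup), the highest and lowest latent potencies are taken
  as positives and negatives — mimicking expert-curated databases that
  over-represent the ends of the potency spectrum. This reproduces, at the
  synthetic level, the observation that the external set's inter-class MMD
  exceeds the training set's.
* **Hazards mode** (optional): binomial tumor counts at a dose grid under
  λ(t,d) = (1+βd)λ₀(t) with baseline cumulative hazard 0.105 (≈10% baseline
  incidence), joint MLE of (Λ₀, β) by Nelder–Mead, and TD50 = log(2)/β̂ —
  used to verify the label pipeline recovers a known β within 10%.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, stereochemistry, tautomerism, activity cliffs, or
assay-protocol heterogeneity. Passing results on this benchmark demonstrate
that the pipeline's machinery is correct and that the training procedure
extracts planted structure-potency signal; they say nothing about
predictive accuracy on real bioassay data.

## Reference study conditions

The ablation experiment fixed in `molpotency.benchmark`: 1500 training
molecules with multi-experiment TD50s, 3000 mutagenicity molecules at 70%
concordance, 400 external-test molecules, planted effect weight 2. The
scaled-down model for this benchmark uses a frozen 32-dimensional encoder
and trunk widths 128/64/32/32/16 with batch 128, patience 3, ≤30 epochs
per phase — sizes chosen so a 20-seed, four-variant ablation is a
minutes-scale single-CPU computation. Seeds vary weight initialization,
dropout and minibatch order; the dedup split is held fixed across seeds so
variant comparisons are paired. The reported result is the ordering of
mean held-out Pearson: multi-round (3 cycles) > single pre-train >
fingerprint-only.

## Known limitations

* The graph encoder is used frozen (supervised fine-tuning of the encoder
  itself is out of scope); its embedding contributes structural signal but
  is not task-adapted unless external embeddings are supplied.
* Canonical SMILES strings are toolkit-version-defined; deduplication is
  consistent within a run, not across toolkits.
* The graph-edit counterfactual sampler proposes chemistry from a fixed
  edit alphabet; regions of chemical space requiring ring construction or
  rearrangement are under-sampled.
* DeLong p-values use the classical estimator, not a paired bootstrap.
* The MLP widths, learning rate, batch size and patience defaults are
  reasonable-practice choices, not the result of an exhaustive sweep; the
  sweep machinery exists for users who need one.
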