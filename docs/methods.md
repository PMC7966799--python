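# Methods

This note documents the models and procedures implemented in `rxnlens`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real reaction data.

## The prediction model being interpreted

All interpretation methods in the package are defined against a predictor
contract: a sequence-to-sequence model over SMILES tokens that exposes

* `embed(tokens)` — the N x d source token-embedding matrix,
* `encoder_states` — final encoder states, one row per source token,
* `sequence_probability(source, target)` — the teacher-forced product of
  per-token conditional probabilities of the target sequence, including
  the end-of-sequence symbol, as a differentiable function of the source
  embeddings, and
* `gradient` — d(sequence probability) / d(source embeddings).

The reference implementation is a compact pre-layer-norm encoder–decoder
transformer written directly over NumPy with a small reverse-mode
autodiff core (`rxnlens.autodiff`); every primitive is verified against
central finite differences in the test suite, and the model-level
gradient is checked to 1e-4 relative error.  Sinusoidal positional
encodings are added inside the forward pass, *after* the embedding
matrix that attributions are taken with respect to, so the attribution
baseline passes through exactly the same code path as a real input.  The
output projection is zero-initialized, which makes the untrained model's
conditional distribution exactly uniform over the vocabulary — a useful
calibration point (`(1/V)^(T+1)` sequence probabilities) and a harmless
initialization for training.

The sequence probability is the plain product of conditionals, not
length-normalized: the quantity attributed is a probability in [0, 1].

Default width is d = 256 (matching the latent width the retrieval module
stores); the desk-scale presets used in tests and examples shrink the
model (d = 48–64, 1 layer, 2 heads) so that training on the synthetic
corpora takes minutes on one CPU.  Training uses Adam with a per-epoch
multiplicative learning-rate decay, teacher forcing, batch padding with
additive attention masks, and is fully deterministic given the config
seed (initialization, shuffling, and updates all flow from it).

Training corpora can be doubled with random-equivalent SMILES spellings
(`augment_records`), the standard augmentation protocol for SMILES
seq2seq models.  The bias experiment uses it by default: on the
synthetic task it substantially improves decoding validity and
generalization from the length-2–8 training chains to the length-9–10
test chains.

## Input attribution (integrated gradients)

For a selective reaction with two plausible products, the quantity
explained is the probability difference dF(x) = F_major(x) - F_minor(x),
where x is the N x d source embedding matrix.  Attributions are

IG_i(x) = (x_i - x'_i) · ∫₀¹ ∂dF(x' + α(x - x'))/∂x_i dα,

summed over the d embedding coordinates to give one value per token.
Both candidate products are canonicalized before scoring so neither is
penalized by a non-canonical spelling.

Choices:

* **Baseline** x′ is the embedding of the `.` separator token repeated N
  times.  `.` separates molecules and carries no chemical information.
* **Quadrature**: midpoint Riemann rule, default 50 steps.  Midpoint is
  exact for linear objectives (asserted to 1e-9 in tests) and the
  completeness gap |Σᵢ IG_i − (dF(x) − dF(x'))| is recorded on every
  result; on the trained desk-scale model it falls below 1% of the span
  at 500 steps.
* **Grouping**: token attributions are aggregated to substructures —
  each reagent molecule is one unit (with the `.` preceding it), each
  ring system within the reactants is one unit (fused rings merged;
  ring-closure digits assigned to their ring), each outermost
  parenthesized branch hanging off a non-ring atom is one unit
  (parentheses included, nested branches absorbed), and every remaining
  token is a singleton.  The groups partition the token set, so
  aggregation conserves the total attribution exactly.
* **Importance cutoff**: a group is flagged important when the magnitude
  of its attribution strictly exceeds its uniform share — the
  probability-difference span divided evenly over tokens times the group
  size.  The raw ratio is exposed so stricter cutoffs can be applied.
* **Signs**: positive attributions favour the major product, negative
  the minor one.

No smoothing is applied to attributions on parts of the input that do
not drive selectivity; they can be noisy when the model is uncertain.

## Training-data attribution (latent retrieval)

Each reaction input is encoded by mean-pooling the final encoder states
over all source tokens (reagents and separators included — the pooling
has no exclusions).  Similarity between a query u and a stored training
reaction v is

score(u, v) = 1 / (1 + ‖u − v‖),

a monotone map of Euclidean distance onto (0, 1] with score 1 iff the
vectors coincide.  Retrieval is exact brute force over the index —
desk-scale indexes are thousands of rows, and exactness makes the
behaviour fully checkable against exhaustive scoring.  The index
persists as a row-major float32 binary with a JSON sidecar carrying ids
and a fingerprint of the producing model; queries with a mismatched
fingerprint are rejected rather than silently compared across models.

## Tanimoto transfer splitting

Products are featurized as Morgan fingerprints of radius 3 hashed to
1024 bits.  A transfer split first performs a seeded random split at an
initial test fraction, then moves every test reaction whose (first
listed) product has Tanimoto similarity ≥ σ to any training product
into the training set.  Because transfers only grow the training side, a
single pass against the initial training set suffices.  The initial
fraction is then adjusted by bisection (tolerance 0.5 percentage points,
at most 20 iterations, same seed per iteration so the procedure is a
deterministic function of the fraction) until the achieved test fraction
matches the target; if the target is unreachable the best split is
returned flagged `converged=False`.  Every returned split satisfies the
postcondition max cross-set product Tanimoto < σ.

"Within similarity σ" is interpreted as *similarity ≥ σ triggers
exclusion*, so the kept test set satisfies a strict < σ bound.
Multi-product reactions are featurized by their first listed product.

For diagnosing whether similar products also undergo similar
*transformations*, reaction difference fingerprints are provided: the
signed count-fingerprint difference (products minus reactants, reagents
excluded), compared with the continuous Tanimoto
⟨a,b⟩ / (‖a‖² + ‖b‖² − ⟨a,b⟩).  The min/max form of the count Tanimoto
is not well defined for mixed-sign vectors (the denominator can vanish
for unequal inputs), while the continuous form reduces to the bit
Tanimoto on 0/1 vectors and scores identical difference vectors 1.

## The synthetic regioselectivity benchmark

The generator emulates Friedel–Crafts acylation of singly substituted
benzenes: ten para-directing and ten meta-directing benzene derivatives
(stored as canonical SMILES constants) react with acyl chlorides to give
the para- or meta-acylated product via implementer-written reaction
SMARTS templates.  Acyl chlorides are built from straight carbon chains
of length 2–8 with 0–1 C=C double bonds (23 distinct molecules after
canonical deduplication) by attaching C(=O)Cl to an sp3 carbon — either
one seeded-random position per chain (`random`, 22 acyl chlorides) or
every symmetry-distinct position (`exhaustive`, 75 acyl chlorides, the
default for dataset building).  Chains with no sp3 carbon (ethylene) are
skipped.

Training corpora realize their para:meta ratio *exactly* by splitting
the acyl pool into integer-weighted subsets; surplus acyl chlorides that
would break exactness are dropped by seeded choice:

| corpus   | ratio  | construction                         | size (exhaustive) |
|----------|--------|--------------------------------------|-------------------|
| balanced | 1:1    | all 75 acyls × all 20 benzyls        | 750 : 750         |
| biased   | 9:1    | 63 : 7 acyl split × 10 benzyls each  | 630 : 70          |
| severe   | 100:1  | 60 acyls × 10 para benzyls vs 2 × 3 meta benzyls | 600 : 6 |

The fixed test set uses three named para and three named meta benzyls
with saturated chains of length 9–10 (10 acyl chlorides), giving 30 para
and 30 meta reactions; its acyl chlorides are disjoint from every
training acyl chloride by chain length.  Every generated product is
re-classified by an independent substructure-query route
(`classify_orientation`, which builds ortho/meta/para query molecules
from the benzyl and matches the decoded product against them), and
corpus construction fails loudly on any disagreement with the requested
orientation.

`classify_orientation` is total on arbitrary decoded strings: unparseable
SMILES → `invalid`, parseable without the expected substitution pattern
→ `other`.

## The bias-recovery experiment

For each corpus an ensemble of reference models (distinct seeds, same
data) is trained, and every few epochs each member greedy-decodes the
balanced test set; decodes are classified para / meta / other / invalid
against each reaction's own benzyl.  Fractions use the full test set as
denominator, so the four categories sum to 1 per member and checkpoint
while the para and meta curves alone need not.  Decodes that hit the
length cap count as invalid.

Desk-scale conditions (chosen once; all seeded): ensembles of 4 members,
d = 48, 1 layer, 2 heads, batch 128, Adam at 2.5e-3 with 0.99 per-epoch
decay, float32 arithmetic, augmentation on, 45/70/40 epochs for
balanced/biased/severe (epoch counts scale roughly inversely with corpus
size so members see comparable optimizer-step budgets).  Under these
conditions the balanced ensemble converges to near-equal para and meta
fractions, the severely biased ensemble produces essentially no meta
predictions, and the meta fraction orders balanced > biased > severe.

## What the synthetic benchmark does and does not show

The generator produces a *closed* world: one reaction family, two
outcomes, noiseless labels, systematic enumeration, and a test set whose
only extrapolation axis is chain length.  Passing the bias-recovery and
split checks on it demonstrates that the machinery — training, decoding,
classification, fingerprinting, transfer splitting, attribution — is
correct and that the predictor inherits dataset imbalance rather than
chemistry, but it does not certify behaviour on real patent-mined
corpora, which add label noise, reagent/condition variation, many
reaction families and much longer inputs.  The splitting and retrieval
code paths accept such corpora unchanged (brute-force similarity search
scales to hundreds of thousands of products in hours, outside the test
budget).

## Numerical choices and degenerate inputs

* float64 is the default model dtype; float32 is used by the training
  presets for speed.  Attribution always accumulates path gradients in
  float64 regardless of model dtype.
* Attention masking uses additive −1e9 terms; padded key positions are
  masked in both encoder and decoder, and loss is averaged over non-pad
  label positions only.
* Ties in retrieval break by corpus order (stable sort on score).
* `tanimoto` of two all-zero bit vectors is defined as 0; the same
  convention applies to the continuous count Tanimoto.
* Empty products, empty reactants, unmatched parentheses, dangling ring
  closures, out-of-vocabulary tokens and mismatched latent dimensions
  all raise typed errors rather than propagating silently.

## Known limitations

* The reference model is desk-scale; its probability scores are
  calibration-free and should be compared only within a model.
* The printed corpus sizes above are those produced by the package's own
  enumeration; `random` placement gives smaller pools (one acyl chloride
  per chain).
* Greedy decoding only; proportions are top-1 statistics.
* No atom-mapping and no stereochemistry handling beyond what the
  chemistry toolkit applies by default; the difference-fingerprint
  diagnostic ignores reagents by construction.
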