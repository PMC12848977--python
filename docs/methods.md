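# Methods

## Overview

`smolgen` is a desk-scale re-implementation of a two-stage pipeline for
de novo small-molecule design: (1) a decoder-only transformer language model
over SELFIES tokens, pretrained on a drug-like corpus with next-token
cross-entropy; (2) PPO fine-tuning of that model against docking-score
rewards squashed into [0, 1] by a logistic, including two-pocket (dual
target) and scaffold-constrained variants; plus a nine-criterion evaluation
suite and a molecule/scaffold novelty analysis. Everything runs on one CPU
in minutes against a deterministic surrogate docking adapter; real engines
plug in through the same adapter contract.

## The SELFIES codec

SELFIES is a bracketed molecular string grammar whose defining property is
*totality*: every token sequence derives a chemically valid molecule,
because bond orders are capped by remaining valences, branch/ring operands
are read from index tokens, and derivation simply halts at saturation. The
codec here implements that grammar natively over the neutral organic subset
C/N/O/S/P/F/Cl/Br/I (default valences 4/3/2/2/3/1/1/1/1), with:

- bracket-level tokenization (one token per `[...]` symbol);
- `[BranchK]`/`[RingK]` symbols whose operands are base-16 index tokens
  (K = operand width), ring targets counted back in atom-creation order;
- encoding by depth-first traversal of the RDKit-kekulized graph from the
  first atom of the canonical ordering, so a canonical SMILES always maps to
  one token sequence;
- decoding by replaying the derivation into an RDKit `RWMol` followed by
  sanitization.

Out of scope by design: formal charges, isotopes, radicals, multi-fragment
species and stereochemistry (stereo descriptors are stripped on encoding).
These classes are documented in the vocabulary's category map but the
synthetic corpus never produces them. Round trips
(`SMILES -> tokens -> SMILES`) are exact on the supported subset, with the
toolkit's RDKit-canonical SMILES as the identity key everywhere.

Decoding robustness rules (all preserve validity): a saturated attachment
ends the current derivation; truncated branch/ring operands discard the
symbol; duplicate or self-referential ring bonds are skipped; unknown
tokens are ignored.

## Synthetic corpus

The corpus generator emulates a filtered screening-library subset
(molecular weight 250–500 Da, LogP 1–4.5, at most 82 tokens including the
`[SOS]`/`[EOS]` controls — a Lipinski-style window). It samples 8–60
chemical tokens per draw from a fixed weighted alphabet (carbon-rich, with
N/O at frequencies that keep LogP inside the window and branch/ring symbols
at roughly drug-like framework rates), decodes, computes descriptors with
RDKit, and rejection-filters. Acceptance is ~8%, so 1,000 molecules cost a
few seconds. The attempt budget (default `1000 + 200 n`) aborts with the
dominant rejection dimension named when a window is unsatisfiable.

What this emulates: the length, weight and lipophilicity window of the real
library, and a non-trivial covariance between size, rings and heteroatom
content. What it does not: realistic functional-group statistics,
aromatic-ring prevalence (kekulized random rings are rarely aromatic),
synthesizability, or the multimillion-molecule diversity of a real
database. Tests passing on this corpus therefore demonstrate the *machinery*
(tokenization, training, RL, metrics), not chemical conclusions about real
libraries.

## Model

GPT-2-style pre-norm decoder blocks: learned absolute positional embeddings
over 82 positions, per-block LayerNorm -> multi-head causal self-attention
-> residual, LayerNorm -> 4x GELU feed-forward -> residual, final LayerNorm
and a linear head. The logit space is padded to 512 slots; slots beyond the
realized vocabulary and the `[PAD]` class are hard-masked to -inf, so they
carry exactly zero probability. Presets: M (24 blocks, width 1024, 16
heads), L (36/1280/20), XL (48/1600/25) and `tiny` (2/64/4) for desk-scale
runs. Core parameter accounting counts the attention and feed-forward
projection matrices, 12·d² per block; under this convention M is
301,989,888 (302M at million rounding) and L is ~708M against a printed
702M (≈0.8% discrepancy, presumably a different counting convention), which
is why the L preset is asserted to 1% rather than exactly.

Two attention masks: look-ahead (causal) and padding (pad positions are
invisible as keys, given the true lengths), so pad-region content cannot
influence chemical positions. Input embedding and output head are *not*
tied, keeping padded-slot masking independent of the embedding table.

Sampling is multinomial at a configurable temperature with three
control-token rules: `[PAD]` and `[SOS]` are never admissible; the first
generated token must be an atom token; `[EOS]` is admissible only once an
atom token has been emitted. The first/EOS rules guarantee a non-empty
derivation, which with grammar totality yields 100% validity for any
weights, random or trained. Decoding stops at the first `[EOS]`; later
tokens are discarded. Sampling uses an incremental key/value-cached forward
pass (plain NumPy) that matches the training-path forward to float32
round-off.

The network, its gradients and both training loops run on a small in-package
reverse-mode autodiff over NumPy arrays (`smolgen.autograd`) with
numerically verified primitives (matmul, broadcasted arithmetic, softmax /
log-softmax with additive masks, LayerNorm, GELU, gather, clip) and an Adam
optimizer with global-norm gradient clipping at 1.0.

## Pretraining

Each iteration samples molecules with replacement — no epoch boundaries —
until a fixed token budget is gathered (desk default 8,192 tokens; the
paper-scale configuration is 519,168 tokens and up to 10,000 iterations),
then minimizes mean next-token cross-entropy in nats over non-`[PAD]`
targets. Learning rate: linear warmup then cosine decay to lr/10. Early
stopping: an exponential moving average of the loss (factor 0.9) that fails
to improve by 1e-3 for `patience` iterations counts as converged. Adam's
β₁/β₂/weight decay are config-exposed (defaults 0.9/0.999/0). A fresh tiny
model starts at ln(effective vocabulary) nats as expected from near-uniform
logits, and reaches ~1.7 nats after 300 iterations on the 2,000-molecule
study corpus (~4 minutes, one CPU).

## Rewards

Docking scores x (kcal/mol, more negative better) map to rewards by
R(x) = 1 − σ(f(x)) with σ the logistic and f the affine map sending the
empirical docking range [−12, −6] onto [−6, 6] (f(x) = 2x + 18 with
defaults). Hence R(−9) = 0.5, R(−12) + R(−6) = 1, and R is strictly
decreasing in x. Out-of-range scores are extrapolated linearly rather than
clamped — the logistic already saturates smoothly, preserving gradient
signal. The two-pocket reward is the convex combination
αR(x₁) + βR(x₂), α + β = 1 (equal preference α = β = 0.5 by default).

Scaffold constraints are enforced doubly: generation is primed with the
scaffold's SELFIES tokens (the sequence begins `[SOS]` + scaffold), and the
reward is gated to zero for molecules that do not contain the scaffold as
an RDKit substructure match. Either mechanism alone leaves leaks (priming
can be overwritten by later ring closures; gating alone explores slowly);
together they reproduce the observable — near-total scaffold retention
with improving scores.

The surrogate docking adapter maps a molecule to
−9 + 3·tanh(w·z) kcal/mol, where z is a vector of six standardized
structural descriptors (heavy atoms, rings, aromatic atoms, heteroatom
fraction, rotatable bonds, LogP) and w is a unit vector drawn from a
generator seeded by the adapter seed XOR a hash of the pocket identifier —
deterministic, smooth, pocket-dependent, and centred so that typical corpus
molecules score near the middle of the range (epoch-0 mean rewards around
0.4–0.5, leaving headroom for optimization). Standardization constants are fixed to
the synthetic corpus's descriptor location/spread. Failures (unparseable
input) receive the worst-case score −6 rather than aborting a batch.

## PPO

Terminal-only reward at the final generated token with discount 1 (docking
exists only for complete molecules); generalized advantage estimation
(λ = 0.95 default) spreads it backwards; advantages are normalized to zero
mean / unit variance across each rollout batch (the reward range (0,1) is
narrow, so normalization stabilizes update magnitudes). The value head is a
linear map from the final hidden state, trained with squared error against
returns. Updates use the clipped surrogate (ε = 0.2, 4 passes per batch),
an entropy bonus (0.01), and an optional KL penalty toward the frozen
pre-RL reference. Per-token log-probabilities — for both the behavior
snapshot and the updated policy — are computed under the *sampler's*
admissibility masks, so likelihood ratios are exact.

Epoch diagnostics: mean rollout reward, mean raw surrogate score, per-epoch
samples, and the empirical frequency of each chemical token over the
epoch's samples (a probability vector over the vocabulary). Token
frequencies are empirical counts rather than model conditionals: directly
computable and the observable form of "token probability evolution". The
best epoch is selected by mean rollout reward.

Desk-scale study conditions (used by the test suite): tiny model pretrained
on 2,000 synthetic molecules (300 iterations), 10 PPO epochs of 256
rollouts, three seeds. Under these conditions the median best-epoch reward
exceeds the epoch-0 reward by roughly a factor of two; paper-scale absolute
docking improvements are not reproducible at this scale and are replaced by
that relative-uplift property.

## Evaluation

- Diversity: 1 − mean pairwise Tanimoto over 2048-bit radius-2 Morgan
  (ECFP4) fingerprints, all unordered pairs; undefined below two molecules.
- Validity / uniqueness / novelty: GuacaMol-style, in dependency order
  (uniqueness over valid, novelty over unique), canonical SMILES as key.
- QED (RDKit), LogP-in-[0,5] percentage, SAS (RDKit contrib `sascorer`).
- Toxicity: percentage of molecules with any of 12 endpoint probabilities
  ≥ 0.5 ("flagged", matching the lower-is-better orientation). The default
  predictor is a deterministic structural-alert stub (12 SMARTS alerts ->
  0.9/0.05); it is a test harness honoring the 12-endpoint contract, not a
  trained assay model, so published toxicity percentages are not
  reproducible with it. A trained predictor can be plugged in through the
  same one-molecule -> 12-probability contract.
- Novelty confusion: molecule novel iff max Tanimoto against the reference
  < 0.4 (radius-2 Morgan unifies this with the diversity fingerprints);
  scaffold novel iff the Bemis–Murcko framework's canonical SMILES is
  absent from the reference's framework set. Counts fill a 2×2 table.

## Numerical and design choices

- Float32 weights/activations; losses reduced in float64 where it matters.
- `-1e9` as the additive -inf surrogate; masked classes renormalize to
  exactly zero probability after softmax.
- Vocabulary ordering: `[PAD]`, `[SOS]`, `[EOS]` at ids 0–2, then observed
  tokens lexicographically — deterministic and corpus-order-independent, so
  checkpoints are stable across runs.
- Uniqueness keeps first occurrence on ties; greedy sampling resolves
  probability ties by lowest id (argmax convention).
- Checkpoints: `.npz` weight blob + plain-text JSON sidecar carrying the
  config, vocabulary hash and iteration; loading verifies the hash.
- CLI stage seeds are derived from the global seed by hashing the stage
  name (stage-level reproducibility without cross-stage coupling).

## Known limitations

- The codec's chemical subset excludes charged/stereo species; corpora
  containing them are rejected at encoding, not silently coerced.
- The surrogate reward is a six-descriptor linear-tanh landscape: useful
  for exercising RL machinery, trivially exploitable compared to a real
  docking funnel, and blind to 3-D geometry.
- Desk-scale models (tiny preset) memorize corpus statistics quickly;
  conclusions about large-scale pretraining dynamics do not transfer.
- Single-threaded NumPy training: paper-scale presets are instantiable and
  countable but not trainable in reasonable time here.
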