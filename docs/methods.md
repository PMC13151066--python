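# Methods

## Problem setting

Short peptides (3–10 residues) can self-assemble into supramolecular
aggregates whose morphology — elongated fibrils versus compact spheres —
determines their utility as materials. Direct morphology labels are
scarce, so this package steers generation through *proxy descriptors*
computed on the isolated monomer: sequence length, net charge at neutral
pH, a β-strand flag from the monomer's secondary structure, the
hydrophobic moment, plus two aggregation descriptors (a continuous
aggregation propensity, AP, and a binary self-assembly flag derived from
it). The pipeline generates candidate sequences under user-chosen
subsets of these descriptors, screens them for aggregation, verifies
descriptor compliance, and quantifies simulated aggregate shape.

## Descriptors

- **Net charge** q = Σ_l q_l with q_l = +1 for Lys/Arg, −1 for Asp/Glu,
  0 otherwise (His uncharged at neutral pH). Integer, unitless.
- **β-strand flag**: f_β = (#residues labelled `E`)/L over a DSSP-style
  label string supplied *as input* (the package never runs a secondary
  structure assignment program); binarized to `has_beta_strand = 1` iff
  f_β > 0. Only the letter `E` counts — isolated-bridge `B` does not.
- **Hydrophobic moment** M = ‖(1/L) Σ_l h_l v̂_l‖, with h_l the
  Eisenberg consensus hydrophobicity of residue l (the scale is embedded
  as a constant table, `descriptors.EISENBERG_SCALE`) and v̂_l the unit
  vector along Cα→Cβ. The 1/L factor makes M length-independent; the
  construction uses only relative geometry, so M is invariant under
  rigid motion. For Gly or a missing Cβ, a virtual Cβ is placed by the
  standard tetrahedral construction from backbone N, Cα, C — this is
  deterministic and rotation-covariant, which an arbitrary fixed unit
  vector would not be.
- **Units.** All internal geometry is in nanometres; PDB input (Å) is
  converted on read. Conditioning uses min–max normalization with
  statistics fitted on the training split only; binary slots are pinned
  to (0, 1) so they pass through unchanged, a constant slot maps to 0
  with a warning, and a never-observed slot falls back to (0, 1).

The fixed slot order of the 6-vector c is
`(length, ap, is_assembled, has_beta_strand, hydrophobic_moment,
net_charge)`; slots 2–3 are binary, the rest continuous.

## Corpus assembly

AP sources are merged with a priority-source dedup policy (the overlap
report records mean |ΔAP| between sources). Self-assembly labels use the
global operational separators AP ≥ 1.8 → SA, AP ≤ 1.65 → no-SA,
intermediates unlabeled; the thresholds are configurable but deliberately
length-independent. Random-augmentation sequences draw length uniformly
from 3–10 and residues i.i.d. uniform over the 20 canonical codes, and
carry no AP/SA labels by construction. Missing values are an explicit
sentinel (`NA` in files, NaN in memory) plus a mask bit — never imputed.
Splits are stratified by length (80/10/10), deterministic under a seed;
strata smaller than 3 fall back to train with a warning.

## The masked conditional VAE

Sequences are framed as `<bos> r_1 … r_L <eos>` and right-padded to a
12-token frame over a 23-symbol vocabulary (20 residues + 3 specials).
Given descriptors c ∈ R⁶ and observation mask m ∈ {0,1}⁶, an MLP ϕ
summarizes the masked context, s = ϕ([c ⊙ m, m]); unobserved slots are
zeroed before ϕ, so they can influence nothing downstream — the package
treats this as a hard contract and tests it end-to-end (summary, prior,
and fixed-seed generation are bitwise invariant to perturbing an
unobserved slot).

Three components share s:

- **Encoder** q(z|y): token embeddings + sinusoidal positions through a
  pre-norm transformer encoder; contextual states are mean-pooled over
  non-pad positions and mapped by two linear heads to the mean and
  log-variance of a diagonal Gaussian over z.
- **Conditional prior** p(z|s): two linear heads on s.
- **Decoder** p(y|z, s): a pre-norm transformer decoder with causal
  self-attention whose cross-attention memory holds exactly two tokens —
  a projected latent token and a projected condition token. Decoding is
  autoregressive until `<eos>`, with multinomial sampling from the
  temperature-scaled softmax (the frame bound forces `<eos>` at position
  L_max + 1, and an empty decode is resampled).

The loss is

L = L_rec + β·L_KL + λ_mask·L_mask + λ_bin·L_bin + λ_cont·L_cont

with L_rec the label-smoothed token cross-entropy over non-pad targets
(including `<eos>`), L_KL the closed-form diagonal-Gaussian KL between
posterior and conditional prior averaged over the batch, and three light
auxiliary heads on s: BCE on all d mask bits, BCE on *observed* binary
slots only, MSE on *observed* continuous slots only (a sample with no
observed slots of a kind contributes zero to that term). β follows a
cyclic schedule (linear ramp over the first half of each cycle, then
flat).

Training uses AdamW with LR halving on validation plateau, weighted
sampling (×2 for positive `is_assembled`, ×10 for positive
`has_beta_strand`), per-example stochastic masking of observed slots
(drop probability 0.5, always keeping at least one), and per-epoch
augmentation with uniformly random peptides that observe only the length
slot.

### Defaults and the knobs that matter

Full-scale architecture defaults: 2 layers, 8 heads, width 256 for both
encoder and decoder; 250 epochs, AdamW lr 1e-3, weight decay 1e-4,
plateau patience 30, 5000 augmentation peptides per epoch. Quantities
with no authoritative value are explicit config with these defaults:
latent K = 32, summary width 64, ϕ hidden 128, λ_mask = λ_bin = λ_cont
= 1.0, label smoothing ε = 0.1, mask-drop 0.5, cyclic-β period 25 with
β_max = 1.0, temperature 1.0.

The desk-scale configuration (`toy_config()`: width 48, 4 heads, 2
layers, K = 8, 40 epochs) trains in about a minute on one CPU. It sets
ε = 0.01: with temperature-1 multinomial decoding, label smoothing caps
the probability of the correct token at ≈1−ε at every step, so ε
directly bounds achievable condition compliance — at ε = 0.1 a
length-conditioned model cannot exceed ≈90% length compliance no matter
how long it trains, while at ε = 0.01 the same model reaches ≈98%.

Evaluation of the teacher-forced conditional cross-entropy uses the
prior mean as the latent by default (deterministic); sampling the latent
is available by flag. Perplexity is exp(CE) by definition.

## Two-head aggregation predictor

A shared sequence encoder feeds a linear projection and two heads: AP
regression (MSE) and SA classification (logistic, BCE); each term is
averaged only over rows that carry that label, so unlabeled rows
contribute nothing. The encoder is an interface: the default is a small
trainable transformer with masked-mean pooling over residue positions
(special and pad tokens excluded), and an adapter slot exists for an
external pretrained protein language encoder — none is required, and no
external weights ship with the package. Training is two-stage: heads
only with the encoder frozen (AdamW lr 1e-3, 5 epochs), then end-to-end
with discriminative rates (encoder 1e-5, heads 1e-3) and exponential
decay (6 epochs). Those stage-2 settings presume a pretrained encoder;
the desk-scale configuration instead uses encoder lr 1e-3 with 30
stage-2 epochs because a from-scratch encoder needs an ordinary learning
rate. BCE:MSE weighting defaults to 1:1 (configurable).

## Screening funnel

Condition grids sweep the morphology-proxy windows: spheres — lengths
5–7, hydrophobic moment 0.6–1.0 in steps of 0.1 (inclusive, 5 values),
net charge 0.4–0.6 in steps of 0.05 (half-open, 4 values), 60
conditions; fibrils — lengths 7–10, `has_beta_strand = 1`, the same
net-charge sweep, 16 conditions. Moment and charge targets are in
min–max normalized units; `is_assembled` is fixed to 1 everywhere. The
endpoint conventions are the only reading under which a 4800-sequence
budget per regime splits evenly (80 and 300 per condition); both
endpoints are configurable.

Stages: budgeted generation → within-regime dedup (keep first) →
aggregation screen (classifier probability ≥ 0.75 AND predicted
AP ≥ 1.8) → descriptor compliance (every conditioned slot recomputed
from a caller-supplied structure provider must satisfy the matching
rule) → top-15 by predicted AP, ties broken lexicographically for
determinism. A structure-provider failure drops that candidate with a
logged reason. Stage counts are monotone non-increasing by construction.
Baselines run the same screen over uniformly random sequences or
length-only (all proxies masked) generation.

Matching rule: binary slots exact; continuous slots
|pred − target| ≤ 0.10·|target|, with an absolute fallback of 0.02
normalized units when the target is exactly 0 (the relative rule
degenerates there). The aggregate requires all conditioned slots
simultaneously, hence is non-increasing in the number of conditioned
descriptors k.

Cohort statistics: two-sided Wilson score intervals for hit rates
(statsmodels), calls-per-hit N/H with an infinity sentinel at H = 0,
and two-sided Fisher exact tests (scipy; minimum-likelihood two-sided
rule) with the sample odds ratio a·d/(b·c), reported as infinite when a
zero cell makes it undefined.

## Trajectory metrics

- **AP from SASA**: AP = mean(S₁, S₂) / mean(S_{T−1}, S_T) over a
  time-ordered per-frame SASA series (nm²), requiring T ≥ 4. SASA falls
  as peptides bury surface, so aggregators give AP > 1, consistent with
  the SA threshold of 1.8; the ratio is scale-invariant.
- **Clustering**: beads j, k connect iff d_jk − (r_j + r_k) < r_cut
  (default 0.6 nm) with d_jk the minimum-image center distance under an
  orthorhombic periodic box; clusters are connected components; the
  largest is selected by bead count (by mass via flag).
- **RMOI**: members of the largest cluster are unwrapped by walking a
  BFS spanning tree of the contact graph, placing each bead at its
  minimum-image position relative to an already-placed neighbour
  (correct for contact-connected clusters; a cluster percolating more
  than half the box along an axis cannot be represented faithfully by
  any pairwise minimum-image scheme — a known limitation of the metric
  itself). After translating the mass-weighted centroid to the origin,
  the inertia tensor I = Σ_j m_j(‖r̃_j‖²·1 − r̃_j r̃_jᵀ) is
  diagonalized and RMOI = λ₁/λ₃ ∈ (0, 1]. Classification: fibrillar iff
  RMOI ≤ 0.35, spherical iff RMOI ≥ 0.75, undefined between; replicate
  runs combine by strict majority (ties → undefined with a warning).
- **Bead parameters**: radii and masses come from a configurable lookup
  keyed by bead size class; defaults are half the LJ σ of the regular /
  small / tiny coarse-grained classes (0.235 / 0.205 / 0.170 nm) with
  masses 72 / 54 / 36 u. An unknown class raises rather than silently
  defaulting. Only the final saved frame is analysed by default.

## Synthetic data and what passing tests show

`make_synthetic_corpus` emulates the real corpus's observable structure:
uniform random sequences (length 3–10), exact sequence-derived slots, a
*planted* monotone AP rule — ap = 1.2 + 1.2·(hydrophobic residue
fraction) + N(0, 0.05), chosen once so the AP range ≈[1.2, 2.4]
straddles the 1.65/1.8 labeling thresholds the way the real AP
distribution does — SA labels thresholded from that AP, a deterministic
sequence-only hydrophobic moment (the classic 100°-per-residue helical
wheel), a rare β flag for longer sequences, and configurable per-slot
missingness (default 50% on the 3D slots, 20% on AP) mirroring partial
descriptor coverage. The planted ground truth is retained in a
`true_ap` column for recovery tests.

What it does **not** emulate: real sequence–structure coupling (the
moment is a sequence formula, not geometry), realistic amino-acid
composition bias, correlations between β content and AP, or any actual
simulation physics. Passing recovery tests therefore demonstrate that
the models can extract planted signal at the stated scale and that the
pipeline's plumbing (masking, filtering, statistics) is correct — not
that the desk-scale models match full-scale predictive accuracy on real
peptides.

## Numerical choices

- Float64 throughout the autodiff engine (`pepmorph.nn`), a
  self-contained vectorized reverse-mode implementation whose gradients
  are finite-difference-checked in the test suite; attention masks are
  additive (−1e9), BCE-with-logits uses the |x|-stable form, and
  log-softmax subtracts the row max.
- Needleman–Wunsch scoring is unstated by convention: match +1,
  mismatch 0, gap 0, identity = matches / alignment length × 100 over
  the first optimal alignment (deterministic); configurable, and
  absolute similarity values depend on it.
- Levenshtein distances are computed by edlib; the test suite carries an
  independent dynamic-programming oracle.
- Gaussian-mixture condition sampling fits per-length mixtures on
  complete descriptor rows, selecting the component count by BIC in
  1–5 (reg_covar 1e-6); sampled masks spread queries evenly over
  k ∈ {1..6} with length always observed so every query is well-posed.
- Checkpoints are a single `.npz` holding weights plus a JSON header
  (format version, config, scaling stats, vocabulary); loading verifies
  version and vocabulary and round-trips to bit-identical generation.

## Problem sizes used by the shipped experiments

The recovery experiments run at sizes a single CPU handles comfortably
while leaving the conclusions unchanged: the length-conditioning study
trains the desk-scale generator on 1600 peptides (length-only
conditioning corpus, 40 epochs) and measures compliance on 400
conditional samples; the predictor study trains on 4000 planted-rule
records and evaluates rank correlation on a 500-record held-out split.
Oracle equivalences (KL vs Monte Carlo at 1e5 draws, clustering vs
union-find, inertia vs dense eigensolver, NED/NW vs enumeration) use
randomized instances small enough to enumerate exactly.

## Known limitations

- The built-in encoder is intentionally small; absolute accuracy on real
  corpora depends on a pretrained protein language encoder plugged into
  the adapter slot and full-scale training, neither of which ships here.
- The unimodal Gaussian conditional prior averages over the multimodal
  set of sequences consistent with a sparse mask; richer priors are out
  of scope.
- RMOI compresses shape to one ratio: wide fibrils drift into the
  undefined band, and box-spanning aggregates can score spuriously high.
- Triclinic boxes are unsupported (orthorhombic only); SASA itself is
  consumed as a series, never computed from coordinates.
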