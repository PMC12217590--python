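# Methods

## The model

`rgm` implements *renormalizing generative models*: stacks of discrete
state-space models in which transitions among hidden states are conditioned
on latent **paths**.  One level of the hierarchy is a path-augmented POMDP
with categorical tensors

- **A** — likelihoods mapping states to outcomes (or, between levels, to the
  initial states **D** and paths **E** of child groups),
- **B** — state transitions, one slice per path,
- **D**, **E** — priors over initial states and paths,
- **c** — preference counts over outcomes.

All tensors carry Dirichlet concentration parameters ("counts"); normalizing
a count tensor over its outcome axis recovers the categorical distributions,
and digamma differences give expected log-probabilities under the implied
Dirichlet posteriors.  Hierarchical composition is renormalizing: a state at
level *n* generates the initial state and path of each child group at level
*n − 1*, which then unfolds for *R* time steps before the parent updates.
One top-level state therefore spans ∏R level-0 steps — an *event* — and the
hierarchy encodes sequences of sequences.

Two structural commitments matter for inference:

1. **Partition structure.** Children never share parents, so within one
   segment the model is a tree; between segments the top level is a Markov
   chain over events.
2. **Separation of timescales.** Each level performs exactly *R* child
   updates per own update, on a fixed clock; there is no backward message
   passing (smoothing) across segments.

## Fast structure learning

Structure is self-assembled from data, without gradients, by alternating
two renormalization-group operators:

- *spatial blocking*: nearest-neighbour groups are merged; every unique
  combination of member symbols becomes a one-hot likelihood column, in
  order of first appearance;
- *temporal blocking*: the symbol sequence is cut into segments of length
  *R* (pairs by default); every unique segment becomes one super-symbol,
  identified with an (initial state, path) pair.  Paths are successor
  tables filled greedily: a segment joins the first path slice consistent
  with all of its transitions, so distinct continuations of the same
  initial state always occupy distinct slices.

Because every unique observation gets its own one-hot column, top-down
generation from the inferred top trajectory reproduces the training sequence
exactly: structure learning is lossless compression of the training set.
The number of top states is bounded by ⌈T/∏R⌉.

Growth gating (optional, off for batch learning) compares a parent model
with one augmented by a new latent cause.  We accept the new cause iff
ΔF + ΔG > 0 where ΔF is the accuracy gain of the best explanation
(max-state expected log-likelihood) and ΔG the mutual-information gain of
the floored count tensor.  A duplicate of an existing precise column yields
ΔF = 0 and ΔG < 0 and is rejected; an orthogonal observation is accepted.

## Frontends

Images are tessellated into equal pixel blocks; each block vector
concatenates colour channels and *R* consecutive frames (time-major).  Per
group, the training ensemble is mean-centred and decomposed by SVD; the
retained left singular vectors (at most `max_vectors`, and only components
with S_i/S_1 > 1/64) span the code.  Singular variates are quantized to an
odd number of uniformly spaced levels symmetric about zero (span = the
largest training magnitude per variate), so zero is always a bin centre and
a constant group encodes a single symbol.  Among rank-k linear codes the SVD
basis maximizes retained variance, hence (for Gaussian-ish ensembles) the
mutual information between block and code; the test suite verifies this
against random orthonormal bases.  Each retained variate becomes one
categorical observation channel of the level-0 model.

Audio passes through a Gabor filterbank with a *fixed* Gaussian envelope
(default 32 ms) on log-spaced centre frequencies — effectively a short-term
Fourier transform on a log grid.  The inverse drives one cosine oscillator
per bin with the interpolated magnitude envelope; reconstruction is not
sample-exact (phase is discarded), but band-limited content re-analyses to
magnitude images correlating > 0.9 with the original.

## Inference

The upward sweep is exact: within a segment the model is a tree, so
per-group likelihood messages over symbols are products of child messages
gathered through the (floored) one-hot mappings, combined across the
segment's *R* slots.  The top chain is inverted by forward filtering;
accumulated negative log-evidence is the variational free energy F, and −F
the ELBO.  For a model built from N distinct equiprobable exemplars, exact
observation of one exemplar gives ELBO = −ln N, which the tests assert.

The downward sweep distributes the top posterior through segments and
spatial mappings, fusing the cached upward evidence at each level; with
one-hot mappings this product form is exact.  Missing or imprecise
observations are uniform likelihood rows (zero log-contribution), which is
also how pattern completion works: masked groups receive their posterior
predictive from the recognized context.

For single-level models the package separately provides (a) exact marginals
by per-path forward–backward plus a path mixture, used as the oracle
surface, and (b) a mean-field coordinate-descent iterator (`vmp_fixed_point`)
whose expectations are softmaxes of summed log-domain messages and whose
free energy is non-increasing across sweeps (asserted at 1e-9).  Iteration
stops when |ΔF| < 1e-4 nats or after 16 sweeps.  Digamma expected-log
tensors are used for finite counts; logs of normalized tensors in the
infinite-count limit.

## Learning

Likelihood updates are outer products Δa = o ⊗ s of outcome and parent-state
expectations, committed with probability p = σ(−α·G) evaluated over the two
actions "update"/"don't", where G(a) = −MI(a) − expected cost.  MI is the
plug-in mutual information of the joint the counts encode, computed by two
independent routes (direct p·ln p/pq summation, and the raw-count entropy
decomposition) that must agree to 1e-6.  The expected-cost term measures
preferences against the uniform baseline, ln(K·c_o/Σc), so uniform
preferences contribute exactly zero.  With α = 512 (the demonstration
default) the Bayesian model average is effectively model selection.
`active_learn` commits an update only when the committed tensor's MI does
not decrease — the Maxwell's-demon gate — so the recorded MI trace is
monotone; convergence is declared when the mean MI gain over a 32-exemplar
window falls below 1e-3 nats.

Bayesian model reduction scores a reduced prior a′ against fitted posterior
counts **a** and original prior a purely with log-beta algebra,
ΔF = lnΒ(**a**) + lnΒ(a′) − lnΒ(a) − lnΒ(**a** + a′ − a), applied per
conditioning column; the tests check the identity ΔF = 0 at a′ = a and
agreement with directly computed conjugate log evidences at 1e-8.

## Planning and play

The expected free energy of a path decomposes as G = risk − novelty +
ambiguity: risk is the KL from predicted outcomes to preferences (clipped at
32 nats where preference mass vanishes), ambiguity the expected outcome
entropy given states, and novelty the Dirichlet information gain
Σ q(o,s)(1/a_os − 1/A_s).  Inductive inference runs breadth-first backwards
from rewarded events over allowable transitions (normalized probability
> 1e-3); successors precluded from reaching a reward within the horizon
receive a −32-nat log-prior, and the remaining mass follows softmax(−G).

The game loop realizes predictions: the agent filters a posterior over
top-level events (transition prior with preclusion penalties at each event
boundary, per-frame likelihood updates within it) and moves the paddle one
cell per step toward the predicted paddle position of the most probable
event.  Three scheduling/precision choices proved essential and are part of
the design:

- the event clock is fixed (phase = time mod ∏R, never resynchronized),
  matching the reactive scheduling of the hierarchy;
- the paddle row is the *controllable* modality: its prediction errors are
  resolved by action, so it enters state estimation at reduced precision
  (weight 0.25) and event recognition conditions on the ball cells alone;
- the event estimate used for action is restricted to events that explain
  the ball exactly over the current window, which prevents a wrong
  "ball twin" (same position, different velocity) from being sustained by
  its agreement with the agent's own paddle.

When no event explains the ball the agent emits `stay` until a recognizable
event within the attracting set reappears.  Recognized events accumulate
Dirichlet counts during play, sharpening likelihoods and raising the ELBO
trace.  The sticky-hand parameter replaces the argmax move by a sample from
the softmax action posterior with the given probability.

## Synthetic worlds

The fixture generators define the study conditions:

- **Glyphs** (digit stand-ins): seven-segment stroke templates for 10
  classes, 13 exemplars each, jittered by distinct seeded integer offsets
  and alternating stroke thickness on 32×32 RGB frames; distinctness is
  verified *after* codec quantization (7 levels, ≤16 vectors, 8×8 blocks),
  regenerating with the next seed on a collision.
- **Periodic video** (dove stand-in): a disc orbiting a fixed square,
  64 frames with exact period 32.
- **Lorenz video**: Euler–Maruyama integration of the Lorenz system
  (σ=10, ρ=28, β=8/3; dt=0.01, 5 substeps/frame, state noise 2.0·√dt,
  500-step deterministic burn-in), the (x, y) states mapped affinely so the
  wings fill 80 % of a 64×64 frame, a white disc over a faint dotted trail
  of the whole trajectory.  The frame is 64×64 with 16×16-pixel blocks — a
  4×4 group grid — chosen because the measured quantity (uniqueness of
  8-frame segments under chaos) does not depend on pixel count, so larger
  frames only cost time.
- **Pong/Breakout**: 12×9 grids of 5 (Pong) or 6 (Breakout) cell states,
  rendered as 32×32-pixel tiles when pixels are needed; the games feed the
  model directly through the cell alphabet.  Pong's paddle occupies the top
  row and the game is never reset: a miss reflects the ball like a bare
  wall, so the ball stays on one periodic orbit (period lcm(22, 16) = 176).
  Breakout has three bottom target rows (golden row last); hits remove the
  topmost standing row, the golden hit or a miss resets (paddle centred,
  ball served at a fixed height with seeded horizontal jitter).
  Training data are reward-bracketed: runs from just after one hit to and
  including the next, miss-free, preferring segments that start from novel
  post-hit ball configurations before repeating any, concatenated to the
  budget (1,024 frames for Pong out of 21,280 random-play frames — extended
  in further chunks in the rare case the budget is not reached — and 2,048
  for Breakout).

What the fixtures do *not* emulate: real handwriting variability (glyph
jitter is rigid), photometric noise, natural video statistics, or reverberant
audio.  Passing tests therefore certify the algorithmic contracts — lossless
compression, exact inference, gated learning, inductive planning — not
performance on natural data, for which only an external loader hook exists.

## Numerical choices and degenerate inputs

- Count floor ε = 1/32 by default (games use 1/128), configurable; zero
  columns normalize to uniform so generation is defined everywhere.
- All message passing is log-domain with max-subtraction before softmax.
- Trailing partial segments are dropped with a warning, never padded.
- Ties in unique-symbol enumeration cannot occur (exact equality on
  discrete codes); successor slices are ordered by first appearance.
- Zero-evidence observations under an unfloored model raise rather than
  silently renormalize.

## Known limitations

- The exactness of hierarchical inference relies on the one-hot mappings
  produced by structure learning; after heavy count accumulation the
  downward product form is an approximation (exact only for near-
  deterministic mappings).
- Expert play is brittle by construction: the agent cannot respond to ball
  trajectories absent from its reward-bracketed training set.  At the
  default study conditions roughly two thirds of random seeds yield full
  orbit coverage and a miss-free 512-step episode; the remainder lack one
  or two corner-approach segments and miss exactly there.
- The audio inverse discards phase; it is a sonification of the magnitude
  image, not a waveform codec.
- Pong's 176-step orbit makes segment lengths multiples of 4; temporal
  schedules that do not divide the hit interval would break the fixed event
  clock alignment that play relies on.
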