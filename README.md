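# rgm — renormalizing generative models

`rgm` is a Python toolkit for building, learning, and deploying
*renormalizing generative models*: hierarchical discrete state-space models
(generalized POMDPs with latent **paths**) whose levels are related by
renormalization-group operators — blocking over space and time.  It is aimed
at researchers in active inference and Bayesian approaches to perception,
learning, and control who want a complete, testable implementation of:

- **fast structure learning** — self-assembly of the hierarchy from data by
  recording unique states and transitions while coarse-graining, which
  compresses a training sequence losslessly into a stack of one-hot
  likelihood mappings and path-conditioned transition tensors;
- **variational inversion** — message passing with a strict separation of
  timescales (each level performs R child updates per own update), yielding
  posteriors over states and paths and the variational free energy
  F (−F is the ELBO);
- **active learning** — Dirichlet count updates gated by the expected free
  energy of the parameters, G(a) = −MI(a) − expected cost, with precision
  α: only information-increasing updates are assimilated;
- **Bayesian model reduction** — post-hoc scoring of simpler priors by
  log-beta algebra, ΔF = lnΒ(**a**) + lnΒ(a′) − lnΒ(a) − lnΒ(**a**+a′−a);
- **planning as inference** — expected free energy over paths
  (G = risk − novelty + ambiguity), inductive backward reachability from
  rewarded events, and action that realizes predicted outcomes;
- **synthetic worlds** — glyph images, exactly periodic video, a
  Lorenz-SDE-driven ball video, chirp audio, and 12×9 grid Pong/Breakout
  with sparse rewards, so every stage runs without downloads.

The continuous frontend quantizes media into discrete symbols: images are
tiled into blocks, each block (colour and R frames concatenated) is
projected on its leading left singular vectors, and the singular variates
are quantized to an odd number of levels centred on zero.  Audio passes
through a fixed-envelope Gabor (Morlet-style) filterbank first.

See `docs/methods.md` for the model, algorithms, and numerical choices.

## A worked example

Classify synthetic glyphs (13 exemplars for each of 10 classes, all
pairwise distinct after quantization):

```sh
rgm run-demo digits --seed 0
```

prints (abridged):

```json
{
 "level_state_counts": [[45, 32, "...", 49], [95, 98, 80, 96], [130]],
 "image_level_states": 130,
 "label_mapping_shape": [130, 10],
 "lossless": true,
 "train_accuracy": 1.0,
 "elbo_median": -65.31,
 "mi_trace_final": 2.302585092994046,
 "mi_bound": 2.302585092994046
}
```

Reading this: the 16 first-level groups (8×8-pixel blocks of a 32×32 image)
hold 24–51 unique quantized patterns each; 2×2 blocking yields four quadrant
groups (80–98 states); the image-spanning third level holds exactly **130**
latent states — one per training exemplar, so inversion is lossless
(`lossless: true`) — and a fourth, supervision level maps the 10 classes
onto those 130 states.  Every training exemplar is classified correctly, and
gated active learning drives the label-level mutual information to its
ceiling ln 10 ≈ 2.3026 nats (`mi_trace_final` = `mi_bound`).

Other pipelines, same interface: `rgm run-demo dove` (a 64-frame period-32
video compresses to 8 events whose learned transitions form a closed orbit;
generating 128 frames cycles it exactly 4 times), `lorenz`, `birdsong`,
`pong` (structure-learn expert play from reward-bracketed random frames,
then play by inductive inference — a fully covered model never misses),
and `breakout`.  The library surface behind the CLI lives in
`rgm.model_core`, `rgm.frontends`, `rgm.structure`, `rgm.inference`,
`rgm.learning`, `rgm.planning`, `rgm.worlds`, and `rgm.demos`.

```sh
rgm make-fixtures --kind periodic --out fx --seed 0
rgm learn-structure --frames fx/frames --block 8 8 --r 2 --out model
rgm generate --model model --top-state 0 --horizon 32 --out frames_out
rgm play --env pong --steps 512 --sticky 0.0 --seed 0 --record episode.json
```

Models serialize to a directory with a human-readable `manifest.json` plus
an HDF5 array container (`rgm.save_model` / `rgm.load_model`).

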