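"""End-to-end demonstration pipelines on synthetic fixtures.

Each demo mirrors one of the canonical use cases: glyph classification
(digits), periodic video compression (dove stand-in), chaotic video
(Lorenz-driven ball), birdsong-style audio, and grid-game planning (Pong,
Breakout).  Every pipeline runs fixtures -> frontend -> fast structure
learning -> inference/learning/planning and returns a machine-readable
report dictionary; all randomness flows through the single ``seed``.
"""

from __future__ import annotations

import numpy as np

from . import frontends, inference, learning, planning, structure, worlds

__all__ = [
    "demo_digits",
    "demo_periodic",
    "demo_lorenz",
    "demo_birdsong",
    "demo_pong",
    "demo_breakout",
    "run_demo",
]

#: Study conditions for the grid games: training frames selected from random
#: play, and the random-play budget they are selected out of.
PONG_TRAIN_FRAMES = 1024
PONG_RANDOM_FRAMES = 21280
BREAKOUT_TRAIN_FRAMES = 2048
BREAKOUT_RANDOM_FRAMES = 4 * PONG_RANDOM_FRAMES


def demo_digits(seed: int = 0, n_classes: int = 10, per_class: int = 13, active: bool = True):
    """Glyph classification: 130 distinct exemplars, label level, ELBO scoring."""
    frames, labels, part, codecs, obs = worlds.distinct_glyphs(
        n_classes=n_classes, per_class=per_class, seed=seed
    )
    model = structure.fast_structure_learn(obs, R_schedule=[1, 1, 1], temporal=False)
    model.partition, model.codecs = part, codecs
    structure.add_label_level(model, labels)
    # lossless generation: every exemplar is reproduced exactly from its state
    regen = inference.expand_top(model, model.top.sequence)
    lossless = bool(np.array_equal(regen, obs.codes))
    post, elbo = inference.classify(model, obs)
    accuracy = float(np.mean(np.argmax(post, axis=1) == labels))
    report = {
        "level_state_counts": [
            [int(g.n_symbols) for g in lv.groups] for lv in model.levels
        ],
        "image_level_states": int(model.top.n_states),
        "label_mapping_shape": list(model.label.counts.shape),
        "lossless": lossless,
        "train_accuracy": accuracy,
        "elbo_median": float(np.median(elbo)),
    }
    if active:
        model, mi, el = learning.active_learn(model, obs, labels=labels, alpha=512.0)
        report["mi_trace_final"] = float(mi[-1])
        report["mi_bound"] = float(np.log(n_classes))
    return model, obs, report


def demo_periodic(seed: int = 0, n_frames: int = 64, period: int = 32):
    """Periodic video: orbit discovery and multi-cycle generation."""
    frames = worlds.periodic_video(n_frames=n_frames, period=period, image_size=32)
    part = frontends.fit_partition(frames, (8, 8), R=2)
    codecs = frontends.fit_codecs(frames, part, max_vectors=16, n_levels=7)
    obs = frontends.encode(frames, part, codecs)
    model = structure.fast_structure_learn(obs, R_schedule=[1, 1, 2])
    model.partition, model.codecs = part, codecs
    regen = inference.expand_top(model, model.top.sequence)
    gen = inference.generate(model, int(model.top.sequence[0]), horizon=2 * n_frames // part.R)
    gen_frames = frontends.decode(gen, part, codecs)
    report = {
        "top_events": int(model.top.n_states),
        "top_sequence_len": int(model.top.sequence.size),
        "lossless": bool(np.array_equal(regen, obs.codes)),
        "generated_frames": int(gen_frames.shape[0]),
        "cycles_generated": int(gen.codes.shape[0] * part.R // period),
    }
    return model, obs, report


def demo_lorenz(seed: int = 0, n_frames: int = 1024, image_size: int = 64):
    """Chaotic video: structure from the first half, transitions from the second."""
    frames, states = worlds.lorenz_video(n_frames, image_size=image_size, seed=seed)
    half = n_frames // 2
    part = frontends.fit_partition(frames[:half], (image_size // 4, image_size // 4), R=2)
    codecs = frontends.fit_codecs(frames[:half], part, max_vectors=16, n_levels=5)
    obs = frontends.encode(frames[:half], part, codecs)
    model = structure.fast_structure_learn(obs, R_schedule=[2, 2, 1])
    model.partition, model.codecs = part, codecs
    n_paths_before = model.top.B.shape[2]
    obs2 = frontends.encode(frames[half:], part, codecs)
    learning.learn_transitions(model, obs2)
    report = {
        "top_events": int(model.top.n_states),
        "frames_for_structure": half,
        "segments_all_unique": bool(model.top.n_states == model.top.sequence.size),
        "transition_paths_before": int(n_paths_before),
        "transition_paths_after": int(model.top.B.shape[2]),
    }
    return model, obs, report


def demo_birdsong(seed: int = 0, sr: int = 8820):
    """Chirp-call audio: time-frequency frontend, event compression, resynthesis."""
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(8):  # two calls of four chirps each, varied crescendos
        f0 = float(rng.uniform(300, 900))
        events.append((f0, f0 * rng.uniform(1.5, 3.0), 0.25))
    wave = worlds.tone_sequence(events, sr=sr)
    tf, freqs, hop = frontends.audio_to_tf(wave, sr, f_min=40, f_max=4000, n_bins=64)
    # carve the time axis into voxel frames: 64 frequency bins x L time bins
    L = 8
    n_chunks = tf.shape[1] // L
    chunks = tf[:, : n_chunks * L].T.reshape(n_chunks, L, tf.shape[0]).transpose(0, 2, 1)
    chunks = chunks[..., None] / max(tf.max(), 1e-12)
    part = frontends.fit_partition(chunks, (4, L), R=1)
    codecs = frontends.fit_codecs(chunks, part, max_vectors=16, n_levels=5)
    obs = frontends.encode(chunks, part, codecs)
    model = structure.fast_structure_learn(
        obs,
        R_schedule=[1, 2, 2],
        merge_schedule=[
            [[4 * b + j for j in range(4)] for b in range(4)],  # 16 bands -> 4
            [[0, 1, 2, 3]],  # 4 -> 1
        ],
    )
    model.partition, model.codecs = part, codecs
    gen = inference.generate(
        model, int(model.top.sequence[0]), horizon=model.top.sequence.size * 4, seed=seed
    )
    dec = frontends.decode(gen, part, codecs)
    tf_gen = dec[..., 0].transpose(1, 0, 2).reshape(tf.shape[0], -1) * max(tf.max(), 1e-12)
    wave_gen = frontends.tf_to_audio(tf_gen, freqs, hop, sr)
    report = {
        "tf_bins": int(tf.shape[0]),
        "voxel_frames": int(n_chunks),
        "top_events": int(model.top.n_states),
        "generated_seconds": float(wave_gen.size / sr),
    }
    return model, obs, report


def _game_pipeline(env, n_random: int, budget: int, seed: int):
    # selection is continued (in further chunks of random play on the same
    # environment) until the training budget is met
    log = worlds.random_play(env, n_random, seed=seed)
    for chunk in range(1, 9):
        try:
            train, rewards, log = worlds.select_segments(log, budget)
            break
        except ValueError:
            if chunk == 8:
                raise
            log = worlds.concat_logs(log, worlds.random_play(env, n_random, seed=seed + chunk))
    obs = worlds.cells_to_observation(train, env.n_cell_states, grid_shape=(env.H, env.W))
    n_cells = env.n_cells
    model = structure.fast_structure_learn(
        obs,
        R_schedule=[1, 2, 2],
        merge_schedule=[[list(range(n_cells))], [[0]]],
        floor=1.0 / 128.0,
    )
    rewarded = planning.rewarded_events(model, rewards)
    pref = np.zeros(model.top.n_states)
    pref[rewarded] = 1.0
    model.preferences = pref
    return model, obs, rewarded, log


def demo_pong(seed: int = 0, play_steps: int = 512, sticky_p: float = 0.0,
              n_random: int = PONG_RANDOM_FRAMES, budget: int = PONG_TRAIN_FRAMES):
    """Pong: reward-bracketed structure learning, then inductive expert play."""
    env = worlds.PongEnv(seed=seed)
    model, obs, rewarded, log = _game_pipeline(env, n_random, budget, seed)
    start = log.selected_segments[0][0]
    play_env = worlds.PongEnv(seed=seed + 1)
    play_env.state = log.states[start]  # snapshot preceding the first training frame
    play = planning.play_episode(
        model, play_env, play_steps, rewarded,
        start_event=int(model.top.sequence[0]), sticky_p=sticky_p, seed=seed,
    )
    report = {
        "training_frames": int(obs.codes.shape[0]),
        "top_events": int(model.top.n_states),
        "event_bound": budget // model.temporal_factor,
        "transition_paths": int(model.top.B.shape[2]),
        "rewarded_events": int(rewarded.size),
        "play_steps": play_steps,
        "hits": play.n_hits,
        "misses": play.n_misses,
        "lost_windows": play.lost_windows,
        "elbo_first_half": float(np.mean(play.elbo[: play_steps // 2])),
        "elbo_second_half": float(np.mean(play.elbo[play_steps // 2 :])),
    }
    return model, play, report


def demo_breakout(seed: int = 0, play_steps: int = 512, sticky_p: float = 0.1,
                  n_random: int = BREAKOUT_RANDOM_FRAMES, budget: int = BREAKOUT_TRAIN_FRAMES):
    """Breakout: doubled training budget, sticky action, recovery after misses."""
    env = worlds.BreakoutEnv(seed=seed)
    model, obs, rewarded, log = _game_pipeline(env, n_random, budget, seed)
    start = log.selected_segments[0][0]
    play_env = worlds.BreakoutEnv(seed=seed + 1)
    play_env.state = log.states[start]  # snapshot preceding the first training frame
    play = planning.play_episode(
        model, play_env, play_steps, rewarded,
        start_event=int(model.top.sequence[0]), sticky_p=sticky_p, seed=seed,
    )
    report = {
        "training_frames": int(obs.codes.shape[0]),
        "top_events": int(model.top.n_states),
        "transition_paths": int(model.top.B.shape[2]),
        "rewarded_events": int(rewarded.size),
        "play_steps": play_steps,
        "hits": play.n_hits,
        "misses": play.n_misses,
        "lost_windows": play.lost_windows,
        "elbo_first_half": float(np.mean(play.elbo[: play_steps // 2])),
        "elbo_second_half": float(np.mean(play.elbo[play_steps // 2 :])),
    }
    return model, play, report


_DEMOS = {
    "digits": demo_digits,
    "dove": demo_periodic,
    "lorenz": demo_lorenz,
    "birdsong": demo_birdsong,
    "pong": demo_pong,
    "breakout": demo_breakout,
}


def run_demo(name: str, seed: int = 0, **kwargs):
    """Run one named demo pipeline; returns its report dictionary."""
    if name not in _DEMOS:
        raise ValueError(f"unknown demo {name!r}; choose from {sorted(_DEMOS)}")
    out = _DEMOS[name](seed=seed, **kwargs)
    report = out[-1]
    report["demo"] = name
    report["seed"] = seed
    return out[0], report
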