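"""Synthetic environments and media fixtures.

Everything the demonstrations need is generated here, seeded and
deterministic: grid-world Pong and Breakout with sparse rewards, a
Lorenz-SDE-driven ball video, an exactly periodic articulated video, distinct
class-exemplar glyph images, and chirp-event tone sequences.  The grid games
expose their cell alphabet directly as level-0 discrete observations (the
canonical path for planning experiments); all image fixtures can also flow
through the SVD frontend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CELL_BACKGROUND",
    "CELL_BALL",
    "CELL_PADDLE_L",
    "CELL_PADDLE_M",
    "CELL_PADDLE_R",
    "CELL_TARGET",
    "GridGameState",
    "PongEnv",
    "BreakoutEnv",
    "EpisodeLog",
    "random_play",
    "select_segments",
    "lorenz_video",
    "periodic_video",
    "glyph_images",
    "distinct_glyphs",
    "tone_sequence",
    "render_cells",
]

CELL_BACKGROUND = 0
CELL_BALL = 1
CELL_PADDLE_L = 2
CELL_PADDLE_M = 3
CELL_PADDLE_R = 4
CELL_TARGET = 5  # Breakout only: its cell alphabet has six symbols

#: RGB palette for rendering cells as 32x32 pixel tiles.
PALETTE = np.array(
    [
        [0, 0, 0],  # background
        [255, 255, 255],  # ball
        [80, 160, 255],  # paddle left
        [40, 120, 255],  # paddle mid
        [80, 160, 255],  # paddle right
        [255, 200, 60],  # target
    ],
    dtype=np.uint8,
)


@dataclass
class GridGameState:
    """State of a 12x9 grid game: ball, velocity, paddle, targets, flags."""

    ball: tuple[int, int]  # (x, y); y = 0 is the paddle row
    vel: tuple[int, int]
    paddle_x: int  # leftmost of 3 contiguous paddle cells
    remaining_rows: int = 0  # Breakout target rows still standing
    reward: bool = False
    miss: bool = False
    reset: bool = False


class _GridGame:
    """Common machinery: geometry, serving, rendering."""

    W = 12
    H = 9
    PADDLE = 3
    SERVE_Y = 4
    n_cell_states = 5

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.state = GridGameState(
            ball=(self.W // 2, self.SERVE_Y),
            vel=(1, 1),
            paddle_x=(self.W - self.PADDLE) // 2,
            remaining_rows=self._initial_rows(),
        )
        self.state = replace(self.state, ball=self._serve()[0], vel=self._serve_vel())

    def _initial_rows(self) -> int:
        return 0

    def _serve(self):
        """Ball re-entry: fixed height, random horizontal around the centre."""
        x = int(self.W // 2 + self.rng.integers(-2, 3))
        return (x, self.SERVE_Y), None

    def _serve_vel(self):
        return (int(self.rng.choice([-1, 1])), 1)

    @property
    def n_cells(self) -> int:
        return self.W * self.H

    def observe(self) -> np.ndarray:
        """Cell symbol codes, row-major over (y, x); exactly one ball cell."""
        cells = np.full((self.H, self.W), CELL_BACKGROUND, dtype=np.int64)
        self._draw_targets(cells)
        px = self.state.paddle_x
        cells[0, px : px + self.PADDLE] = (CELL_PADDLE_L, CELL_PADDLE_M, CELL_PADDLE_R)
        bx, by = self.state.ball
        cells[by, bx] = CELL_BALL
        return cells.ravel()

    def _draw_targets(self, cells):
        pass

    def step(self, action: int) -> GridGameState:
        raise NotImplementedError

    def _move_paddle(self, action: int) -> int:
        return int(np.clip(self.state.paddle_x + int(action), 0, self.W - self.PADDLE))


class PongEnv(_GridGame):
    """Pong on a 12x9 grid: paddle on the top row, elastic walls elsewhere.

    The ball moves one cell per step with constant momentum and simply
    bounces around inside the box; the game is never reset.  Reaching the
    paddle row covered is a hit (reward); uncovered, a miss is flagged and
    the ball reflects off the top wall as if it were bare.  Dynamics are
    fully deterministic after the seeded initial serve.
    """

    def step(self, action: int) -> GridGameState:
        px = self._move_paddle(action)
        x, y = self.state.ball
        vx, vy = self.state.vel
        if not 0 <= x + vx <= self.W - 1:
            vx = -vx
        if not 0 <= y + vy <= self.H - 1:
            vy = -vy
        x, y = x + vx, y + vy
        reward = miss = False
        if y == 0:
            reward = px <= x <= px + self.PADDLE - 1
            miss = not reward
            vy = 1  # returned by the paddle or reflected by the bare wall
        self.state = GridGameState(
            ball=(x, y), vel=(vx, vy), paddle_x=px, reward=reward, miss=miss
        )
        return self.state


class BreakoutEnv(_GridGame):
    """Breakout variant: target rows at the bottom, golden row last.

    Hitting the topmost standing target row scores a reward and removes the
    row; hitting the golden (bottom-most) target resets the game.  A miss or
    a reset re-centres the paddle and re-serves the ball at a fixed height
    and a seeded horizontal location around the centre.
    """

    TARGET_ROWS = 3
    n_cell_states = 6

    def _initial_rows(self) -> int:
        return self.TARGET_ROWS

    def _draw_targets(self, cells):
        if self.state.remaining_rows:
            cells[self.H - self.state.remaining_rows :, :] = CELL_TARGET

    def step(self, action: int) -> GridGameState:
        px = self._move_paddle(action)
        x, y = self.state.ball
        vx, vy = self.state.vel
        remaining = self.state.remaining_rows
        if not 0 <= x + vx <= self.W - 1:
            vx = -vx
        target_top = self.H - remaining if remaining else self.H
        if y + vy >= target_top and remaining:
            # ball strikes the face of the topmost standing row
            remaining -= 1
            vy = -1
            reward, miss, reset = True, False, remaining == 0
            x = x + vx
            if reset:
                remaining = self.TARGET_ROWS
                px = (self.W - self.PADDLE) // 2
                (x, y), _ = self._serve()
                vx, vy = self._serve_vel()
            self.state = GridGameState(
                ball=(x, y), vel=(vx, vy), paddle_x=px,
                remaining_rows=remaining, reward=reward, miss=miss, reset=reset,
            )
            return self.state
        if not 0 <= y + vy <= self.H - 1:
            vy = -vy
        x, y = x + vx, y + vy
        reward = miss = reset = False
        if y == 0:
            if px <= x <= px + self.PADDLE - 1:
                reward, vy = True, 1
            else:
                miss = True
                px = (self.W - self.PADDLE) // 2
                (x, y), _ = self._serve()
                vx, vy = self._serve_vel()
        self.state = GridGameState(
            ball=(x, y), vel=(vx, vy), paddle_x=px,
            remaining_rows=remaining, reward=reward, miss=miss, reset=reset,
        )
        return self.state


@dataclass
class EpisodeLog:
    """Frames, actions, rewards and the segments selected for training."""

    frames: np.ndarray  # (T, n_cells) cell codes
    actions: np.ndarray  # (T,)
    rewards: np.ndarray  # (T,) bool
    misses: np.ndarray  # (T,) bool
    states: list[GridGameState] = field(default_factory=list)  # pre-frame snapshots
    selected_segments: list[tuple[int, int]] = field(default_factory=list)


def random_play(env: _GridGame, n_frames: int, seed: int = 0) -> EpisodeLog:
    """Roll the environment under uniform random actions."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, env.n_cells), dtype=np.int64)
    actions = np.zeros(n_frames, dtype=np.int64)
    rewards = np.zeros(n_frames, dtype=bool)
    misses = np.zeros(n_frames, dtype=bool)
    states = []
    for t in range(n_frames):
        states.append(replace(env.state))
        a = int(rng.integers(-1, 2))
        s = env.step(a)
        frames[t] = env.observe()
        actions[t] = a
        rewards[t] = s.reward
        misses[t] = s.miss
    return EpisodeLog(frames=frames, actions=actions, rewards=rewards, misses=misses, states=states)


def concat_logs(a: EpisodeLog, b: EpisodeLog) -> EpisodeLog:
    """Join two contiguous episodes (b must continue a's environment)."""
    return EpisodeLog(
        frames=np.concatenate([a.frames, b.frames]),
        actions=np.concatenate([a.actions, b.actions]),
        rewards=np.concatenate([a.rewards, b.rewards]),
        misses=np.concatenate([a.misses, b.misses]),
        states=a.states + b.states,
    )


def select_segments(log: EpisodeLog, budget: int):
    """Reward-bracketed data selection.

    Keeps frame runs that start from a rewarded outcome (the frame after the
    previous hit), end in the subsequent hit (inclusive — so the terminal
    hit, with the paddle covering the ball, belongs to the segment), and
    contain no miss; chained hits join seamlessly.  Segments are concatenated
    until ``budget`` frames are collected.  Returns ``(frames, rewards,
    log_with_segments)``; raises if random play produced no usable segment.
    """
    hits = np.flatnonzero(log.rewards)
    eligible = [
        (int(i) + 1, int(j) + 1)
        for i, j in zip(hits[:-1], hits[1:])
        if not log.misses[i + 1 : j + 1].any()
    ]
    # smart data selection: cover as many distinct post-hit ball
    # configurations as possible before repeating any (the ball's hit-to-hit
    # dynamics are deterministic, so one segment per configuration suffices
    # to predict expert play from it)
    def config(seg):
        s = log.states[seg[0]]
        return (s.ball, s.vel) if log.states else seg

    seen = set()
    first_pass, rest = [], []
    for seg in eligible:
        c = config(seg)
        (rest if c in seen else first_pass).append(seg)
        seen.add(c)
    segments = []
    total = 0
    for seg in first_pass + rest:
        segments.append(seg)
        total += seg[1] - seg[0]
        if total >= budget:
            break
    if not segments:
        raise ValueError(
            "no reward-to-reward, miss-free segment found; generate more random-play frames"
        )
    if total < budget:
        raise ValueError(
            f"only {total} selected frames available for a budget of {budget}; "
            "generate more random-play frames"
        )
    frames = np.concatenate([log.frames[i:j] for i, j in segments])[:budget]
    rewards = np.concatenate([log.rewards[i:j] for i, j in segments])[:budget]
    log.selected_segments = segments
    return frames, rewards, log


def cells_to_observation(frames: np.ndarray, n_cell_states: int, grid_shape=(9, 12)):
    """Wrap cell-code frames as a DiscreteObservation (one channel per cell)."""
    from .frontends import DiscreteObservation

    n_cells = frames.shape[1]
    return DiscreteObservation(
        codes=np.asarray(frames, dtype=np.int64),
        alphabet=np.full(n_cells, n_cell_states, dtype=np.int64),
        channel_groups=[[c] for c in range(n_cells)],
        grid_shape=grid_shape,
    )


def render_cells(codes: np.ndarray, grid_shape=(9, 12), tile: int = 32) -> np.ndarray:
    """Render cell codes to an RGB frame of (H*tile, W*tile) TrueColor pixels."""
    H, W = grid_shape
    cells = np.asarray(codes).reshape(H, W)
    img = PALETTE[cells]
    return np.kron(img, np.ones((tile, tile, 1), dtype=np.uint8))


# ---------------------------------------------------------------------------
# Lorenz-driven ball video
# ---------------------------------------------------------------------------

LORENZ_SIGMA = 10.0
LORENZ_RHO = 28.0
LORENZ_BETA = 8.0 / 3.0


def _lorenz_drift(s):
    x, y, z = s
    return np.array(
        [LORENZ_SIGMA * (y - x), x * (LORENZ_RHO - z) - y, x * y - LORENZ_BETA * z]
    )


def lorenz_states(n_frames: int, dt: float = 0.01, substeps: int = 5,
                  noise_sd: float = 2.0, seed: int = 0) -> np.ndarray:
    """Euler-Maruyama integration of the Lorenz SDE, one row per frame.

    Each frame advances ``substeps`` Euler steps of ``dt`` with additive state
    noise of standard deviation ``noise_sd * sqrt(dt)`` per step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    s = np.array([1.0, 1.0, 24.0])
    # burn-in onto the attractor (deterministic)
    for _ in range(500):
        s = s + dt * _lorenz_drift(s)
    out = np.zeros((n_frames, 3))
    for t in range(n_frames):
        for _ in range(substeps):
            s = s + dt * _lorenz_drift(s) + noise_sd * np.sqrt(dt) * rng.standard_normal(3)
        out[t] = s
    return out


def lorenz_video(
    n_frames: int,
    dt: float = 0.01,
    noise_sd: float = 2.0,
    image_size: int = 64,
    seed: int = 0,
    substeps: int = 5,
):
    """Render a white ball tracing the Lorenz (x, y) states over a dotted trail.

    The attractor's (x, y) support is affinely mapped so its wings fill 80%
    of the frame.  Returns ``(frames, states)`` with frames (T, S, S, 3)
    floats in [0, 1].
    """
    states = lorenz_states(n_frames, dt=dt, substeps=substeps, noise_sd=noise_sd, seed=seed)
    S = image_size
    span = 22.0  # |x|, |y| rarely exceed this on the attractor
    pos = np.clip((states[:, :2] / span) * 0.4 + 0.5, 0.05, 0.95) * (S - 1)
    frames = np.zeros((n_frames, S, S, 3))
    trail = np.zeros((S, S))
    for t in range(n_frames):
        px, py = pos[t]
        trail[int(round(py)), int(round(px))] = 1.0
    yy, xx = np.mgrid[0:S, 0:S]
    radius = max(S // 16, 2)
    for t in range(n_frames):
        px, py = pos[t]
        frame = np.zeros((S, S))
        frame += 0.3 * trail  # golden dotted trajectory, drawn faintly
        disc = (xx - px) ** 2 + (yy - py) ** 2 <= radius**2
        frame[disc] = 1.0
        frames[t, :, :, 0] = frame
        frames[t, :, :, 1] = np.where(disc, 1.0, 0.25 * trail[0:S, 0:S])
        frames[t, :, :, 2] = np.where(disc, 1.0, 0.0)
    return frames, states


# ---------------------------------------------------------------------------
# Periodic video, glyphs, tones
# ---------------------------------------------------------------------------


def periodic_video(n_frames: int = 64, period: int = 32, image_size: int = 32) -> np.ndarray:
    """Exactly periodic articulated video: a disc orbiting a fixed square.

    Frame t equals frame t + period bit-exactly.  Returns (T, S, S, 3).
    """
    if n_frames % period:
        raise ValueError(f"period {period} must divide n_frames {n_frames}")
    S = image_size
    yy, xx = np.mgrid[0:S, 0:S]
    c = (S - 1) / 2.0
    cycle = np.zeros((period, S, S, 3))
    for t in range(period):
        ang = 2 * np.pi * t / period
        px = c + 0.33 * S * np.cos(ang)
        py = c + 0.33 * S * np.sin(ang)
        disc = (xx - px) ** 2 + (yy - py) ** 2 <= (S / 10.0) ** 2
        frame = np.zeros((S, S))
        frame[int(c) - 2 : int(c) + 3, int(c) - 2 : int(c) + 3] = 0.5
        frame[disc] = 1.0
        cycle[t] = frame[..., None]
    return np.tile(cycle, (n_frames // period, 1, 1, 1))


# 7-segment style stroke templates on a unit cell: (x0, y0, x1, y1) per stroke
_SEGS = {
    "top": (0.2, 0.15, 0.8, 0.15),
    "mid": (0.2, 0.5, 0.8, 0.5),
    "bot": (0.2, 0.85, 0.8, 0.85),
    "tl": (0.2, 0.15, 0.2, 0.5),
    "tr": (0.8, 0.15, 0.8, 0.5),
    "bl": (0.2, 0.5, 0.2, 0.85),
    "br": (0.8, 0.5, 0.8, 0.85),
}
_DIGIT_SEGS = [
    ["top", "tl", "tr", "bl", "br", "bot"],  # 0
    ["tr", "br"],  # 1
    ["top", "tr", "mid", "bl", "bot"],  # 2
    ["top", "tr", "mid", "br", "bot"],  # 3
    ["tl", "mid", "tr", "br"],  # 4
    ["top", "tl", "mid", "br", "bot"],  # 5
    ["top", "tl", "mid", "bl", "br", "bot"],  # 6
    ["top", "tr", "br"],  # 7
    ["top", "mid", "bot", "tl", "tr", "bl", "br"],  # 8
    ["top", "mid", "bot", "tl", "tr", "br"],  # 9
]


def _draw_stroke(img, x0, y0, x1, y1, thickness):
    S = img.shape[0]
    n = 2 * S
    ts = np.linspace(0, 1, n)
    xs = x0 + (x1 - x0) * ts
    ys = y0 + (y1 - y0) * ts
    yy, xx = np.mgrid[0:S, 0:S]
    for x, y in zip(xs * (S - 1), ys * (S - 1)):
        img[(xx - x) ** 2 + (yy - y) ** 2 <= thickness**2] = 1.0


def glyph_images(
    n_classes: int = 10, per_class: int = 13, image_size: int = 32, seed: int = 0
):
    """Distinct class-exemplar glyphs: jittered seven-segment digit strokes.

    Each exemplar of a class shifts the class template by a distinct (dx, dy)
    offset drawn (seeded) from a coarse grid, so exemplars are pairwise
    distinct by construction in pixel space.  Returns ``(frames, labels)``
    with frames (n_classes * per_class, S, S, 3) in [0, 1], grouped by class.
    """
    if n_classes > len(_DIGIT_SEGS):
        raise ValueError(f"at most {len(_DIGIT_SEGS)} glyph classes available")
    rng = np.random.default_rng(seed)
    S = image_size
    offsets = [(dx, dy) for dx in (-4, -2, 0, 2, 4) for dy in (-4, -2, 0, 2, 4)]
    frames = np.zeros((n_classes * per_class, S, S, 3))
    labels = np.zeros(n_classes * per_class, dtype=np.int64)
    i = 0
    for k in range(n_classes):
        chosen = rng.permutation(len(offsets))[:per_class]
        for e in range(per_class):
            dx, dy = offsets[chosen[e]]
            img = np.zeros((S, S))
            th = 1.6 + 0.4 * (e % 2)
            for seg in _DIGIT_SEGS[k]:
                x0, y0, x1, y1 = _SEGS[seg]
                _draw_stroke(
                    img,
                    x0 + dx / S,
                    y0 + dy / S,
                    x1 + dx / S,
                    y1 + dy / S,
                    th,
                )
            frames[i] = img[..., None]
            labels[i] = k
            i += 1
    return frames, labels


def distinct_glyphs(
    n_classes: int = 10,
    per_class: int = 13,
    image_size: int = 32,
    seed: int = 0,
    block_shape=(8, 8),
    n_levels: int = 7,
    max_vectors: int = 16,
    attempts: int = 10,
):
    """Glyphs verified pairwise-distinct *after* codec quantization.

    Fits the demo codec on the generated set, encodes, and checks that every
    whole-image code is unique; on a collision the set is regenerated with
    the next seed.  Returns ``(frames, labels, part, codecs, obs)``.
    """
    from . import frontends

    for attempt in range(attempts):
        frames, labels = glyph_images(n_classes, per_class, image_size, seed + attempt)
        part = frontends.fit_partition(frames, block_shape, R=1)
        codecs = frontends.fit_codecs(frames, part, max_vectors=max_vectors, n_levels=n_levels)
        obs = frontends.encode(frames, part, codecs)
        uniq = np.unique(obs.codes, axis=0)
        if uniq.shape[0] == obs.codes.shape[0]:
            return frames, labels, part, codecs, obs
    raise RuntimeError(
        f"glyphs collide after quantization in {attempts} attempts; widen the codec"
    )


def tone_sequence(events, sr: int = 8000) -> np.ndarray:
    """Concatenated chirp events: ``events`` is a list of (f0, f1, duration_s)."""
    from scipy.signal import chirp

    parts = []
    for f0, f1, dur in events:
        t = np.arange(int(dur * sr)) / sr
        env = np.sin(np.pi * np.minimum(t / dur, 1.0)) ** 2  # smooth on/offset
        parts.append(env * chirp(t, f0=f0, t1=dur, f1=f1))
    return np.concatenate(parts) if parts else np.zeros(0)
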