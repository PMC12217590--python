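"""Planning as inference: expected free energy, induction, and action.

A path's prior probability is the softmax of its negative expected free
energy, decomposed into *risk* (KL from predicted outcomes to preferred
ones), *ambiguity* (expected outcome entropy given states), and *novelty*
(expected information gain about the Dirichlet parameters), with
``G = risk - novelty + ambiguity``.

Inductive inference works backwards from rewarded events over the top-level
transition graph: a state is precluded at horizon k if no allowable
transition chain reaches a rewarded event within k steps.  Planning assigns
precluded successors a large negative log-prior, so the agent only ever
predicts paths inside the attracting set that links rewards; action then
simply realizes those predictions, by choosing whichever move best matches
the predicted outcome of the controllable modality (here, the paddle row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .inference import expand_top
from .model_core import RGModel, normalize, softmax

__all__ = [
    "EfeDecomposition",
    "efe_paths",
    "ReachabilityMap",
    "inductive_reachability",
    "plan_next_event",
    "select_action",
    "rewarded_events",
    "PlayLog",
    "play_episode",
]

#: Log-prior penalty (nats) for transitions into precluded states: large but
#: finite so the softmax stays well defined.
PRECLUSION_COST = 32.0
#: Ceiling (nats) on the risk of outcomes with zero preference mass.
RISK_CEILING = 32.0
#: Normalized transition probability above which an edge counts as allowable.
EDGE_THRESHOLD = 1e-3


@dataclass
class EfeDecomposition:
    """Expected free energy of one path, term by term (all in nats)."""

    risk: float
    ambiguity: float
    novelty: float

    @property
    def G(self) -> float:
        return self.risk - self.novelty + self.ambiguity


def efe_paths(
    A: np.ndarray,
    B: np.ndarray,
    q_state: np.ndarray,
    c: np.ndarray | None = None,
    floor: float = 1e-6,
) -> list[EfeDecomposition]:
    """Expected free energy per path, one event ahead.

    ``A`` are likelihood counts (outcomes x states), ``B`` transition counts
    (states x states x paths) and ``q_state`` the current state posterior.
    ``c`` holds preference counts over outcomes (uniform when omitted).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    q_state = np.asarray(q_state, dtype=float)
    n_out = A.shape[0]
    Anorm = normalize(A + floor)
    col_sums = (A + floor).sum(axis=0)
    pref = np.full(n_out, 1.0 / n_out) if c is None else np.asarray(c, float) / np.asarray(c, float).sum()
    with np.errstate(divide="ignore"):
        log_pref = np.log(pref)
    out = []
    for u in range(B.shape[2]):
        q_next = normalize(B[:, :, u] + floor) @ q_state
        q_out = Anorm @ q_next
        # risk: KL from predicted outcomes to preferences, clipped where the
        # preference mass vanishes
        ratio = np.where(pref > 0, np.log(q_out + 1e-300) - log_pref, RISK_CEILING)
        if np.any((pref <= 0) & (q_out > 1e-12)):
            warnings.warn("predictive support on a zero-preference outcome; risk clipped")
        risk = float(np.sum(q_out * np.minimum(ratio, RISK_CEILING)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(Anorm > 0, Anorm * np.log(Anorm), 0.0).sum(axis=0)
        ambiguity = float(ent @ q_next)
        novelty = float(
            np.sum((Anorm * q_next[None, :]) * (1.0 / (A + floor) - 1.0 / col_sums[None, :]))
        )
        out.append(EfeDecomposition(risk=risk, ambiguity=ambiguity, novelty=novelty))
    return out


@dataclass
class ReachabilityMap:
    """Minimal number of events from each state to a rewarded event."""

    steps_to_reward: np.ndarray  # float; np.inf where a reward is precluded
    rewarded_set: np.ndarray

    def precluded(self) -> np.ndarray:
        return ~np.isfinite(self.steps_to_reward)


def inductive_reachability(
    B: np.ndarray,
    rewarded_set,
    horizon: int | None = None,
    threshold: float = EDGE_THRESHOLD,
) -> ReachabilityMap:
    """Backward breadth-first iteration over allowable transitions.

    An edge s -> s' is allowable when any path slice gives it normalized
    probability above ``threshold``.  Rewarded states sit at 0 steps; states
    from which no chain of length <= horizon reaches a reward are precluded.
    """
    rewarded = np.asarray(list(rewarded_set), dtype=np.int64)
    if rewarded.size == 0:
        raise ValueError("rewarded_set must be non-empty")
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    allow = np.zeros((n, n), dtype=bool)  # allow[s', s]
    for u in range(B.shape[2]):
        allow |= normalize(B[:, :, u]) > threshold
    # keep only columns with actual support (normalize maps empty cols to uniform)
    allow &= B.sum(axis=2) > 0
    steps = np.full(n, np.inf)
    steps[rewarded] = 0.0
    frontier = set(rewarded.tolist())
    k = 0
    horizon = n if horizon is None else horizon
    while frontier and k < horizon:
        k += 1
        nxt = set()
        for t in frontier:
            for s in np.flatnonzero(allow[t]):
                if steps[s] > k:
                    steps[s] = k
                    nxt.add(int(s))
        frontier = nxt
    return ReachabilityMap(steps_to_reward=steps, rewarded_set=rewarded)


def plan_next_event(
    B: np.ndarray,
    q_state: np.ndarray,
    reach: ReachabilityMap,
    G: np.ndarray | None = None,
    floor: float = 1e-6,
):
    """Prior over paths (and implied next events) one step ahead.

    Paths whose predicted successors are precluded from reaching a reward
    carry the preclusion cost; the remaining mass follows ``softmax(-G)``.
    Returns ``(path_prior, state_prior)``; falls back to uniform with a
    warning when every successor is precluded.
    """
    B = np.asarray(B, dtype=float)
    n_paths = B.shape[2]
    G = np.zeros(n_paths) if G is None else np.asarray(G, dtype=float)
    precluded = reach.precluded()
    logp = np.empty(n_paths)
    preds = []
    for u in range(n_paths):
        q_next = normalize(B[:, :, u] + floor) @ np.asarray(q_state, float)
        preds.append(q_next)
        logp[u] = -G[u] - PRECLUSION_COST * float(q_next @ precluded)
    if all(float(p @ precluded) > 0.999 for p in preds):
        warnings.warn("all successors precluded; falling back to a uniform path prior")
        path_prior = np.full(n_paths, 1.0 / n_paths)
    else:
        path_prior = softmax(logp)
    state_prior = np.einsum("u,us->s", path_prior, np.stack(preds))
    return path_prior, state_prior


def select_action(
    predicted_obs: np.ndarray,
    candidate_actions,
    env_model,
    sticky_p: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Choose the action whose consequence best matches the prediction.

    ``env_model(action)`` returns the controllable-modality outcome codes the
    action would produce; the score of an action is the number of codes
    agreeing with ``predicted_obs`` (maximizing predictive accuracy =
    minimizing variational free energy restricted to that modality).  With
    probability ``sticky_p`` the action is instead sampled from the softmax
    action posterior — the "shaky hand".
    """
    candidate_actions = list(candidate_actions)
    if not candidate_actions:
        raise ValueError("empty candidate action set")
    target = np.asarray(predicted_obs)
    scores = np.array(
        [float(np.sum(np.asarray(env_model(a)) == target)) for a in candidate_actions]
    )
    rng = np.random.default_rng(seed) if rng is None else rng
    if sticky_p > 0 and rng.random() < sticky_p:
        p = softmax(scores)
        return candidate_actions[int(rng.choice(len(candidate_actions), p=p))]
    return candidate_actions[int(np.argmax(scores))]


def rewarded_events(model: RGModel, rewards: np.ndarray) -> np.ndarray:
    """Top states whose training segments contained a reward."""
    factor = model.temporal_factor
    T_top = model.top.sequence.size
    seg = np.asarray(rewards[: T_top * factor], dtype=bool).reshape(T_top, factor)
    return np.unique(model.top.sequence[seg.any(axis=1)])


@dataclass
class PlayLog:
    """Frame-level record of one planned episode."""

    frames: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    misses: np.ndarray
    elbo: np.ndarray  # per-frame log-likelihood of the recognized event
    n_hits: int = 0
    n_misses: int = 0
    lost_windows: int = 0
    event_trace: list[int] = field(default_factory=list)


def play_episode(
    model: RGModel,
    env,
    n_steps: int,
    rewarded: np.ndarray,
    start_event: int | None = None,
    sticky_p: float = 0.0,
    seed: int = 0,
    floor: float = 1.0 / 128.0,
    accumulate: bool = True,
    paddle_precision: float = 0.25,
) -> PlayLog:
    """Realize the model's predictions in a grid game for ``n_steps`` frames.

    The agent tracks a posterior over top-level events: at each event
    boundary the prior follows the learned transitions with precluded
    successors penalized (inductive inference); within the event each
    observed frame multiplies in its likelihood.  The paddle row is the
    *controllable* modality: its prediction errors are resolved by action
    (the agent moves to realize the predicted paddle), so it enters state
    estimation with reduced precision ``paddle_precision`` and event
    recognition conditions on the remaining (ball) cells.  When no event
    explains the ball the agent emits `stay` and re-recognizes over the
    whole event alphabet at every phase.  Recognized events accumulate
    Dirichlet counts (sharper likelihoods, rising ELBO) when ``accumulate``
    is on.
    """
    factor = model.temporal_factor
    n_top = model.top.n_states
    H, W = env.H, env.W
    alpha_sz = float(env.n_cell_states)
    events = np.stack([expand_top(model, np.array([e])) for e in range(n_top)])
    events = events.reshape(n_top, factor, -1)  # (n_top, factor, n_cells)
    reach = inductive_reachability(model.top.B, rewarded)
    precluded = reach.precluded()
    trans = normalize(model.top.B.sum(axis=2) + floor)  # successor | event
    rng = np.random.default_rng(seed)

    def paddle_x_of(codes) -> int:
        # the ball may overdraw one paddle cell, so use each part's code
        # (left/mid/right) to recover the leftmost paddle cell
        row = np.asarray(codes).reshape(H, W)[0]
        hit = np.flatnonzero((row >= 2) & (row <= 4))
        if not hit.size:
            return (W - env.PADDLE) // 2
        i = int(hit[0])
        return int(np.clip(i - (int(row[i]) - 2), 0, W - env.PADDLE))

    visit = np.ones(n_top)  # Dirichlet count per event likelihood column
    if start_event is None:
        start_event = int(model.top.sequence[0])
    log_b = np.full(n_top, -PRECLUSION_COST)
    log_b[start_event] = 0.0
    lost = False

    frames = np.zeros((n_steps, env.n_cells), dtype=np.int64)
    actions = np.zeros(n_steps, dtype=np.int64)
    rewards = np.zeros(n_steps, dtype=bool)
    misses = np.zeros(n_steps, dtype=bool)
    elbo = np.zeros(n_steps)
    log = PlayLog(frames, actions, rewards, misses, elbo)

    n_cells = env.n_cells

    def paddle_row(px: int) -> np.ndarray:
        row = np.zeros(W, dtype=np.int64)
        row[px : px + env.PADDLE] = (2, 3, 4)
        return row

    def paddle_after(a) -> np.ndarray:
        return paddle_row(int(np.clip(env.state.paddle_x + a, 0, W - env.PADDLE)))

    # per-cell precision: the paddle (top) row is controllable, so it carries
    # reduced weight during state estimation
    weights = np.ones(n_cells)
    weights[:W] = paddle_precision
    ball_cells = np.arange(W, n_cells)

    confident = True  # some event explains the ball exactly so far this window
    anchored = True  # the last event boundary was recognized
    ball_ok = np.ones(n_top, dtype=bool)  # ball-exact over the current window
    for t in range(n_steps):
        # the event clock is fixed: every level updates on a strict schedule
        # of R child updates per own update, so the phase within an event
        # advances with global time and is never resynchronized
        phase = t % factor
        if confident:
            # act on the most probable event among those that still explain
            # the ball exactly.  Anchored: realize its paddle frame by frame
            # (exact replay of the trained path keeps recognition stable);
            # after a lost stretch, rush instead toward the event's *end*
            # paddle — the intentional target that returns the ball.
            masked = np.where(ball_ok, log_b, -np.inf)
            map_e = int(np.argmax(masked))
            target = events[map_e, phase] if anchored else events[map_e, factor - 1]
            target_px = paddle_x_of(target)
            px = env.state.paddle_x
            dists = np.array(
                [abs(int(np.clip(px + a, 0, W - env.PADDLE)) - target_px) for a in (-1, 0, 1)]
            )
            if sticky_p > 0 and rng.random() < sticky_p:
                action = (-1, 0, 1)[int(rng.choice(3, p=softmax(-dists.astype(float))))]
            else:
                action = (-1, 0, 1)[int(np.argmin(dists))]
        else:
            action = 0  # wait for a recognizable event within the attracting set
        state = env.step(action)
        obs = env.observe()
        frames[t] = obs
        actions[t] = action
        rewards[t] = state.reward
        misses[t] = state.miss
        # likelihood of this frame under every event's floored likelihoods,
        # with the controllable (paddle) row at reduced precision
        match = events[:, phase, :] == obs[None, :]
        w_match = match @ weights
        z = visit + floor * alpha_sz
        ll = w_match * np.log((visit + floor) / z) + (weights.sum() - w_match) * np.log(floor / z)
        log_b = log_b + ll
        ball_ok &= match[:, ball_cells].all(axis=1)
        confident = bool(ball_ok.any())
        map_e = int(np.argmax(np.where(ball_ok, log_b, -np.inf))) if confident else int(np.argmax(log_b))
        elbo[t] = float(ll[map_e]) / weights.sum()
        if phase == factor - 1:  # event boundary
            log_b = log_b - logsumexp(log_b)
            recognized = confident
            anchored = recognized
            log.event_trace.append(map_e if recognized else -1)
            if recognized:
                if accumulate and bool(match[map_e].all()):
                    visit[map_e] += 1.0
                prior = trans[:, map_e].copy()
                prior = np.exp(np.log(prior + 1e-12) - PRECLUSION_COST * precluded)
                log_b = np.log(prior / prior.sum() + 1e-300)
            else:
                log.lost_windows += 1
                log_b = np.zeros(n_top)  # uniform re-recognition
            ball_ok = np.ones(n_top, dtype=bool)
    log.n_hits = int(rewards.sum())
    log.n_misses = int(misses.sum())
    return log
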