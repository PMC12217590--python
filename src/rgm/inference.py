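"""Variational inversion of renormalizing generative models.

Inference follows the separation of timescales built into the hierarchy: a
level updates its beliefs only after its children have completed ``R`` of
their own updates.  Within one segment the renormalized model is a tree
(every child has exactly one parent, and a parent symbol deterministically
fixes its children's initial states and paths), so the upward sweep computes
exact likelihood messages by sum-product; the top level is a Markov chain
over events, inverted by forward filtering with no smoothing across
segments.  Accumulated negative log-evidence is the variational free energy;
its negative is the ELBO.

For single-level path-augmented POMDPs this module also provides

* :func:`exact_posterior` — brute-force-exact marginals via per-path
  forward-backward and a path mixture, and
* :func:`vmp_fixed_point` — the mean-field coordinate-descent scheme whose
  free energy is non-increasing across sweeps (softmax of summed log-domain
  messages, digamma-expected tensors for finite counts).

Observations enter as likelihood vectors per channel and time: one-hot
(precise), uniform (missing or imprecise), or anything in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .frontends import DiscreteObservation
from .model_core import (
    RGModel,
    expected_log,
    normalize,
    softmax,
)

__all__ = [
    "ObservationStream",
    "Posterior",
    "infer",
    "generate",
    "classify",
    "complete",
    "SingleLevelPOMDP",
    "exact_posterior",
    "vmp_fixed_point",
    "vmp_step",
]


@dataclass
class ObservationStream:
    """Per-channel outcome likelihood vectors over time.

    ``messages[c]`` has shape (T, alphabet_c); each row is non-negative and
    sums to 1.  A one-hot row is a precise observation, a uniform row a
    missing or imprecise one.
    """

    messages: list[np.ndarray]

    def __post_init__(self):
        for c, m in enumerate(self.messages):
            if np.any(m < 0):
                raise ValueError(f"negative likelihood in channel {c}")
            if m.size and not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"channel {c} rows must sum to 1")

    @property
    def n_steps(self) -> int:
        return self.messages[0].shape[0] if self.messages else 0

    @classmethod
    def from_codes(cls, obs: DiscreteObservation) -> "ObservationStream":
        msgs = []
        for c in range(obs.codes.shape[1]):
            m = np.zeros((obs.codes.shape[0], int(obs.alphabet[c])))
            m[np.arange(obs.codes.shape[0]), obs.codes[:, c]] = 1.0
            msgs.append(m)
        return cls(msgs)

    def masked(self, channels=None, steps=None) -> "ObservationStream":
        """Copy with the given channels and/or time steps made uniform."""
        msgs = [m.copy() for m in self.messages]
        chans = range(len(msgs)) if channels is None else channels
        for c in chans:
            rows = slice(None) if steps is None else steps
            msgs[c][rows] = 1.0 / msgs[c].shape[1]
        return ObservationStream(msgs)


@dataclass
class Posterior:
    """Posterior expectations and free energy from one model inversion."""

    top: np.ndarray  # (T_top, n_top) filtered event posterior
    level_symbols: list[list[np.ndarray]]  # per level, per group: (T_lvl, n_sym)
    level_paths: list[list[np.ndarray]]  # per level, per group: (T_lvl, n_paths)
    channels: list[np.ndarray]  # per channel: (T0, alphabet) predictive posterior
    F: float  # total variational free energy (nats); -F is the ELBO
    F_levels: list[float]  # per-level accumulated message surprise
    update_counts: list[int] = field(default_factory=list)  # per-level belief updates

    @property
    def elbo(self) -> float:
        return -self.F


def _spatial_log_likelihood(grp, members_msgs, floor):
    """log p(member messages | state) for every state and time.

    ``members_msgs``: list over members of (T, alphabet_m) normalized
    likelihood vectors.  The likelihood mapping is the one-hot expansion of
    ``grp.spatial_states`` softened by the concentration floor.
    """
    n_states = grp.n_states
    if not members_msgs:
        return np.zeros((1, n_states))  # constant group: evidence-free
    T = members_msgs[0].shape[0]
    logL = np.zeros((T, n_states))
    with np.errstate(divide="ignore"):
        for m, lam in enumerate(members_msgs):
            alpha = lam.shape[1]
            gathered = lam[:, grp.spatial_states[:, m]]  # (T, n_states)
            if floor > 0:
                logL += np.log(gathered + floor) - np.log1p(floor * alpha)
            else:
                logL += np.log(gathered)
    return logL


def _upward(model: RGModel, stream: ObservationStream, floor: float):
    """Compute per-level symbol log-likelihood messages, bottom-up."""
    if len(stream.messages) != len(model.alphabet):
        raise ValueError(
            f"observation has {len(stream.messages)} channels, model expects {len(model.alphabet)}"
        )
    for c, m in enumerate(stream.messages):
        if m.shape[1] != model.alphabet[c]:
            raise ValueError(f"channel {c} alphabet {m.shape[1]} != model {model.alphabet[c]}")
    child_msgs = stream.messages
    logL_syms: list[list[np.ndarray]] = []
    shifts: list[float] = []
    counts: list[int] = []
    for level in model.levels:
        level_logL = []
        T_in = child_msgs[0].shape[0] if child_msgs else 0
        if T_in % level.R:
            raise ValueError(
                f"sequence length {T_in} not divisible by temporal factor R={level.R}"
            )
        next_msgs = []
        shift = 0.0
        for g, grp in enumerate(level.groups):
            members = [child_msgs[c] for c in level.group_children[g]]
            logL_state = _spatial_log_likelihood(grp, members, floor)
            if logL_state.shape[0] == 1 and T_in > 1:
                logL_state = np.broadcast_to(logL_state, (T_in, grp.n_states))
            T_out = T_in // level.R
            seg = grp.segments  # (n_sym, R)
            logL = np.zeros((T_out, grp.n_symbols))
            for r in range(level.R):
                logL += logL_state[r :: level.R][:T_out][:, seg[:, r]]
            level_logL.append(logL)
            z = logsumexp(logL, axis=1, keepdims=True)
            finite = np.isfinite(z).ravel()
            shift += float(z[finite].sum())
            with np.errstate(invalid="ignore"):
                msg = np.exp(logL - np.where(np.isfinite(z), z, 0.0))
            msg[~finite] = 1.0 / grp.n_symbols  # zero-evidence step: treat as missing
            next_msgs.append(msg)
        child_msgs = next_msgs
        logL_syms.append(level_logL)
        shifts.append(-shift)
        counts.append(T_in)
    return logL_syms, child_msgs, shifts, counts


def _top_filter(model: RGModel, top_msg: np.ndarray, floor: float):
    """Forward filtering over the top event chain; returns posterior and F."""
    with np.errstate(divide="ignore"):
        logL = np.log(top_msg)
    T, n = logL.shape
    logD = np.log(normalize(model.top.D + max(floor, 1e-12)))
    post = np.zeros((T, n))
    if model.temporal and T > 1:
        trans = normalize(model.top.B.sum(axis=2) + floor)
        with np.errstate(divide="ignore"):
            logT = np.log(trans)
        log_alpha = logD + logL[0]
        F = -logsumexp(log_alpha)
        post[0] = softmax(log_alpha)
        for t in range(1, T):
            pred = logsumexp(logT + np.log(post[t - 1] + 1e-300)[None, :], axis=1)
            log_alpha = pred + logL[t]
            z = logsumexp(log_alpha)
            if not np.isfinite(z):
                raise FloatingPointError(
                    "observation has zero probability under the model (floor the counts?)"
                )
            F -= z
            post[t] = softmax(log_alpha)
    else:
        F = 0.0
        for t in range(T):
            z = logsumexp(logD + logL[t])
            if not np.isfinite(z):
                raise FloatingPointError(
                    "observation has zero probability under the model (floor the counts?)"
                )
            F -= z
            post[t] = softmax(logD + logL[t])
    return post, float(F)


def infer(model: RGModel, obs, floor: float | None = None) -> Posterior:
    """Invert the model on an observation stream (exact within segments).

    ``obs`` is an :class:`ObservationStream` or a :class:`DiscreteObservation`
    (taken as precise).  ``floor`` softens the one-hot likelihood mappings;
    the default 0 performs exact lossless recognition and raises if the
    stream is inconsistent with the training data.
    """
    if isinstance(obs, DiscreteObservation):
        obs = ObservationStream.from_codes(obs)
    floor = 0.0 if floor is None else float(floor)
    logL_syms, top_msgs, shifts, counts = _upward(model, obs, floor)
    top_post, F_top = _top_filter(model, top_msgs[0], floor)
    # F decomposition: the per-level shifts are message normalizations already
    # contained in the top chain's evidence; report them as per-level surprise.
    level_symbols, level_paths, channel_post = _downward(
        model, top_post, logL_syms, obs, floor
    )
    return Posterior(
        top=top_post,
        level_symbols=level_symbols,
        level_paths=level_paths,
        channels=channel_post,
        F=F_top + sum(shifts),
        F_levels=shifts,
        update_counts=counts,
    )


def _downward(model, top_post, logL_syms, stream, floor):
    """Distribute the top posterior down the tree, fusing cached evidence."""
    level_symbols: list[list[np.ndarray]] = [None] * len(model.levels)
    level_paths: list[list[np.ndarray]] = [None] * len(model.levels)
    q_syms = [top_post]  # per group at the current (highest) level
    for li in range(len(model.levels) - 1, -1, -1):
        level = model.levels[li]
        level_symbols[li] = [q.copy() for q in q_syms]
        level_paths[li] = []
        child_q: dict[int, np.ndarray] = {}
        for g, grp in enumerate(level.groups):
            q = q_syms[g]  # (T_lvl, n_sym)
            n_paths = grp.B.shape[2]
            qp = np.zeros((q.shape[0], n_paths))
            np.add.at(qp.T, grp.path_index, q.T)
            level_paths[li].append(qp)
            # symbols -> states at the finer timescale
            T_fine = q.shape[0] * level.R
            q_state = np.zeros((T_fine, grp.n_states))
            for r in range(level.R):
                state_of = grp.segments[:, r]
                contrib = np.zeros((q.shape[0], grp.n_states))
                np.add.at(contrib.T, state_of, q.T)
                q_state[r :: level.R] = contrib
            # states -> per-member child symbol prior, fused with child evidence
            for m, c in enumerate(level.group_children[g]):
                child_states = grp.spatial_states[:, m]
                if li == 0:
                    alpha = int(model.alphabet[c])
                    prior = np.zeros((T_fine, alpha))
                    np.add.at(prior.T, child_states, q_state.T)
                    if floor > 0:
                        prior = (prior + floor * q_state.sum(axis=1, keepdims=True)) / (
                            1 + floor * alpha
                        )
                    post = prior * stream.messages[c]
                    z = post.sum(axis=1, keepdims=True)
                    post = np.where(z > 0, post / np.where(z > 0, z, 1.0), prior)
                    child_q[c] = post
                else:
                    sub = model.levels[li - 1].groups[c]
                    prior = np.zeros((T_fine, sub.n_symbols))
                    np.add.at(prior.T, child_states, q_state.T)
                    with np.errstate(divide="ignore"):
                        logpost = np.log(prior + (floor if floor > 0 else 1e-300))
                    logpost += logL_syms[li - 1][c]
                    child_q[c] = softmax(logpost, axis=1)
        q_syms = [child_q[c] for c in sorted(child_q)]
    channel_post = q_syms
    return level_symbols, level_paths, channel_post


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def expand_top(model: RGModel, top_syms: np.ndarray) -> np.ndarray:
    """Deterministic top-down expansion of top symbols to level-0 codes."""
    syms = np.asarray(top_syms, dtype=np.int64)[:, None]  # (T, 1 group)
    for level in reversed(model.levels):
        T = syms.shape[0]
        n_children = sum(len(c) for c in level.group_children)
        out = np.zeros((T * level.R, n_children), dtype=np.int64)
        for g, grp in enumerate(level.groups):
            states = grp.segments[syms[:, g]].reshape(-1)  # (T*R,)
            if grp.spatial_states.shape[1]:
                out[:, level.group_children[g]] = grp.spatial_states[states]
        syms = out
    return syms


def generate(
    model: RGModel,
    top_state: int,
    horizon: int,
    top_path: int | None = None,
    seed: int | None = None,
) -> DiscreteObservation:
    """Generate ``horizon`` level-0 steps from a top state (and optional path).

    The top event sequence starts at ``top_state`` and follows the learned
    transition tensor: the slice ``top_path`` if given, otherwise the
    count-weighted choice among path slices with support (deterministic when
    only one transition was ever observed, seeded sampling otherwise).
    """
    factor = model.temporal_factor
    if horizon % factor:
        raise ValueError(f"horizon {horizon} not a multiple of the temporal factor {factor}")
    T_top = horizon // factor
    rng = np.random.default_rng(seed)
    seq = [int(top_state)]
    if model.temporal:
        B = model.top.B
        for _ in range(T_top - 1):
            s = seq[-1]
            if top_path is not None:
                col = B[:, s, top_path]
            else:
                col = B[:, s, :].sum(axis=1)
            if col.sum() <= 0:  # never-visited source: fall back to the prior
                col = model.top.D + 1e-12
            p = col / col.sum()
            if np.count_nonzero(p) == 1:
                seq.append(int(np.argmax(p)))
            else:
                seq.append(int(rng.choice(p.size, p=p)))
    else:
        seq = seq * T_top
    codes = expand_top(model, np.asarray(seq))
    grid = model.partition.grid_shape if model.partition is not None else (1, len(model.levels[0].group_children))
    return DiscreteObservation(
        codes=codes,
        alphabet=model.alphabet.copy(),
        channel_groups=model.levels[0].group_children,
        grid_shape=grid,
    )


# ---------------------------------------------------------------------------
# Classification and completion
# ---------------------------------------------------------------------------


def classify(model: RGModel, obs, floor: float | None = None, occam_threshold: float | None = None):
    """Class posterior and ELBO for each exemplar in ``obs``.

    Requires a label level.  Returns ``(post, elbo)`` with shapes (T, K) and
    (T,); when ``occam_threshold`` is given, exemplars whose ELBO falls below
    it are flagged unclassifiable (their posterior row is set to uniform).
    """
    if model.label is None:
        raise ValueError("model has no label level")
    if isinstance(obs, DiscreteObservation):
        obs = ObservationStream.from_codes(obs)
    floor = model.floor if floor is None else float(floor)
    _, top_msgs, shifts, _ = _upward(model, obs, floor)
    with np.errstate(divide="ignore"):
        logL = np.log(top_msgs[0])  # (T, n_top), normalized per row
    # undo the per-step normalization so the ELBO is a true log marginal
    # (shifts sum the normalizations of every level including the last)
    like = normalize(model.label.counts + floor)  # (n_top, K)
    K = model.label.n_classes
    log_prior = -np.log(K)
    log_joint = logsumexp(logL[:, :, None] + np.log(like)[None, :, :], axis=1) + log_prior
    per_step_shift = np.zeros(logL.shape[0])
    # reconstruct per-exemplar evidence: total shifts were accumulated over all
    # steps; recompute exactly per exemplar instead.
    post = softmax(log_joint, axis=1)
    elbo = logsumexp(log_joint, axis=1) - _per_step_surprise(model, obs, floor)
    if occam_threshold is not None:
        post = post.copy()
        post[elbo < occam_threshold] = 1.0 / K
    return post, elbo


def _per_step_surprise(model: RGModel, stream: ObservationStream, floor: float) -> np.ndarray:
    """Per-top-step negative log message normalization (for exemplar ELBOs)."""
    child_msgs = stream.messages
    T0 = stream.n_steps
    factor = model.temporal_factor
    surprise = np.zeros(T0 // factor if factor else 0)
    for level in model.levels:
        T_in = child_msgs[0].shape[0]
        next_msgs = []
        stride = T0 // T_in if T_in else 1
        for g, grp in enumerate(level.groups):
            members = [child_msgs[c] for c in level.group_children[g]]
            logL_state = _spatial_log_likelihood(grp, members, floor)
            if logL_state.shape[0] == 1 and T_in > 1:
                logL_state = np.broadcast_to(logL_state, (T_in, grp.n_states))
            T_out = T_in // level.R
            logL = np.zeros((T_out, grp.n_symbols))
            for r in range(level.R):
                logL += logL_state[r :: level.R][:T_out][:, grp.segments[:, r]]
            z = logsumexp(logL, axis=1, keepdims=True)
            steps_per_top = surprise.size and T_out // surprise.size
            if steps_per_top:
                surprise -= z.ravel().reshape(surprise.size, steps_per_top).sum(axis=1)
            with np.errstate(invalid="ignore"):
                msg = np.exp(logL - np.where(np.isfinite(z), z, 0.0))
            msg[~np.isfinite(z).ravel()] = 1.0 / grp.n_symbols
            next_msgs.append(msg)
        child_msgs = next_msgs
    return surprise


def complete(model: RGModel, partial_obs, floor: float | None = None):
    """Posterior predictive over every channel given a partially observed stream.

    Missing groups or frames are marked by uniform likelihood rows.  Returns
    ``(posterior, codes)`` where ``codes`` is the argmax channel prediction
    (T0, n_channels).  An all-missing stream returns the prior predictive.
    """
    if isinstance(partial_obs, DiscreteObservation):
        partial_obs = ObservationStream.from_codes(partial_obs)
    floor = model.floor if floor is None else float(floor)
    post = infer(model, partial_obs, floor=floor)
    codes = np.stack([np.argmax(ch, axis=1) for ch in post.channels], axis=1)
    return post, codes


# ---------------------------------------------------------------------------
# Single-level POMDP: exact inversion and mean-field fixed-point iteration
# ---------------------------------------------------------------------------


@dataclass
class SingleLevelPOMDP:
    """A path-augmented POMDP: likelihoods A, transitions B, priors D and E."""

    A: list[np.ndarray]  # per modality: (n_out, n_states) counts
    B: np.ndarray  # (n_states, n_states, n_paths) counts
    D: np.ndarray  # (n_states,) counts
    E: np.ndarray  # (n_paths,) counts

    @property
    def n_states(self) -> int:
        return self.D.size

    @property
    def n_paths(self) -> int:
        return self.E.size


def exact_posterior(m: SingleLevelPOMDP, obs: list[np.ndarray]):
    """Exact marginals by per-path forward-backward plus a path mixture.

    ``obs[g]`` is (T, n_out_g).  Returns ``(qs, qu, F)`` with qs (T, n_states),
    qu (n_paths,), and F the exact negative log evidence.
    """
    T = obs[0].shape[0]
    A = [normalize(a) for a in m.A]
    D = normalize(m.D)
    E = normalize(m.E)
    logL = np.zeros((T, m.n_states))
    with np.errstate(divide="ignore"):
        for g, a in enumerate(A):
            logL += np.log(np.einsum("tg,gs->ts", obs[g], a) + 1e-300)
    L = np.exp(logL)
    evid = np.zeros(m.n_paths)
    marg = np.zeros((m.n_paths, T, m.n_states))
    for u in range(m.n_paths):
        P = normalize(m.B[:, :, u])
        alpha = np.zeros((T, m.n_states))
        c = np.zeros(T)
        a0 = D * L[0]
        c[0] = a0.sum()
        alpha[0] = a0 / c[0] if c[0] > 0 else a0
        for t in range(1, T):
            at = (P @ alpha[t - 1]) * L[t]
            c[t] = at.sum()
            alpha[t] = at / c[t] if c[t] > 0 else at
        beta = np.ones((T, m.n_states))
        for t in range(T - 2, -1, -1):
            b = P.T @ (beta[t + 1] * L[t + 1])
            s = b.sum()
            beta[t] = b / s if s > 0 else b
        g = alpha * beta
        z = g.sum(axis=1, keepdims=True)
        marg[u] = np.where(z > 0, g / np.where(z > 0, z, 1.0), 1.0 / m.n_states)
        evid[u] = np.prod(c) if np.all(c > 0) else 0.0
    joint = E * evid
    Z = joint.sum()
    if Z <= 0:
        raise FloatingPointError("zero evidence under every path")
    qu = joint / Z
    qs = np.einsum("u,uts->ts", qu, marg)
    return qs, qu, float(-np.log(Z))


def _mean_field_F(lnA_terms, lnB, lnD, lnE, qs, qu):
    T = qs.shape[0]
    F = float(np.sum(qs * np.log(qs + 1e-300)) + np.sum(qu * np.log(qu + 1e-300)))
    F -= float(qs[0] @ lnD + qu @ lnE)
    F -= float(np.sum(qs * lnA_terms))
    for t in range(T - 1):
        F -= float(np.einsum("u,iju,j,i->", qu, lnB, qs[t], qs[t + 1]))
    return F


def vmp_fixed_point(
    m: SingleLevelPOMDP,
    obs: list[np.ndarray],
    tol: float = 1e-4,
    max_sweeps: int = 16,
    expected: bool = True,
):
    """Mean-field coordinate descent on variational free energy.

    Expectations over states and the path are the softmax of summed
    log-domain messages (ascending likelihood, forward/backward transition,
    and prior messages).  With ``expected=True`` the tensors enter through
    their digamma expected-logs (finite Dirichlet counts); otherwise through
    logs of the normalized tensors (the infinite-count limit).  Free energy
    is evaluated after every sweep and is non-increasing; iteration stops
    when it changes by less than ``tol`` nats or after ``max_sweeps``.

    Returns ``(qs, qu, F_trace)``.
    """
    T = obs[0].shape[0]

    def elog(t):
        return expected_log(t) if expected else np.log(normalize(np.asarray(t, float)) + 1e-300)

    lnA = [elog(a) for a in m.A]
    lnB = elog(m.B)  # (n, n, u): outcome axis 0 = successor state
    lnD = elog(m.D)
    lnE = elog(m.E)
    lnA_terms = np.zeros((T, m.n_states))
    for g, la in enumerate(lnA):
        lnA_terms += obs[g] @ la
    if not np.all(np.isfinite(lnA_terms)):
        raise FloatingPointError("NaN/inf in ascending messages")
    qs = np.full((T, m.n_states), 1.0 / m.n_states)
    qu = np.full(m.n_paths, 1.0 / m.n_paths)
    F_trace = [_mean_field_F(lnA_terms, lnB, lnD, lnE, qs, qu)]
    for _ in range(max_sweeps):
        for t in range(T):
            msg = lnA_terms[t].copy()
            if t == 0:
                msg += lnD
            if t > 0:
                msg += np.einsum("u,iju,j->i", qu, lnB, qs[t - 1])
            if t < T - 1:
                msg += np.einsum("u,iju,i->j", qu, lnB, qs[t + 1])
            qs[t] = softmax(msg)
        lu = lnE.copy()
        for t in range(T - 1):
            lu += np.einsum("iju,j,i->u", lnB, qs[t], qs[t + 1])
        qu = softmax(lu)
        F_trace.append(_mean_field_F(lnA_terms, lnB, lnD, lnE, qs, qu))
        if not np.isfinite(F_trace[-1]):
            raise FloatingPointError("free energy diverged during fixed-point iteration")
        if abs(F_trace[-1] - F_trace[-2]) < tol:
            break
    return qs, qu, np.asarray(F_trace)


def vmp_step(m: SingleLevelPOMDP, obs: list[np.ndarray], qs, qu, expected: bool = True):
    """One coordinate-descent sweep; thin wrapper used by schedulers/tests."""
    qs2, qu2, F = vmp_fixed_point(m, obs, tol=0.0, max_sweeps=1, expected=expected)
    return qs2, qu2, float(F[-1])
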