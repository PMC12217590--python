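"""Fast structure learning: self-assembly of an RGM by coarse-graining.

A renormalizing generative model is grown from a discrete observation
sequence without any gradient-based training.  Each ascent applies one
renormalization-group operator:

1. *spatial* blocking — nearest-neighbour child groups are merged and every
   unique combination of their symbols becomes one state of the merged group
   (a one-hot likelihood column, appended in order of first appearance);
2. *temporal* blocking — the state sequence is cut into non-overlapping
   segments of length ``R``; every unique segment becomes one super-symbol,
   equivalently an (initial state, path) pair, and the observed transitions
   are recorded in the group's ``B`` tensor, one path slice per distinct
   dynamics.

Repeating until a single group remains yields a hierarchy whose top-down
generation reproduces the training sequence exactly: inversion of the learned
model is lossless compression of the training data.

Optionally, model growth can be gated by the change in free energy plus
expected free energy (a new latent cause is added only when the augmented
model is the better explanation), and a supervision level can be stacked on
top to map class labels to the exemplar states they generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frontends import DiscreteObservation
from .model_core import (
    DEFAULT_FLOOR,
    GroupLevel,
    LabelLevel,
    ModelLevel,
    RGModel,
    TopLevel,
    mutual_information,
    normalize,
)

__all__ = [
    "unique_state_columns",
    "one_hot_likelihoods",
    "unique_transitions",
    "segment_paths",
    "coarse_grain",
    "quad_merge",
    "fast_structure_learn",
    "add_label_level",
    "GrowthDecision",
    "gate_growth",
]


def unique_state_columns(codes: np.ndarray):
    """Unique symbol combinations, one per state, in order of first appearance.

    ``codes`` is (T, n_members); returns ``(states, index_seq)`` where
    ``states[k]`` is the member-symbol combination of state k and
    ``index_seq[t]`` maps each time step to its state.  The one-hot likelihood
    columns of the spec are the one-hot expansion of ``states``
    (:func:`one_hot_likelihoods`).
    """
    codes = np.atleast_2d(np.asarray(codes))
    if codes.shape[0] == 0:
        raise ValueError("empty observation sequence")
    _, first, inv = np.unique(codes, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")  # first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return codes[np.sort(first)], rank[inv]


def one_hot_likelihoods(states: np.ndarray, alphabet) -> list[np.ndarray]:
    """Per-member one-hot likelihood matrices (alphabet_m x n_states)."""
    states = np.atleast_2d(states)
    out = []
    for m in range(states.shape[1]):
        A = np.zeros((int(alphabet[m]), states.shape[0]))
        A[states[:, m], np.arange(states.shape[0])] = 1.0
        out.append(A)
    return out


def unique_transitions(seq: np.ndarray, n_states: int | None = None) -> np.ndarray:
    """Record observed successor relations in path slices of a B tensor.

    Each distinct successor of a source state occupies a distinct path slice
    (slices filled greedily, in order of first appearance), so every slice is
    one-hot by column over the sources it has seen.  Returns counts of shape
    (n_states, n_states, n_paths).
    """
    seq = np.asarray(seq, dtype=np.int64)
    if seq.size < 2:
        raise ValueError("need an index sequence of length >= 2")
    n = int(n_states if n_states is not None else seq.max() + 1)
    tables: list[np.ndarray] = []  # successor table per path slice, -1 = unset
    counts: list[np.ndarray] = []
    for s, s2 in zip(seq[:-1], seq[1:]):
        for tab, cnt in zip(tables, counts):
            if tab[s] == s2:
                cnt[s2, s] += 1
                break
            if tab[s] == -1:
                tab[s] = s2
                cnt[s2, s] += 1
                break
        else:
            tab = np.full(n, -1, dtype=np.int64)
            cnt = np.zeros((n, n))
            tab[s] = s2
            cnt[s2, s] = 1
            tables.append(tab)
            counts.append(cnt)
    return np.stack(counts, axis=2) if counts else np.zeros((n, n, 1))


def segment_paths(segments: np.ndarray, n_states: int):
    """Assign a path slice to every unique segment; build the B tensor.

    A path is a successor table shared across initial states; a segment fits a
    path if none of its transitions conflicts with what that path has already
    committed to.  Distinct segments with the same initial state always land
    on distinct paths, so (initial state, path) identifies the segment.
    Returns ``(path_index, B)``.
    """
    segments = np.atleast_2d(segments)
    R = segments.shape[1]
    tables: list[np.ndarray] = []
    path_index = np.zeros(segments.shape[0], dtype=np.int64)
    for j, seg in enumerate(segments):
        trans = list(zip(seg[:-1], seg[1:]))
        for u, tab in enumerate(tables):
            if all(tab[s] in (-1, s2) for s, s2 in trans):
                path_index[j] = u
                break
        else:
            tables.append(np.full(n_states, -1, dtype=np.int64))
            path_index[j] = len(tables) - 1
        tab = tables[path_index[j]]
        for s, s2 in trans:
            tab[s] = s2
    n_paths = max(len(tables), 1)
    B = np.zeros((n_states, n_states, n_paths))
    for j, seg in enumerate(segments):
        for s, s2 in zip(seg[:-1], seg[1:]):
            B[s2, s, path_index[j]] += 1
    return path_index, B


def coarse_grain(codes: np.ndarray, group_merge: list[list[int]], R: int):
    """One renormalization: spatial merge then temporal segment grouping.

    ``codes`` is the (T, n_child_groups) symbol sequence at the current level;
    ``group_merge`` partitions child groups among the merged groups.  Returns
    ``(new_codes, level)`` where ``new_codes`` is (T // R, n_groups) and
    ``level`` the fitted :class:`ModelLevel`.  A trailing partial segment is
    dropped with a warning rather than padded.
    """
    codes = np.asarray(codes)
    T = codes.shape[0]
    if R < 1:
        raise ValueError("temporal factor R must be >= 1")
    if T % R:
        warnings.warn(f"dropping trailing partial segment ({T % R} of {T} steps)")
        codes = codes[: (T // R) * R]
        T = codes.shape[0]
    if T == 0:
        raise ValueError("sequence shorter than one segment")
    groups = []
    new_cols = []
    for members in group_merge:
        if members:
            states, sseq = unique_state_columns(codes[:, members])
        else:  # constant group owning no channels: one implicit state
            states = np.zeros((1, 0), dtype=np.int64)
            sseq = np.zeros(T, dtype=np.int64)
        n_states = states.shape[0]
        seg = sseq.reshape(T // R, R)
        symbols, symbol_seq = unique_state_columns(seg)
        path_index, B = segment_paths(symbols, n_states)
        D = np.bincount(symbols[:, 0], minlength=n_states).astype(float)
        E = np.bincount(path_index, minlength=B.shape[2]).astype(float)
        groups.append(
            GroupLevel(
                spatial_states=states,
                segments=symbols,
                init_index=symbols[:, 0].copy(),
                path_index=path_index,
                B=B,
                D=D,
                E=E,
            )
        )
        new_cols.append(symbol_seq)
    level = ModelLevel(group_children=[list(m) for m in group_merge], R=R, groups=groups)
    return np.stack(new_cols, axis=1), level


def quad_merge(grid_shape: tuple[int, int]) -> tuple[list[list[int]], tuple[int, int]]:
    """Merge a (gh, gw) row-major grid of groups into 2x2 super-groups.

    Odd or unit dimensions collapse the remainder into the last super-group
    row/column; a grid that is already 1x1 merges everything into one group.
    """
    gh, gw = grid_shape
    if gh * gw == 1:
        return [[0]], (1, 1)
    nh, nw = max(gh // 2, 1), max(gw // 2, 1)
    merge = [[] for _ in range(nh * nw)]
    for g in range(gh * gw):
        y, x = divmod(g, gw)
        py, px = min(y // 2, nh - 1), min(x // 2, nw - 1)
        merge[py * nw + px].append(g)
    return merge, (nh, nw)


def fast_structure_learn(
    obs: DiscreteObservation,
    R_schedule: list[int],
    merge_schedule: list[list[list[int]]] | None = None,
    temporal: bool = True,
    floor: float = DEFAULT_FLOOR,
) -> RGModel:
    """Self-assemble an RGM from a discrete observation sequence.

    ``R_schedule[i]`` is the temporal grouping of ascent i; the first ascent
    always merges the observation channels into their spatial groups
    (``obs.channel_groups``), subsequent ascents follow ``merge_schedule`` or,
    by default, 2x2 nearest-neighbour grid merges until a single group
    remains.  With ``temporal=False`` (independent exemplars, e.g. static
    images) every R must be 1 and no transitions are recorded at the top.
    """
    if not temporal and any(r != 1 for r in R_schedule):
        raise ValueError("exemplar (non-temporal) models require R == 1 at every ascent")
    codes = obs.codes
    if codes.shape[0] == 0:
        raise ValueError("empty observation sequence")

    merges: list[list[list[int]]] = [list(obs.channel_groups)]
    grid = obs.grid_shape
    if merge_schedule is not None:
        merges += [list(m) for m in merge_schedule]
        if len(merges) != len(R_schedule):
            raise ValueError(
                f"inconsistent schedules: {len(merges)} merges vs {len(R_schedule)} temporal factors"
            )
    else:
        while len(merges) < len(R_schedule):
            m, grid = quad_merge(grid)
            merges.append(m)
    if len(merges) != len(R_schedule):
        raise ValueError("merge and R schedules have different lengths")

    levels = []
    for merge, R in zip(merges, R_schedule):
        codes, level = coarse_grain(codes, merge, R)
        levels.append(level)
    if codes.shape[1] != 1:
        raise ValueError(
            f"schedule ended with {codes.shape[1]} groups; must renormalize to a single group"
        )
    top_seq = codes[:, 0]
    n_top = int(top_seq.max()) + 1
    if temporal and top_seq.size >= 2:
        B = unique_transitions(top_seq, n_top)
        D = np.zeros(n_top)
        D[top_seq[0]] = 1.0
    else:
        B = np.zeros((n_top, n_top, 1))
        D = np.bincount(top_seq, minlength=n_top).astype(float)
    model = RGModel(
        alphabet=obs.alphabet.copy(),
        levels=levels,
        top=TopLevel(n_states=n_top, B=B, D=D, sequence=top_seq.copy()),
        temporal=temporal,
        floor=floor,
    )
    model.consistency_check()
    return model


def add_label_level(model: RGModel, labels) -> RGModel:
    """Stack a supervision level mapping classes to exemplar states.

    ``labels`` gives one categorical label per training exemplar (per entry of
    the top training sequence); the likelihood column for class k spreads over
    the top states observed with label k.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != model.top.sequence.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {model.top.sequence.shape[0]} training exemplars"
        )
    n_classes = int(labels.max()) + 1
    counts = np.zeros((model.top.n_states, n_classes))
    for s, k in zip(model.top.sequence, labels):
        counts[s, k] += 1.0
    model.label = LabelLevel(counts=counts, n_classes=n_classes)
    return model


@dataclass
class GrowthDecision:
    """Outcome of the grow-or-not comparison between parent and augmented model."""

    delta_F: float  # accuracy gain of the augmented model (nats)
    delta_G: float  # expected-free-energy gain (mutual-information gain, nats)
    accepted: bool


def gate_growth(
    candidate_column: np.ndarray,
    a: np.ndarray,
    obs: np.ndarray,
    floor: float = DEFAULT_FLOOR,
) -> GrowthDecision:
    """Decide whether to add a new latent cause for observation ``obs``.

    The parent model has likelihood counts ``a`` (outcomes x states); the
    augmented model appends ``candidate_column`` (a one-hot outcome vector) as
    a new state.  The decision combines the accuracy gain of the best
    explanation, ``delta_F = max_s ln p(o|s, m') - max_s ln p(o|s, m)``, with
    the information gain ``delta_G = MI(a') - MI(a)`` of the floored counts:
    the new cause is accepted iff ``delta_F + delta_G > 0``.  An observation
    already explained exactly by an existing column yields no accuracy gain
    and a complexity (mutual-information) cost, so it is rejected.
    """
    a = np.asarray(a, dtype=float)
    cand = np.asarray(candidate_column, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if not np.isclose(cand.sum(), 1.0):
        raise ValueError("candidate column must be normalized")
    a_aug = np.concatenate([a, cand[:, None]], axis=1)
    logp = np.log(normalize(a + floor))
    logp_aug = np.log(normalize(a_aug + floor))
    delta_F = float((o @ logp_aug).max() - (o @ logp).max())
    delta_G = mutual_information(a_aug + floor) - mutual_information(a + floor)
    return GrowthDecision(delta_F=delta_F, delta_G=delta_G, accepted=delta_F + delta_G > 0)
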