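"""Active learning of Dirichlet likelihoods and Bayesian model reduction.

Likelihood counts are not updated unconditionally: each candidate update is
treated as an action whose prior probability follows the expected free energy
of the parameters with and without it, ``P(u) = softmax(-alpha * G(a|u))``.
The parameter expected free energy is the negative mutual information the
counts encode minus the expected preference cost, so gated accumulation is a
Maxwell's-demon-like filter that admits only information-increasing updates.
Committing with probability mass ``p_accept`` yields the Bayesian model
average ``a <- a + p_accept * delta`` ; as the precision ``alpha`` grows the
average tends to all-or-none Bayesian model selection.

Bayesian model reduction scores simpler priors post hoc from the fitted
posterior counts using log-beta algebra alone, without revisiting the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import infer
from .model_core import (
    RGModel,
    dirichlet_log_beta,
    mutual_information,
    mutual_information_counts,
    normalize,
    softmax,
)

__all__ = [
    "parameter_efe",
    "parameter_efe_counts",
    "UpdateProposal",
    "propose_update",
    "active_learn",
    "learn_transitions",
    "ReductionQuery",
    "bmr_delta_f",
]


def _expected_cost(a: np.ndarray, c: np.ndarray | None) -> float:
    """Expected preference cost, zero under uniform preferences.

    Preferences enter as log-probabilities relative to the uniform baseline,
    ``ln(K c_o / sum c)``, expected under the outcome marginal of the joint
    the counts encode.  A uniform ``c`` therefore contributes exactly zero.
    """
    if c is None:
        return 0.0
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float).ravel()
    if c.size != a.shape[0]:
        raise ValueError(f"preference vector length {c.size} != outcome count {a.shape[0]}")
    if np.any(c <= 0):
        raise ValueError("preference counts must be positive")
    m = a.reshape(a.shape[0], -1)
    q_o = m.sum(axis=1)
    q_o = q_o / q_o.sum()
    return float(q_o @ (np.log(c / c.sum()) + np.log(c.size)))


def parameter_efe(a, c=None) -> float:
    """Expected free energy of likelihood counts: -MI - expected cost (nats).

    With uniform preferences this is simply the negative mutual information
    between outcomes and the hidden states conditioning them — the quantity
    active learning drives up.
    """
    return -mutual_information(a) - _expected_cost(np.asarray(a, dtype=float), c)


def parameter_efe_counts(a, c=None) -> float:
    """Cross-validation route: MI via the raw-count entropy decomposition."""
    return -mutual_information_counts(a) - _expected_cost(np.asarray(a, dtype=float), c)


@dataclass
class UpdateProposal:
    """A candidate Dirichlet increment and its two-action evaluation."""

    delta: np.ndarray  # outer-product increment, total mass <= 1
    G0: float  # parameter EFE without the update (nats)
    G1: float  # parameter EFE with the update (nats)
    p_accept: float  # probability of committing

    def committed(self, a: np.ndarray) -> np.ndarray:
        """Bayesian model average: a + p_accept * delta (mass-preserving)."""
        return np.asarray(a, dtype=float) + self.p_accept * self.delta


def propose_update(
    a: np.ndarray,
    outcome_vec: np.ndarray,
    parent_expectations: list[np.ndarray] | np.ndarray,
    c=None,
    alpha: float = 512.0,
) -> UpdateProposal:
    """Score the two actions "update or not" for one observation.

    ``delta`` is the outer product of the outcome expectation and the parent
    state expectations (unit total mass for normalized inputs); ``p_accept``
    is the softmax probability of the update action at precision ``alpha``.
    As ``alpha -> inf`` with ``G1 < G0`` the average becomes selection.
    """
    if alpha < 0:
        raise ValueError("precision alpha must be non-negative")
    a = np.asarray(a, dtype=float)
    parts = [np.asarray(outcome_vec, dtype=float).ravel()]
    if isinstance(parent_expectations, np.ndarray) and parent_expectations.ndim == 1:
        parent_expectations = [parent_expectations]
    parts += [np.asarray(p, dtype=float).ravel() for p in parent_expectations]
    delta = parts[0]
    for p in parts[1:]:
        delta = np.multiply.outer(delta, p)
    if delta.shape != a.shape:
        raise ValueError(f"delta shape {delta.shape} != counts shape {a.shape}")
    G0 = parameter_efe(a, c)
    G1 = parameter_efe(a + delta, c)
    p = softmax(np.array([-alpha * G0, -alpha * G1]))
    return UpdateProposal(delta=delta, G0=G0, G1=G1, p_accept=float(p[1]))


def active_learn(
    model: RGModel,
    obs,
    labels=None,
    alpha: float = 512.0,
    c=None,
    tol: float = 1e-3,
    window: int = 32,
    floor: float | None = None,
):
    """Assimilate an exemplar stream with EFE-gated Dirichlet accumulation.

    Each exemplar is inverted under the current model; the proposed update of
    the supervision likelihood (class -> exemplar state; or, without labels,
    the top initial-state counts) is committed only when the committed tensor
    carries more mutual information than before, so the recorded MI trace is
    monotone non-decreasing.  Convergence is declared when the mean MI gain
    over the trailing ``window`` exemplars drops below ``tol`` nats.

    Returns ``(model, mi_trace, elbo_trace)``; traces are per-exemplar, with
    ``mi_trace[t]`` the MI after exemplar t.
    """
    from .frontends import DiscreteObservation
    from .inference import ObservationStream

    floor = model.floor if floor is None else float(floor)
    if isinstance(obs, DiscreteObservation):
        streams = [
            ObservationStream.from_codes(
                DiscreteObservation(
                    codes=obs.codes[[t]],
                    alphabet=obs.alphabet,
                    channel_groups=obs.channel_groups,
                    grid_shape=obs.grid_shape,
                )
            )
            for t in range(obs.codes.shape[0])
        ]
    else:
        streams = list(obs)
    if labels is not None and len(labels) != len(streams):
        raise ValueError("one label per exemplar required")
    if labels is not None and model.label is None:
        raise ValueError("labelled learning requires a label level")
    mi_trace, elbo_trace = [], []
    for t, stream in enumerate(streams):
        post = infer(model, stream, floor=floor)
        s_top = post.top[-1]
        if labels is not None:
            a = model.label.counts
            onehot = np.zeros(model.label.n_classes)
            onehot[int(labels[t])] = 1.0
            prop = propose_update(a, s_top, [onehot], c=c, alpha=alpha)
            committed = prop.committed(a)
            if mutual_information(committed) >= mutual_information(a):
                model.label.counts = committed
        else:
            model.top.D = model.top.D + s_top
        if labels is not None:
            mi_trace.append(mutual_information(model.label.counts))
        else:
            mi_trace.append(mutual_information(model.top.B.sum(axis=2)))
        elbo_trace.append(post.elbo)
        if len(mi_trace) > window and (mi_trace[-1] - mi_trace[-1 - window]) / window < tol:
            break
    return model, np.asarray(mi_trace), np.asarray(elbo_trace)


def learn_transitions(model: RGModel, obs, floor: float | None = None) -> RGModel:
    """Accumulate top-level transition counts from a further exposure.

    The stream is inverted, the MAP event sequence extracted, and each
    observed successor relation added to a consistent path slice of the top
    transition tensor (a new slice when every existing one conflicts).  This
    is how dynamics observed after structure learning — e.g. stochastic
    switches between chaotic orbits — are assimilated.
    """
    floor = model.floor if floor is None else float(floor)
    post = infer(model, obs, floor=floor)
    seq = np.argmax(post.top, axis=1)
    n = model.top.n_states
    B = model.top.B.copy()
    tabs = [np.argmax(B[:, :, u], axis=0) * (B[:, :, u].sum(axis=0) > 0) - (B[:, :, u].sum(axis=0) <= 0) for u in range(B.shape[2])]
    for s, s2 in zip(seq[:-1], seq[1:]):
        placed = False
        for u, tab in enumerate(tabs):
            if tab[s] == s2 or tab[s] < 0:
                B[s2, s, u] += 1.0
                tab[s] = s2
                placed = True
                break
        if not placed:
            newB = np.zeros((n, n, 1))
            newB[s2, s, 0] = 1.0
            B = np.concatenate([B, newB], axis=2)
            tab = np.full(n, -1)
            tab[s] = s2
            tabs.append(tab)
    model.top.B = B
    return model


@dataclass
class ReductionQuery:
    """Counts for one Bayesian model reduction: posterior, prior, reduced prior."""

    posterior: np.ndarray  # fitted counts **a**
    prior: np.ndarray  # original prior counts a
    reduced_prior: np.ndarray  # candidate simpler prior a'


def bmr_delta_f(q: ReductionQuery):
    """Change in free energy for a reduced prior, by log-beta algebra.

    ``delta_F = ln B(post) + ln B(reduced) - ln B(prior) - ln B(reduced_post)``
    with ``reduced_post = post + reduced - prior`` — positive values favour
    the reduced model.  Tensors are treated column-wise (each conditioning
    column is its own Dirichlet) and the column contributions summed.
    Returns ``(delta_F, reduced_posterior)``.
    """
    post = np.asarray(q.posterior, dtype=float)
    prior = np.asarray(q.prior, dtype=float)
    red = np.asarray(q.reduced_prior, dtype=float)
    if post.shape != prior.shape or post.shape != red.shape:
        raise ValueError("posterior, prior and reduced prior must share a shape")
    red_post = post + red - prior
    if np.any(red_post <= 0):
        raise ValueError("reduction infeasible: reduced posterior has non-positive counts")
    cols = post.reshape(post.shape[0], -1)
    pcols = prior.reshape(post.shape[0], -1)
    rcols = red.reshape(post.shape[0], -1)
    rpcols = red_post.reshape(post.shape[0], -1)
    dF = 0.0
    for j in range(cols.shape[1]):
        dF += (
            dirichlet_log_beta(cols[:, j])
            + dirichlet_log_beta(rcols[:, j])
            - dirichlet_log_beta(pcols[:, j])
            - dirichlet_log_beta(rpcols[:, j])
        )
    return float(dF), red_post
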