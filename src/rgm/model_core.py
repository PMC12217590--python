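"""Core data model and elementary tensor operators.

A renormalizing generative model (RGM) is a stack of discrete state-space
levels.  Every probabilistic object in the model is parameterized by a tensor
of non-negative Dirichlet concentration parameters ("counts"); normalizing a
count tensor over its outcome axis yields the categorical distributions the
model actually uses.  This module holds

* the elementary operators (column normalization, digamma expected-log,
  softmax, mutual information) that every other module builds on;
* the containers describing a structure-learned hierarchy (:class:`GroupLevel`,
  :class:`ModelLevel`, :class:`TopLevel`, :class:`RGModel`);
* serialization of a model to a directory with a JSON manifest plus an HDF5
  array file.

Axis convention: the *outcome* axis of a count tensor is always axis 0;
conditioning axes follow.  Indexing is 0-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import h5py
import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "DEFAULT_FLOOR",
    "CountTensor",
    "InvalidCountError",
    "normalize",
    "expected_log",
    "softmax",
    "log_softmax",
    "mutual_information",
    "mutual_information_counts",
    "dirichlet_log_beta",
    "GroupLevel",
    "ModelLevel",
    "TopLevel",
    "LabelLevel",
    "RGModel",
    "save_model",
    "load_model",
]

#: Global default concentration-parameter floor used when likelihoods learned
#: by structure learning are softened before active learning or imprecise
#: inference.  1/32 is the value used for the video pattern-completion
#: experiments; games use 1/128.
DEFAULT_FLOOR = 1.0 / 32.0

FORMAT_VERSION = 1


class InvalidCountError(ValueError):
    """Raised when a count tensor violates non-negativity/positivity."""


def _as_array(t) -> np.ndarray:
    if isinstance(t, CountTensor):
        return t.counts
    return np.asarray(t, dtype=float)


def normalize(t, axis: int = 0) -> np.ndarray:
    """Column-normalize a count tensor over its outcome axis.

    Zero columns map to the uniform distribution: this keeps generation
    defined for states that were never visited during training.

    Raises
    ------
    InvalidCountError
        If any entry is negative.
    """
    a = _as_array(t)
    if np.any(a < 0):
        raise InvalidCountError("count tensor has negative entries")
    total = a.sum(axis=axis, keepdims=True)
    n = a.shape[axis]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, a / np.where(total > 0, total, 1.0), 1.0 / n)
    return out


def expected_log(t, axis: int = 0) -> np.ndarray:
    """Expected log-probability under a Dirichlet with counts ``t``.

    Returns ``psi(a) - psi(sum over outcome axis)`` elementwise, the
    expectation of the log categorical parameters under the implied Dirichlet
    posterior.  Every entry is <= 0.  Columns must be strictly positive;
    callers are expected to apply a concentration floor first.
    """
    a = _as_array(t)
    if np.any(a < 0):
        raise InvalidCountError("count tensor has negative entries")
    total = a.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise InvalidCountError("zero column in expected_log; floor counts first")
    if np.any(a <= 0):
        raise InvalidCountError("non-positive entry in expected_log; floor counts first")
    return digamma(a) - digamma(total)


def softmax(v, axis: int = 0) -> np.ndarray:
    """Normalized exponential, invariant to additive shifts along ``axis``."""
    v = np.asarray(v, dtype=float)
    shifted = v - v.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(v, axis: int = 0) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    shifted = v - v.max(axis=axis, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))


def mutual_information(joint) -> float:
    """Mutual information (nats) of the joint implied by a count tensor.

    Axis 0 is the outcome; all conditioning axes are flattened into a single
    "state" axis.  The counts are normalized over *all* elements to recover the
    joint distribution they encode, and the plug-in MI is returned.  Degenerate
    single-row or single-column joints carry no information and return 0.
    """
    a = _as_array(t=joint)
    if np.any(a < 0):
        raise InvalidCountError("count tensor has negative entries")
    m = a.reshape(a.shape[0], -1)
    if m.shape[0] < 2 or m.shape[1] < 2:
        return 0.0
    total = m.sum()
    if total <= 0:
        return 0.0
    p = m / total
    po = p.sum(axis=1)
    ps = p.sum(axis=0)
    nz = p > 0
    outer = po[:, None] * ps[None, :]
    return float(np.sum(p[nz] * (np.log(p[nz]) - np.log(outer[nz]))))


def mutual_information_counts(joint) -> float:
    """MI via the count/entropy decomposition, for cross-validation.

    Computes ``(sum a ln a - sum a_i. ln a_i. - sum a_.j ln a_.j + A ln A)/A``
    directly from raw counts.  Algebraically identical to
    :func:`mutual_information`; the two follow different floating-point paths
    and serve as mutual checks.
    """
    a = _as_array(t=joint)
    m = a.reshape(a.shape[0], -1)
    if m.shape[0] < 2 or m.shape[1] < 2:
        return 0.0
    total = m.sum()
    if total <= 0:
        return 0.0

    def xlogx(x):
        x = np.asarray(x)
        nz = x > 0
        out = np.zeros_like(x, dtype=float)
        out[nz] = x[nz] * np.log(x[nz])
        return out.sum()

    return float(
        (xlogx(m) - xlogx(m.sum(axis=1)) - xlogx(m.sum(axis=0)) + xlogx(total))
        / total
    )


def dirichlet_log_beta(a) -> float:
    """Log multivariate beta function of a (flattened) count vector."""
    a = np.asarray(a, dtype=float).ravel()
    if np.any(a <= 0):
        raise InvalidCountError("log-beta requires strictly positive counts")
    return float(gammaln(a).sum() - gammaln(a.sum()))


@dataclass
class CountTensor:
    """A non-negative tensor of Dirichlet counts with named axes.

    ``axis_roles[0]`` names the outcome axis; the remaining entries name the
    conditioning axes (states, paths, factors ...).
    """

    counts: np.ndarray
    axis_roles: tuple[str, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise InvalidCountError("count tensor has negative entries")
        if self.axis_roles and len(self.axis_roles) != self.counts.ndim:
            raise ValueError("axis_roles must match tensor rank")

    def normalized(self) -> np.ndarray:
        return normalize(self.counts)

    def expected_log(self) -> np.ndarray:
        return expected_log(self.counts)

    def floored(self, eps: float = DEFAULT_FLOOR) -> "CountTensor":
        return CountTensor(self.counts + eps, self.axis_roles)


# ---------------------------------------------------------------------------
# Structure-learned hierarchy containers
# ---------------------------------------------------------------------------


@dataclass
class GroupLevel:
    """One group's tensors at one level ascent.

    ``spatial_states`` maps this group's *state* indices to the symbols of the
    member child groups: row k lists, for each member, the child symbol the
    k-th state generates.  Its one-hot expansion is the composite likelihood
    (the D-type mapping) from this level's states to child states.

    ``segments`` maps this group's *super-symbol* indices (passed to the level
    above) to the R successive state indices the symbol spans.  Each symbol is
    equivalently the pair (initial state, path): ``init_index`` and
    ``path_index`` record that decomposition, and ``B`` holds the transition
    counts (state x state x path) recorded from the observed segments.
    """

    spatial_states: np.ndarray  # (n_states, n_members) int
    segments: np.ndarray  # (n_symbols, R) int
    init_index: np.ndarray  # (n_symbols,)
    path_index: np.ndarray  # (n_symbols,)
    B: np.ndarray  # (n_states, n_states, n_paths) counts
    D: np.ndarray  # (n_states,) initial-state counts
    E: np.ndarray  # (n_paths,) path counts

    @property
    def n_states(self) -> int:
        return self.spatial_states.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.segments.shape[0]

    @property
    def n_paths(self) -> int:
        return self.B.shape[2] if self.B.size else 1


@dataclass
class ModelLevel:
    """One renormalization: a spatial merge followed by a temporal grouping.

    ``group_children`` partitions the child groups among this level's groups:
    entry g lists the child-group indices that group g generates.  Every child
    appears in exactly one entry (the bipartition of children into initial
    states and paths at the level below is realized by ``GroupLevel.segments``:
    a parent symbol fixes the child's initial state and path).
    """

    group_children: list[list[int]]
    R: int
    groups: list[GroupLevel]

    def __post_init__(self):
        flat = [c for g in self.group_children for c in g]
        if len(flat) != len(set(flat)):
            raise ValueError("group_children is not a partition: duplicated child")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class TopLevel:
    """Single-factor top of the hierarchy: events and their transitions."""

    n_states: int
    B: np.ndarray  # (n, n, n_paths) counts; empty for exemplar models
    D: np.ndarray  # (n,) counts
    sequence: np.ndarray  # training sequence of top symbols


@dataclass
class LabelLevel:
    """Supervision level: likelihood counts mapping classes to top states."""

    counts: np.ndarray  # (n_top_states, n_classes)
    n_classes: int


@dataclass
class RGModel:
    """Ordered stack of levels plus the frontend codec, the serializable artifact.

    ``alphabet`` gives the per-group symbol-alphabet sizes of the level-0
    (observation-adjacent) discrete codes.  ``levels[0]`` renormalizes those
    codes; the last level feeds the single-factor :class:`TopLevel`.
    ``temporal`` distinguishes sequence models (video, games) from exemplar
    models (independent images).
    """

    alphabet: np.ndarray
    levels: list[ModelLevel]
    top: TopLevel
    temporal: bool = True
    label: LabelLevel | None = None
    partition: object | None = None  # frontends.BlockPartition
    codecs: list | None = None  # list[frontends.GroupCodec]
    floor: float = DEFAULT_FLOOR
    preferences: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def temporal_factor(self) -> int:
        """Level-0 time steps spanned by one top-level state."""
        f = 1
        for lv in self.levels:
            f *= lv.R
        return f

    def consistency_check(self) -> None:
        """Verify child-group counts line up between adjacent levels."""
        n_child = len(self.alphabet)
        for i, lv in enumerate(self.levels):
            flat = sorted(c for g in lv.group_children for c in g)
            if flat != list(range(n_child)):
                raise ValueError(f"level {i} children are not a partition of 0..{n_child - 1}")
            n_child = lv.n_groups
        if n_child != 1:
            raise ValueError("top of the hierarchy must be a single group")


# ---------------------------------------------------------------------------
# Serialization: JSON manifest + HDF5 arrays
# ---------------------------------------------------------------------------


class ModelFormatError(IOError):
    """Raised on version mismatch or a corrupted/truncated model container."""


def save_model(m: RGModel, path) -> None:
    """Write ``m`` to directory ``path`` (manifest.json + arrays.h5)."""
    from . import frontends  # local import to avoid a cycle

    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "temporal": m.temporal,
        "floor": m.floor,
        "n_levels": m.n_levels,
        "group_children": [lv.group_children for lv in m.levels],
        "R": [lv.R for lv in m.levels],
        "top_n_states": m.top.n_states,
        "has_label": m.label is not None,
        "n_classes": m.label.n_classes if m.label is not None else 0,
        "has_codecs": m.codecs is not None,
        "has_partition": m.partition is not None,
    }
    if m.partition is not None:
        manifest["partition"] = {
            "image_shape": list(m.partition.image_shape),
            "block_shape": list(m.partition.block_shape),
            "R": m.partition.R,
        }
    (p / "manifest.json").write_text(json.dumps(manifest, indent=1))
    with h5py.File(p / "arrays.h5", "w") as f:
        f.create_dataset("alphabet", data=np.asarray(m.alphabet, dtype=np.int64))
        for i, lv in enumerate(m.levels):
            for g, grp in enumerate(lv.groups):
                pre = f"level{i}/group{g}/"
                f.create_dataset(pre + "spatial_states", data=grp.spatial_states)
                f.create_dataset(pre + "segments", data=grp.segments)
                f.create_dataset(pre + "init_index", data=grp.init_index)
                f.create_dataset(pre + "path_index", data=grp.path_index)
                f.create_dataset(pre + "B", data=grp.B)
                f.create_dataset(pre + "D", data=grp.D)
                f.create_dataset(pre + "E", data=grp.E)
        f.create_dataset("top/B", data=m.top.B)
        f.create_dataset("top/D", data=m.top.D)
        f.create_dataset("top/sequence", data=m.top.sequence)
        if m.label is not None:
            f.create_dataset("label/counts", data=m.label.counts)
        if m.preferences is not None:
            f.create_dataset("preferences", data=m.preferences)
        if m.codecs is not None:
            for g, c in enumerate(m.codecs):
                pre = f"codec{g}/"
                f.create_dataset(pre + "basis", data=c.basis)
                f.create_dataset(pre + "singular_values", data=c.singular_values)
                f.create_dataset(pre + "bin_centers", data=c.bin_centers)
                f.create_dataset(pre + "mean", data=c.mean)
                f[pre + "basis"].attrs["n_levels"] = c.n_levels


def load_model(path) -> RGModel:
    """Load a model saved by :func:`save_model`; inverse is bit-exact."""
    from . import frontends

    p = Path(path)
    mf = p / "manifest.json"
    if not mf.exists():
        raise ModelFormatError(f"no manifest.json under {p}")
    try:
        manifest = json.loads(mf.read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"corrupted manifest: {e}") from e
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(f"unsupported model format version {version!r}")
    try:
        with h5py.File(p / "arrays.h5", "r") as f:
            alphabet = f["alphabet"][()]
            levels = []
            for i in range(manifest["n_levels"]):
                groups = []
                g = 0
                while f"level{i}/group{g}" in f:
                    pre = f[f"level{i}/group{g}"]
                    groups.append(
                        GroupLevel(
                            spatial_states=pre["spatial_states"][()],
                            segments=pre["segments"][()],
                            init_index=pre["init_index"][()],
                            path_index=pre["path_index"][()],
                            B=pre["B"][()],
                            D=pre["D"][()],
                            E=pre["E"][()],
                        )
                    )
                    g += 1
                levels.append(
                    ModelLevel(
                        group_children=manifest["group_children"][i],
                        R=manifest["R"][i],
                        groups=groups,
                    )
                )
            top = TopLevel(
                n_states=manifest["top_n_states"],
                B=f["top/B"][()],
                D=f["top/D"][()],
                sequence=f["top/sequence"][()],
            )
            label = None
            if manifest["has_label"]:
                label = LabelLevel(counts=f["label/counts"][()], n_classes=manifest["n_classes"])
            preferences = f["preferences"][()] if "preferences" in f else None
            codecs = None
            if manifest["has_codecs"]:
                codecs = []
                g = 0
                while f"codec{g}" in f:
                    pre = f[f"codec{g}"]
                    codecs.append(
                        frontends.GroupCodec(
                            basis=pre["basis"][()],
                            singular_values=pre["singular_values"][()],
                            n_levels=int(pre["basis"].attrs["n_levels"]),
                            bin_centers=pre["bin_centers"][()],
                            mean=pre["mean"][()],
                        )
                    )
                    g += 1
    except (OSError, KeyError) as e:
        raise ModelFormatError(f"corrupted or truncated model container: {e}") from e
    partition = None
    if manifest.get("has_partition"):
        pm = manifest["partition"]
        partition = frontends.BlockPartition(
            image_shape=tuple(pm["image_shape"]),
            block_shape=tuple(pm["block_shape"]),
            R=pm["R"],
        )
    return RGModel(
        alphabet=alphabet,
        levels=levels,
        top=top,
        temporal=manifest["temporal"],
        label=label,
        partition=partition,
        codecs=codecs,
        floor=manifest["floor"],
        preferences=preferences,
    )
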