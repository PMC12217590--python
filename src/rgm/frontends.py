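"""Continuous-media frontends: block tiling, SVD codecs, time-frequency maps.

The first renormalization-group operator maps continuous observations to
discrete symbols.  Images (or image sequences) are tessellated into
non-overlapping pixel blocks; each block — concatenating colour channels and
``R`` successive frames into one vector — is projected onto the leading left
singular vectors of its training ensemble, and the resulting singular variates
are quantized to an odd number of levels centred on zero.  Among all rank-k
linear codes, the SVD basis maximizes retained variance (equivalently the
mutual information between block and code under a Gaussian sample
distribution), which is why it is the canonical blocking transformation here.

Audio uses a Morlet-style filterbank with a *fixed* Gaussian envelope
(effectively a short-term Fourier transform on log-spaced centre frequencies)
to produce a time-frequency magnitude image that the same block machinery can
then quantize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockPartition",
    "GroupCodec",
    "DiscreteObservation",
    "fit_partition",
    "block_vectors",
    "fit_codec",
    "encode",
    "decode",
    "audio_to_tf",
    "tf_to_audio",
]

#: Relative singular-value retention threshold: components with
#: S_i / S_1 <= RETENTION_DEFAULT are dropped (in addition to the max_vectors
#: cap).  The training criterion asks only for "large" singular values; this
#: fixed relative cutoff makes the choice reproducible.
RETENTION_DEFAULT = 1.0 / 64.0


@dataclass
class BlockPartition:
    """Row-major tiling of an image into equal blocks.

    ``R`` is the temporal grouping: each block vector concatenates ``R``
    successive frames (and all colour channels), so one discrete time step of
    the model spans ``R`` raw frames.
    """

    image_shape: tuple[int, int, int]  # (H, W, C)
    block_shape: tuple[int, int]  # (h, w)
    R: int = 1

    def __post_init__(self):
        H, W, _ = self.image_shape
        h, w = self.block_shape
        if H % h or W % w:
            raise ValueError(
                f"image dims {H}x{W} not divisible by block dims {h}x{w}; no implicit padding"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.image_shape[0] // self.block_shape[0], self.image_shape[1] // self.block_shape[1])

    @property
    def n_groups(self) -> int:
        gh, gw = self.grid_shape
        return gh * gw

    @property
    def centroids(self) -> np.ndarray:
        """(n_groups, 2) block-centre pixel coordinates (row, col)."""
        h, w = self.block_shape
        gh, gw = self.grid_shape
        rows = (np.arange(gh) * h + (h - 1) / 2.0)
        cols = (np.arange(gw) * w + (w - 1) / 2.0)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


@dataclass
class GroupCodec:
    """Per-group SVD basis plus the quantization grid for its variates.

    ``basis`` holds the retained left singular vectors (columns, orthonormal);
    ``bin_centers`` is (k, n_levels), uniformly spaced and symmetric about
    zero per variate, so the central level encodes "at the mean".
    """

    basis: np.ndarray  # (dim, k)
    singular_values: np.ndarray  # (k,)
    n_levels: int
    bin_centers: np.ndarray  # (k, n_levels)
    mean: np.ndarray  # (dim,)

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def variates(self, vectors: np.ndarray) -> np.ndarray:
        return (vectors - self.mean) @ self.basis

    def quantize(self, variates: np.ndarray) -> np.ndarray:
        """Nearest-bin index per variate; deterministic."""
        idx = np.empty(variates.shape, dtype=np.int64)
        for j in range(self.k):
            idx[:, j] = np.argmin(np.abs(variates[:, [j]] - self.bin_centers[j][None, :]), axis=1)
        return idx

    def reconstruct(self, indices: np.ndarray) -> np.ndarray:
        v = np.take_along_axis(
            np.broadcast_to(self.bin_centers, (indices.shape[0],) + self.bin_centers.shape),
            indices[:, :, None],
            axis=2,
        )[:, :, 0]
        return self.mean + v @ self.basis.T


@dataclass
class DiscreteObservation:
    """Discrete first-level observations: one categorical channel per variate.

    ``codes[t, c]`` is the quantization index of channel ``c`` at (coarse)
    time ``t``; ``alphabet[c]`` its number of levels.  ``channel_groups`` maps
    each spatial group to the channels (variates) it owns — a constant group
    owns no channels and contributes a single implicit symbol.
    """

    codes: np.ndarray  # (T, n_channels) int
    alphabet: np.ndarray  # (n_channels,) int
    channel_groups: list[list[int]]
    grid_shape: tuple[int, int]

    def __post_init__(self):
        if self.codes.size and np.any(self.codes >= self.alphabet[None, :]):
            raise ValueError("code index exceeds its alphabet size")

    @property
    def n_steps(self) -> int:
        return self.codes.shape[0]


def fit_partition(frames: np.ndarray, block_shape: tuple[int, int], R: int = 1) -> BlockPartition:
    """Tile ``frames`` (T, H, W[, C]) into blocks of ``block_shape`` pixels."""
    frames = _as_thwc(frames)
    T, H, W, C = frames.shape
    if T % R:
        raise ValueError(f"frame count {T} not divisible by temporal grouping R={R}")
    return BlockPartition(image_shape=(H, W, C), block_shape=tuple(block_shape), R=R)


def _as_thwc(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3:
        frames = frames[..., None]
    if frames.ndim != 4:
        raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
    return frames


def block_vectors(frames: np.ndarray, part: BlockPartition) -> np.ndarray:
    """Stack per-group training vectors: (n_groups, T//R, h*w*C*R).

    The block vector concatenates the ``R`` frames of a temporal segment and
    all colour channels (time-major, then row, column, channel).
    """
    frames = _as_thwc(frames)
    T, H, W, C = frames.shape
    h, w = part.block_shape
    if (H, W, C) != part.image_shape:
        raise ValueError(f"frame shape {(H, W, C)} does not match partition {part.image_shape}")
    R = part.R
    if T % R:
        raise ValueError(f"frame count {T} not divisible by R={R}")
    gh, gw = part.grid_shape
    n_seg = T // R
    # (n_seg, R, gh, h, gw, w, C) -> groups row-major
    x = frames.reshape(n_seg, R, gh, h, gw, w, C)
    x = x.transpose(2, 4, 0, 1, 3, 5, 6)  # (gh, gw, n_seg, R, h, w, C)
    return x.reshape(gh * gw, n_seg, R * h * w * C)


def fit_codec(
    vectors: np.ndarray,
    max_vectors: int = 16,
    n_levels: int = 7,
    retention: float = RETENTION_DEFAULT,
) -> GroupCodec:
    """Fit one group's SVD codec from its (n_samples, dim) training vectors.

    Retains the k <= max_vectors leading components whose relative singular
    value exceeds ``retention``; a constant group retains none and encodes a
    single symbol.  ``n_levels`` must be odd so zero is a bin centre.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one training vector")
    if n_levels % 2 == 0 or n_levels < 1:
        raise ValueError("n_levels must be odd and positive")
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0):
        k = 0
        U = np.zeros((X.shape[1], 0))
        S = np.zeros(0)
    else:
        U, S, _ = np.linalg.svd(Xc.T, full_matrices=False)
        keep = S > retention * S[0]
        k = min(int(keep.sum()), max_vectors)
        U, S = U[:, :k], S[:k]
    variates = Xc @ U
    amax = np.abs(variates).max(axis=0) if k else np.zeros(0)
    amax = np.where(amax > 0, amax, 1.0)
    centers = np.linspace(-1.0, 1.0, n_levels)[None, :] * amax[:, None]
    return GroupCodec(basis=U, singular_values=S, n_levels=n_levels, bin_centers=centers, mean=mean)


def fit_codecs(frames, part: BlockPartition, max_vectors=16, n_levels=7, retention=RETENTION_DEFAULT):
    """Fit one codec per group of the partition."""
    vecs = block_vectors(frames, part)
    return [fit_codec(vecs[g], max_vectors, n_levels, retention) for g in range(part.n_groups)]


def encode(frames, part: BlockPartition, codecs) -> DiscreteObservation:
    """Quantize frames to per-variate categorical channels (deterministic)."""
    vecs = block_vectors(frames, part)
    n_seg = vecs.shape[1]
    channel_groups: list[list[int]] = []
    cols = []
    alpha = []
    c0 = 0
    for g, codec in enumerate(codecs):
        idx = codec.quantize(codec.variates(vecs[g]))
        channel_groups.append(list(range(c0, c0 + codec.k)))
        c0 += codec.k
        if codec.k:
            cols.append(idx)
            alpha.extend([codec.n_levels] * codec.k)
    codes = np.concatenate(cols, axis=1) if cols else np.zeros((n_seg, 0), dtype=np.int64)
    return DiscreteObservation(
        codes=codes,
        alphabet=np.asarray(alpha, dtype=np.int64),
        channel_groups=channel_groups,
        grid_shape=part.grid_shape,
    )


def decode(obs: DiscreteObservation, part: BlockPartition, codecs) -> np.ndarray:
    """Invert :func:`encode`: frames (T, H, W, C) from quantized variates."""
    H, W, C = part.image_shape
    h, w = part.block_shape
    gh, gw = part.grid_shape
    n_seg = obs.n_steps
    frames = np.zeros((n_seg, part.R, gh, h, gw, w, C))
    for g, codec in enumerate(codecs):
        chans = obs.channel_groups[g]
        if codec.k:
            block = codec.reconstruct(obs.codes[:, chans])
        else:
            block = np.broadcast_to(codec.mean, (n_seg, codec.mean.size))
        gy, gx = divmod(g, gw)
        frames[:, :, gy, :, gx, :, :] = block.reshape(n_seg, part.R, h, w, C)
    return frames.reshape(n_seg * part.R, gh * h, gw * w, C)


# ---------------------------------------------------------------------------
# Audio time-frequency frontend
# ---------------------------------------------------------------------------


def audio_to_tf(
    waveform: np.ndarray,
    sr: int,
    f_min: float = 40.0,
    f_max: float = 4000.0,
    n_bins: int = 64,
    envelope_ms: float = 32.0,
    hop: int | None = None,
):
    """Fixed-envelope Gabor (Morlet-style) magnitude time-frequency image.

    Centre frequencies are log-spaced between ``f_min`` and ``f_max``; the
    Gaussian envelope is fixed at ``envelope_ms`` for every bin, making the
    transform effectively a short-term Fourier transform on a log grid.

    Returns ``(tf, freqs, hop)`` where ``tf`` has shape (n_bins, n_times).
    """
    from scipy.signal import fftconvolve

    y = np.asarray(waveform, dtype=float).ravel()
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max > sr / 2:
        raise ValueError(f"f_max={f_max} exceeds Nyquist {sr / 2}")
    freqs = np.geomspace(f_min, f_max, n_bins)
    sigma = envelope_ms / 1000.0 * sr  # samples
    half = int(np.ceil(3 * sigma))
    t = np.arange(-half, half + 1)
    env = np.exp(-0.5 * (t / sigma) ** 2)
    env /= env.sum()
    if hop is None:
        hop = max(1, int(round(sr * envelope_ms / 1000.0 / 4)))
    tf = np.empty((n_bins, int(np.ceil(y.size / hop))))
    for b, f in enumerate(freqs):
        kernel = env * np.exp(2j * np.pi * f / sr * t)
        resp = fftconvolve(y, kernel, mode="same")
        tf[b] = np.abs(resp)[::hop][: tf.shape[1]]
    return tf, freqs, hop


def tf_to_audio(tf: np.ndarray, freqs: np.ndarray, hop: int, sr: int) -> np.ndarray:
    """Overlap-add resynthesis: per-bin cosines with accumulated phase.

    Magnitude envelopes are linearly interpolated back to the sample rate and
    drive one oscillator per bin at its centre frequency.  Reconstruction is
    not sample-exact (phase is discarded by the magnitude transform) but
    band-limited content re-analyses to a closely correlated magnitude image.
    """
    tf = np.asarray(tf, dtype=float)
    n_samples = tf.shape[1] * hop
    tt = np.arange(n_samples)
    frame_t = np.arange(tf.shape[1]) * hop
    y = np.zeros(n_samples)
    for b, f in enumerate(freqs):
        m = np.interp(tt, frame_t, tf[b])
        y += m * np.cos(2 * np.pi * f / sr * tt)
    peak = np.abs(y).max()
    if peak > 0:
        y = y / peak
    return y
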