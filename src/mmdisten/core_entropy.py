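"""Multivariate multiscale modified-distribution entropy (MM-mDistEn).

The estimator quantifies the irregularity of a multichannel time series.
It composes six steps, each exposed as its own function:

1.  ``assemble_multivariate`` — stack c equal-length channels into a
    c × N matrix.
2.  ``coarse_grain`` — replace each channel by non-overlapping window
    means of width s (the scale factor), keeping floor(N/s) points.
3.  ``embed`` — delay-embed every channel with dimension m and delay τ
    and concatenate the per-channel vectors at equal time indices into
    composite (c·m)-dimensional state vectors.
4.  ``distance_matrix`` — all pairwise Chebyshev distances between
    distinct composite vectors (upper triangle, diagonal excluded).
5.  ``fuzzy_transform`` — map each distance d to the fuzzy similarity
    exp(−(d/r)^n) with tolerance r = r_coeff × SD and exponent n.
6.  ``empirical_pdf`` + Shannon entropy — histogram the similarities
    into B equal bins on [0, 1] and return −(1/log2 B)·Σ p·log2 p,
    a value in [0, 1].

``mm_mdisten`` runs the chain for one scale; ``entropy_profile`` maps it
over a list of scales, yielding the per-recording feature vector used
downstream for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "DegenerateSignalError",
    "MultichannelSignal",
    "EntropyConfig",
    "CoarseGrainedSeries",
    "PhaseSpaceMatrix",
    "DistanceMatrix",
    "EntropyProfile",
    "assemble_multivariate",
    "coarse_grain",
    "embed",
    "remove_baseline",
    "distance_matrix",
    "fuzzy_transform",
    "empirical_pdf",
    "mm_mdisten",
    "entropy_profile",
    "read_channel_csv",
    "write_channel_csv",
    "read_config",
    "write_profile_csv",
]


class DegenerateSignalError(ValueError):
    """Raised for zero-variance input, where the tolerance r = r_coeff·SD
    would collapse to 0 and the fuzzy transform is undefined."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultichannelSignal:
    """A c-channel recording of N samples.

    ``sample_rate`` is carried as metadata only; the entropy math is
    sampling-rate agnostic.
    """

    data: np.ndarray
    sample_rate: float = 1.0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError(f"signal data must be 2-D (channels × samples), got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError(f"need ≥1 channel and ≥2 samples, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains NaN or Inf values")
        if self.channel_names is not None and len(self.channel_names) != arr.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        object.__setattr__(self, "data", arr)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EntropyConfig:
    """Parameter bundle for MM-mDistEn.

    Parameters
    ----------
    m : embedding dimension (uniform across channels).
    tau : time delay of the embedding.
    r_coeff : tolerance coefficient; the tolerance is r = r_coeff × SD of
        the coarse-grained data (see ``sd_mode``).
    n : fuzzy exponent, the "step" of the exponential membership function.
    B : histogram bin count for the empirical PDF.
    scales : coarse-graining factors to evaluate.
    metric : 'chebyshev' (default) or 'euclidean' vector distance.
    sd_mode : 'pooled' computes one SD over all channels and retained
        samples; 'per_channel' averages the per-channel SDs.
    baseline : 'vector' (default) removes each channel's m-point local
        mean from its delay vector before distances are taken — the
        convention of the fuzzy similarity the r/n modification comes
        from, which keeps the tolerance r = 0.2·SD from saturating the
        membership function; 'none' uses the raw embedding vectors.
    """

    m: int = 3
    tau: int = 1
    r_coeff: float = 0.2
    n: float = 2.0
    B: int = 64
    scales: tuple[int, ...] = tuple(range(1, 16))
    metric: str = "chebyshev"
    sd_mode: str = "pooled"
    baseline: str = "vector"

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be a positive integer, got {self.tau}")
        if not (self.r_coeff > 0):
            raise ValueError(f"r_coeff must be > 0, got {self.r_coeff}")
        if not (self.n > 0):
            raise ValueError(f"n must be > 0, got {self.n}")
        if int(self.B) != self.B or self.B < 2:
            raise ValueError(f"B must be an integer ≥ 2, got {self.B}")
        scales = tuple(int(s) for s in self.scales)
        if not scales or any(s < 1 for s in scales):
            raise ValueError(f"scales must be positive integers, got {self.scales}")
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError(f"metric must be 'chebyshev' or 'euclidean', got {self.metric!r}")
        if self.sd_mode not in ("pooled", "per_channel"):
            raise ValueError(f"sd_mode must be 'pooled' or 'per_channel', got {self.sd_mode!r}")
        if self.baseline not in ("vector", "none"):
            raise ValueError(f"baseline must be 'vector' or 'none', got {self.baseline!r}")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "tau", int(self.tau))
        object.__setattr__(self, "B", int(self.B))
        object.__setattr__(self, "scales", scales)

    def validate_length(self, n_samples: int, s: int) -> None:
        """Check floor(N/s) − (m−1)·τ ≥ 2 for a signal of length n_samples."""
        n_s = n_samples // s
        v = n_s - (self.m - 1) * self.tau
        if v < 2:
            raise ValueError(
                f"scale {s}: coarse-grained length {n_s} leaves only {v} embedding "
                f"vectors (need ≥ 2) for m={self.m}, tau={self.tau}"
            )


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """Channel-wise window means at one scale; scale 1 is the identity."""

    data: np.ndarray  # c × floor(N/s)
    scale: int


@dataclass(frozen=True)
class PhaseSpaceMatrix:
    """V composite delay vectors of dimension c·m (rows)."""

    vectors: np.ndarray


@dataclass(frozen=True)
class DistanceMatrix:
    """Upper-triangle pairwise dissimilarities and their fuzzy transforms."""

    values: np.ndarray       # raw distances, length V(V−1)/2
    transformed: np.ndarray  # exp(−(d/r)^n), each in (0, 1]


@dataclass(frozen=True)
class EntropyProfile:
    """Per-scale MM-mDistEn values for one recording."""

    entropy_by_scale: dict[int, float]
    config: EntropyConfig

    def as_vector(self) -> np.ndarray:
        """Entropy values ordered as config.scales."""
        return np.array([self.entropy_by_scale[s] for s in self.config.scales])


# ---------------------------------------------------------------------------
# Step 1 — multivariate assembly
# ---------------------------------------------------------------------------


def assemble_multivariate(
    rows: Sequence[Sequence[float]],
    sample_rate: float = 1.0,
    channel_names: Sequence[str] | None = None,
) -> MultichannelSignal:
    """Stack equal-length channel series into a c × N signal, row order preserved."""
    if len(rows) == 0:
        raise ValueError("need at least one channel series")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"channel series have unequal lengths: {sorted(lengths)}")
    data = np.asarray(rows, dtype=float)
    names = tuple(channel_names) if channel_names is not None else None
    return MultichannelSignal(data=data, sample_rate=sample_rate, channel_names=names)


# ---------------------------------------------------------------------------
# Step 2 — coarse-graining
# ---------------------------------------------------------------------------


def coarse_grain(signal: MultichannelSignal, s: int) -> CoarseGrainedSeries:
    """Non-overlapping window means of width s per channel.

    Output length is floor(N/s); the trailing N mod s samples are
    discarded. s = 1 reproduces the input exactly.
    """
    s = int(s)
    if s < 1:
        raise ValueError(f"scale must be ≥ 1, got {s}")
    n_s = signal.n_samples // s
    if n_s < 2:
        raise ValueError(
            f"scale {s} leaves {n_s} coarse-grained samples from N={signal.n_samples}; need ≥ 2"
        )
    trimmed = signal.data[:, : n_s * s]
    data = trimmed.reshape(signal.n_channels, n_s, s).mean(axis=2)
    return CoarseGrainedSeries(data=data, scale=s)


# ---------------------------------------------------------------------------
# Step 3 — phase-space reconstruction
# ---------------------------------------------------------------------------


def embed(series: CoarseGrainedSeries | np.ndarray, m: int, tau: int) -> PhaseSpaceMatrix:
    """Delay-embed each channel and concatenate at equal time indices.

    Vector j (0-based) is ``concat_c (g[c, j], g[c, j+tau], …,
    g[c, j+(m−1)tau])`` so that one composite vector describes the joint
    multichannel state at time j.  m and τ are uniform across channels.
    """
    data = series.data if isinstance(series, CoarseGrainedSeries) else np.atleast_2d(np.asarray(series, dtype=float))
    c, n_s = data.shape
    v = n_s - (m - 1) * tau
    if v < 2:
        raise ValueError(
            f"series of length {n_s} yields {v} embedding vectors for m={m}, tau={tau}; need ≥ 2"
        )
    # per-channel delay blocks, then channel-major concatenation
    blocks = [
        np.stack([data[ch, k * tau : k * tau + v] for k in range(m)], axis=1) for ch in range(c)
    ]
    return PhaseSpaceMatrix(vectors=np.concatenate(blocks, axis=1))


# ---------------------------------------------------------------------------
# Step 4 — pairwise distances
# ---------------------------------------------------------------------------


def remove_baseline(ps: PhaseSpaceMatrix, n_channels: int, m: int) -> PhaseSpaceMatrix:
    """Subtract each channel block's own mean from every composite vector.

    Each vector is c concatenated m-point delay blocks; the block mean
    is the channel's local baseline at that time index.  Removing it
    makes the subsequent fuzzy similarity compare local waveform shape
    rather than absolute level, the convention of fuzzy-membership
    similarity measures.  Reduces to ordinary vector de-meaning for a
    single channel.
    """
    v = ps.vectors.reshape(ps.vectors.shape[0], n_channels, m)
    v = v - v.mean(axis=2, keepdims=True)
    return PhaseSpaceMatrix(vectors=v.reshape(ps.vectors.shape))


def distance_matrix(ps: PhaseSpaceMatrix, metric: str = "chebyshev") -> np.ndarray:
    """Pairwise distances between distinct composite vectors.

    Returns the V(V−1)/2 upper-triangle entries; the diagonal (i = j) is
    excluded and symmetric pairs are counted once.
    """
    vectors = ps.vectors
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors for pairwise distances")
    return pdist(vectors, metric=metric)


# ---------------------------------------------------------------------------
# Step 5 — fuzzy similarity transform
# ---------------------------------------------------------------------------


def fuzzy_transform(raw: np.ndarray, r: float, n: float) -> np.ndarray:
    """Exponential fuzzy membership μ(d) = exp(−(d/r)^n).

    Maps each distance to a similarity degree in (0, 1]: μ(0) = 1 and μ
    decreases monotonically with distance.  r sets the breadth and n the
    steepness of the membership function.
    """
    if not (r > 0):
        raise ValueError(f"tolerance r must be > 0, got {r}")
    if not (n > 0):
        raise ValueError(f"exponent n must be > 0, got {n}")
    d = np.asarray(raw, dtype=float)
    return np.exp(-((d / r) ** n))


# ---------------------------------------------------------------------------
# Step 6 — empirical PDF and entropy
# ---------------------------------------------------------------------------


def empirical_pdf(values: np.ndarray, B: int) -> np.ndarray:
    """Normalized histogram of similarities over B equal-width bins on [0, 1].

    The support is the fixed codomain of the fuzzy transform, not a
    data-dependent range, which makes the estimator amplitude-scale
    invariant.  Interior bin edges are assigned upward; 1.0 falls in the
    last bin.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot build an empirical PDF from zero values")
    if B < 2:
        raise ValueError(f"bin count B must be ≥ 2, got {B}")
    edges = np.linspace(0.0, 1.0, B + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return counts / vals.size


def _shannon_bits(p: np.ndarray) -> float:
    """Σ −p·log2 p with the 0·log 0 := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _tolerance(cg: CoarseGrainedSeries, cfg: EntropyConfig) -> float:
    """r = r_coeff × SD of the coarse-grained data (population convention)."""
    if cfg.sd_mode == "pooled":
        sd = float(np.std(cg.data))
    else:
        sd = float(np.mean(np.std(cg.data, axis=1)))
    if sd == 0.0:
        raise DegenerateSignalError(
            f"zero-variance signal at scale {cg.scale}: tolerance r = {cfg.r_coeff}·SD is 0"
        )
    return cfg.r_coeff * sd


def mm_mdisten(signal: MultichannelSignal, cfg: EntropyConfig, s: int) -> float:
    """MM-mDistEn at one scale: the full six-step chain.

    Returns −(1/log2 B)·Σ_t P_t·log2 P_t over the B-bin empirical PDF of
    fuzzy-transformed pairwise distances, a dimensionless value in [0, 1].
    Deterministic for fixed input and config.
    """
    cfg.validate_length(signal.n_samples, s)
    cg = coarse_grain(signal, s)
    r = _tolerance(cg, cfg)
    ps = embed(cg, cfg.m, cfg.tau)
    if cfg.baseline == "vector":
        ps = remove_baseline(ps, signal.n_channels, cfg.m)
    raw = distance_matrix(ps, metric=cfg.metric)
    transformed = fuzzy_transform(raw, r, cfg.n)
    p = empirical_pdf(transformed, cfg.B)
    return _shannon_bits(p) / np.log2(cfg.B)


def entropy_profile(signal: MultichannelSignal, cfg: EntropyConfig) -> EntropyProfile:
    """MM-mDistEn at every configured scale (the per-recording feature vector)."""
    for s in cfg.scales:
        cfg.validate_length(signal.n_samples, s)
    values = {s: mm_mdisten(signal, cfg, s) for s in cfg.scales}
    return EntropyProfile(entropy_by_scale=values, config=cfg)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def read_channel_csv(path: str | Path, sample_rate: float = 1.0) -> MultichannelSignal:
    """Read a channel-matrix CSV: one row per channel, optional header row
    of channel names (detected when the first row is non-numeric)."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    first = lines[0].split(",")
    names: tuple[str, ...] | None = None
    try:
        [float(tok) for tok in first]
        start = 0
    except ValueError:
        names = tuple(tok.strip() for tok in first)
        start = 1
    rows = [[float(tok) for tok in ln.split(",")] for ln in lines[start:]]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return assemble_multivariate(rows, sample_rate=sample_rate, channel_names=names)


def write_channel_csv(signal: MultichannelSignal, path: str | Path) -> None:
    """Write a channel-matrix CSV (header row of names when present)."""
    path = Path(path)
    with path.open("w") as fh:
        if signal.channel_names is not None:
            fh.write(",".join(signal.channel_names) + "\n")
        for row in signal.data:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_config(path: str | Path) -> EntropyConfig:
    """Read an EntropyConfig from a flat TOML file mirroring the field names.

    ``scales`` may be a list or an inclusive "lo-hi" range string.
    """
    import tomllib

    with Path(path).open("rb") as fh:
        raw = tomllib.load(fh)
    known = {f for f in EntropyConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if isinstance(raw.get("scales"), str):
        lo, hi = raw["scales"].split("-")
        raw["scales"] = tuple(range(int(lo), int(hi) + 1))
    return EntropyConfig(**raw)


def write_profile_csv(profile: EntropyProfile, path: str | Path) -> None:
    """Write an entropy profile as a two-column scale,entropy CSV."""
    with Path(path).open("w") as fh:
        fh.write("scale,entropy\n")
        for s in profile.config.scales:
            fh.write(f"{s},{profile.entropy_by_scale[s]!r}\n")
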