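"""Synthetic signal generators for validation and end-to-end testing.

Two families:

*   Parameter-selection series — 400-sample univariate benchmarks with
    known irregularity structure: Gaussian white noise, 1/f (pink)
    noise, the chaotic logistic map, and a sinusoid.  These are the
    standard series for checking that a multiscale entropy estimator
    separates stochastic, chaotic and periodic dynamics.
*   Two-class multichannel recordings — emulate the shape of a
    consumer-EEG emotion experiment (14 channels at 128 Hz by default):
    class 0 trials are narrowband oscillations with low additive noise
    (regular, low entropy); class 1 trials are broadband noise-dominated
    (irregular, high entropy).  Each trial carries a continuous rating
    on the 1–9 self-assessment scale, drawn from class-conditional
    distributions straddling the 4.5 binarization threshold.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core_entropy import MultichannelSignal

__all__ = [
    "SimSpec",
    "LabeledDatasetSpec",
    "Trial",
    "generate_series",
    "generate_labeled_dataset",
]

_KINDS = ("gaussian_white", "pink_1overf", "logistic_chaotic", "sinusoid")

#: logistic-map transient discarded before recording starts
_LOGISTIC_BURN_IN = 100


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic series.

    ``params`` is kind-specific: ``sd`` (gaussian), ``exponent`` (pink),
    ``rho``/``x0`` (logistic; x0 drawn per channel when omitted),
    ``frequency``/``phase``/``amplitude`` (sinusoid; frequency in cycles
    per sample, phase drawn uniformly when omitted).
    """

    kind: str
    n_samples: int = 400
    n_channels: int = 1
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}; expected one of {_KINDS}")
        if self.n_samples < 2 or self.n_channels < 1:
            raise ValueError("need n_samples ≥ 2 and n_channels ≥ 1")


def _logistic_channel(rng: np.random.Generator, n: int, rho: float, x0: float | None) -> np.ndarray:
    """One logistic-map orbit x_{t+1} = ρ·x_t·(1−x_t) after burn-in.

    Orbits that collapse onto a fixed point (0, 1, or 1−1/ρ) within the
    recorded window are rejected and the initial condition redrawn; for
    an explicit x0 whose orbit degenerates this raises instead.
    """
    explicit = x0 is not None
    for _ in range(1000):
        x = x0 if explicit else float(rng.uniform(0.05, 0.95))
        series = np.empty(_LOGISTIC_BURN_IN + n)
        series[0] = x
        for t in range(1, series.size):
            series[t] = rho * series[t - 1] * (1.0 - series[t - 1])
        out = series[_LOGISTIC_BURN_IN:]
        # degenerate when the recorded orbit stops moving
        if np.ptp(out) > 1e-6:
            return out
        if explicit:
            raise ValueError(f"logistic orbit from x0={x0} degenerates to a fixed point")
    raise RuntimeError("could not find a non-degenerate logistic initial condition")


def _pink_channel(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec = spec / freqs ** (exponent / 2.0)
    out = np.fft.irfft(spec, n)
    out = out - out.mean()
    return out / out.std() * sd


def generate_series(spec: SimSpec) -> MultichannelSignal:
    """Generate a deterministic multichannel series from its spec."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    chans = []
    for _ in range(spec.n_channels):
        if spec.kind == "gaussian_white":
            chans.append(rng.standard_normal(spec.n_samples) * p.get("sd", 1.0))
        elif spec.kind == "pink_1overf":
            chans.append(_pink_channel(rng, spec.n_samples, p.get("exponent", 1.0), p.get("sd", 1.0)))
        elif spec.kind == "logistic_chaotic":
            chans.append(_logistic_channel(rng, spec.n_samples, p.get("rho", 4.0), p.get("x0")))
        else:  # sinusoid
            amp = p.get("amplitude", 1.0)
            freq = p.get("frequency", 0.05)
            phase = p.get("phase", float(rng.uniform(0, 2 * np.pi)))
            t = np.arange(spec.n_samples)
            chans.append(amp * np.sin(2 * np.pi * freq * t + phase))
    return MultichannelSignal(data=np.asarray(chans))


# ---------------------------------------------------------------------------
# Two-class labeled datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledDatasetSpec:
    """Two-class multichannel dataset emulating an emotion-EEG experiment.

    Channels are not independent: as on a real scalp montage, every
    electrode sees a coherent mixture of a few shared cortical sources
    (volume conduction) plus a small amount of independent sensor
    noise.  The class contrast lives in the source dynamics — class 0
    ("low" rating) sources are narrowband theta/alpha oscillations
    (regular), class 1 ("high" rating) sources are broadband Gaussian
    noise (irregular).  Ratings are uniform on ``class0_rating_range``
    / ``class1_rating_range``, which straddle the 4.5 threshold.
    """

    n_subjects: int = 28
    trials_per_class: int = 10
    n_channels: int = 14
    n_samples: int = 512
    sample_rate: float = 128.0
    n_sources: int = 3
    sensor_noise_sd: float = 0.05
    class0_rating_range: tuple[float, float] = (1.5, 3.5)
    class1_rating_range: tuple[float, float] = (5.5, 8.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_class < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if self.n_samples < 2 or self.n_sources < 1:
            raise ValueError("need n_samples ≥ 2 and n_sources ≥ 1")
        if not (self.class0_rating_range[1] < 4.5 < self.class1_rating_range[0]):
            raise ValueError("class rating ranges must straddle the 4.5 threshold")


@dataclass(frozen=True)
class Trial:
    """One labeled recording: subject/trial identity, signal, and rating."""

    subject_id: int
    trial_id: str
    signal: MultichannelSignal
    rating: float


def _mixed_trial(rng: np.random.Generator, spec: LabeledDatasetSpec, cls: int) -> np.ndarray:
    """One trial: shared sources mixed coherently into all channels.

    Mixing gains are positive (a coherent field, as volume conduction
    produces) and rows are normalized so every channel has comparable
    source power; independent sensor noise is added on top.
    """
    if cls == 0:
        t = np.arange(spec.n_samples) / spec.sample_rate
        sources = np.stack(
            [
                np.sin(2 * np.pi * rng.uniform(4.0, 13.0) * t + rng.uniform(0, 2 * np.pi))
                for _ in range(spec.n_sources)
            ]
        )
    else:
        sources = rng.standard_normal((spec.n_sources, spec.n_samples))
    gains = np.abs(rng.standard_normal((spec.n_channels, spec.n_sources))) + 0.3
    gains /= np.linalg.norm(gains, axis=1, keepdims=True)
    noise = rng.standard_normal((spec.n_channels, spec.n_samples)) * spec.sensor_noise_sd
    return gains @ sources + noise


def generate_labeled_dataset(spec: LabeledDatasetSpec) -> list[Trial]:
    """Generate the full balanced dataset: for each subject,
    trials_per_class regular (class 0) and irregular (class 1) trials
    with class-conditional ratings.  Deterministic per seed; trials
    appear subject-major, class 0 before class 1."""
    rng = np.random.default_rng(spec.seed)
    trials: list[Trial] = []
    for subj in range(spec.n_subjects):
        for cls in (0, 1):
            lo, hi = spec.class0_rating_range if cls == 0 else spec.class1_rating_range
            for k in range(spec.trials_per_class):
                data = _mixed_trial(rng, spec, cls)
                rating = float(rng.uniform(lo, hi))
                trials.append(
                    Trial(
                        subject_id=subj,
                        trial_id=f"s{subj:02d}_c{cls}_t{k:02d}",
                        signal=MultichannelSignal(data=data, sample_rate=spec.sample_rate),
                        rating=rating,
                    )
                )
    return trials
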