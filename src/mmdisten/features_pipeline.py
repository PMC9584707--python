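"""Batch feature extraction: entropy profiles → labeled feature matrices.

Each trial becomes one row of MM-mDistEn values, one column per scale
(or per (channel-group, scale) pair when a grouping such as
frontal/temporal/parietal/occipital is supplied — columns are
group-major).  Self-report ratings on the 1–9 scale are binarized at
4.5 into low/high labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_entropy import EntropyConfig, MultichannelSignal, entropy_profile

__all__ = [
    "LabeledFeatureSet",
    "binarize_rating",
    "extract_features",
    "build_feature_set",
    "feature_column_names",
    "write_feature_csv",
    "read_feature_csv",
]

RATING_THRESHOLD = 4.5


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Entropy feature matrix with aligned binary labels for one subject."""

    features: np.ndarray          # trials × n_features
    labels: np.ndarray            # binary {0, 1}, 1 = high
    trial_ids: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if feats.ndim != 2:
            raise ValueError("features must be a 2-D matrix (trials × features)")
        if feats.shape[0] != labels.shape[0] or feats.shape[0] != len(self.trial_ids):
            raise ValueError("features, labels and trial_ids must align 1:1")
        if not np.all(np.isfinite(feats)):
            raise ValueError("feature matrix contains NaN or Inf")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "trial_ids", tuple(self.trial_ids))


def binarize_rating(score: float, threshold: float = RATING_THRESHOLD) -> str:
    """Binarize a 1–9 self-assessment rating: > threshold → 'high',
    otherwise 'low' (scores exactly at the threshold go to 'low')."""
    if not math.isfinite(score):
        raise ValueError(f"rating must be finite, got {score}")
    return "high" if score > threshold else "low"


def _resolve_group(
    signal: MultichannelSignal, members: Sequence[int | str]
) -> list[int]:
    idx = []
    for m in members:
        if isinstance(m, str):
            if signal.channel_names is None or m not in signal.channel_names:
                raise ValueError(f"channel {m!r} not found in signal")
            idx.append(signal.channel_names.index(m))
        else:
            if not 0 <= m < signal.n_channels:
                raise ValueError(f"channel index {m} out of range")
            idx.append(int(m))
    return idx


def extract_features(
    trials: Sequence[MultichannelSignal],
    cfg: EntropyConfig,
    groups: Mapping[str, Sequence[int | str]] | None = None,
    trial_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Entropy feature matrix: one row per trial.

    Without groups the row is the |scales|-long joint-channel profile.
    With groups, entropy is computed independently on each channel
    subset and rows are the group-major concatenation
    (|groups| × |scales| columns, ordered by the mapping's iteration
    order).  A trial failing the length constraint aborts the batch
    with its trial id named.
    """
    ids = list(trial_ids) if trial_ids is not None else [str(i) for i in range(len(trials))]
    rows = []
    for tid, sig in zip(ids, trials):
        try:
            if groups is None:
                rows.append(entropy_profile(sig, cfg).as_vector())
            else:
                parts = []
                for gname, members in groups.items():
                    idx = _resolve_group(sig, members)
                    sub = MultichannelSignal(
                        data=sig.data[idx], sample_rate=sig.sample_rate
                    )
                    parts.append(entropy_profile(sub, cfg).as_vector())
                rows.append(np.concatenate(parts))
        except ValueError as exc:
            raise ValueError(f"trial {tid!r}: {exc}") from exc
    return np.asarray(rows)


def feature_column_names(
    cfg: EntropyConfig, groups: Mapping[str, Sequence[int | str]] | None = None
) -> list[str]:
    """Column labels matching extract_features' ordering."""
    if groups is None:
        return [f"s{s}" for s in cfg.scales]
    return [f"{g}_s{s}" for g in groups for s in cfg.scales]


def build_feature_set(
    trials: Sequence[MultichannelSignal],
    ratings: Sequence[float],
    cfg: EntropyConfig,
    groups: Mapping[str, Sequence[int | str]] | None = None,
    trial_ids: Sequence[str] | None = None,
    subject_id: str = "",
) -> LabeledFeatureSet:
    """Extract features and binarize ratings into one aligned set."""
    if len(trials) != len(ratings):
        raise ValueError("trials and ratings must align 1:1")
    ids = tuple(trial_ids) if trial_ids is not None else tuple(str(i) for i in range(len(trials)))
    feats = extract_features(trials, cfg, groups=groups, trial_ids=ids)
    labels = np.array([1 if binarize_rating(r) == "high" else 0 for r in ratings])
    return LabeledFeatureSet(features=feats, labels=labels, trial_ids=ids, subject_id=subject_id)


def write_feature_csv(fset: LabeledFeatureSet, path: str | Path) -> None:
    """Write a feature table CSV: trial_id, label, f_1…f_k."""
    cols = {f"f_{j + 1}": fset.features[:, j] for j in range(fset.features.shape[1])}
    df = pd.DataFrame({"trial_id": fset.trial_ids, "label": fset.labels, **cols})
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path, subject_id: str = "") -> LabeledFeatureSet:
    """Read a feature table CSV written by ``write_feature_csv``."""
    df = pd.read_csv(path)
    if "trial_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: expected 'trial_id' and 'label' columns")
    fcols = [c for c in df.columns if c.startswith("f_")]
    if not fcols:
        raise ValueError(f"{path}: no feature columns (f_1…f_k)")
    fcols.sort(key=lambda c: int(c.split("_")[1]))
    return LabeledFeatureSet(
        features=df[fcols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        trial_ids=tuple(str(t) for t in df["trial_id"]),
        subject_id=subject_id,
    )
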