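"""Pipeline configuration and the trial -> raw-feature-table stage.

A single hierarchical config drives every stage (filter, STFT, channels,
deep backend, vocabulary size, classifier, seed); it serialises to YAML/JSON
and is embedded in every output artifact so runs are auditable and
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .deep import DeepBackend, FeatureCache, extract_deep, get_backend
from .io import EEGTrial
from .model import RAW_FEATURE_LENGTH, fuse_features
from .omtlbp import describe
from .preprocess import FilterSpec, bandpass_filter, select_channels
from .spectrogram import STFTConfig, compute_stft, render_image, to_rgb
from .synthetic import PRESETS, SyntheticSpec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective configuration of a BoHDF run."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    stft: STFTConfig = field(default_factory=STFTConfig)
    channels: Optional[list[str]] = None        # None = all channels, stored order
    backend: str = "mock"
    backend_options: dict = field(default_factory=dict)
    colormap: Optional[str] = None              # None = replicate grayscale
    k_per_class: int = 8
    classifier: str = "knn_weighted"
    n_neighbors: int = 10
    normalize_counts: bool = True
    vocab_mode: str = "per_class"
    n_splits: int = 5
    seed: int = 0
    synthetic: dict = field(default_factory=lambda: {"preset": "default",
                                                     "trials_per_class": 30})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stft"]["band"] = list(self.stft.band) if self.stft.band else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        if "stft" in d and isinstance(d["stft"], dict):
            s = dict(d["stft"])
            if s.get("band") is not None:
                s["band"] = tuple(s["band"])
            d["stft"] = STFTConfig(**s)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def synthetic_spec(self) -> SyntheticSpec:
        opts = dict(PRESETS.get(self.synthetic.get("preset", "default"), {}))
        opts.update({k: v for k, v in self.synthetic.items()
                     if k not in ("preset", "trials_per_class")})
        opts.setdefault("seed", self.seed)
        return SyntheticSpec(**opts)


def trial_raw_features(trial: EEGTrial, config: PipelineConfig,
                       backend: DeepBackend,
                       cache: Optional[FeatureCache] = None) -> np.ndarray:
    """Filter one trial and extract the fused 1600-dim raw feature vector of
    every channel: band-pass -> per-channel STFT spectrogram image ->
    texture descriptor + deep features -> concatenation."""
    if config.channels:
        trial = select_channels(trial, config.channels)
    trial = bandpass_filter(trial, config.filter)
    rows = np.empty((trial.n_channels, RAW_FEATURE_LENGTH))
    for ch in range(trial.n_channels):
        spec = compute_stft(trial.samples[ch], trial.fs, config.stft)
        gray = render_image(spec, config.stft)
        texture = describe(gray, normalize=True)
        deep = extract_deep(to_rgb(gray, config.colormap), backend, cache=cache)
        rows[ch] = fuse_features(deep, texture).values
    return rows


def extract_features(trials: Sequence[EEGTrial], config: PipelineConfig,
                     backend: Optional[DeepBackend] = None,
                     cache_dir: Optional[str | Path] = None) -> pd.DataFrame:
    """Run the feature-extraction stage over a dataset.

    Returns a tidy table with one row per (trial, channel):
    ``trial_id, channel, label`` followed by columns ``f0000..f1599``
    (deep features first, texture last).
    """
    backend = backend or get_backend(config.backend, **config.backend_options)
    cache = FeatureCache(cache_dir) if cache_dir is not None else None
    t0 = time.time()
    records = []
    for trial in trials:
        features = trial_raw_features(trial, config, backend, cache=cache)
        names = config.channels or trial.channel_names
        for ch, name in enumerate(names):
            records.append((trial.trial_id, name,
                            -1 if trial.label is None else int(trial.label),
                            features[ch]))
    logger.info("extracted %d x %d raw feature rows from %d trials in %.1f s "
                "(backend=%s)", len(records), RAW_FEATURE_LENGTH, len(trials),
                time.time() - t0, backend.name)
    columns = [f"f{i:04d}" for i in range(RAW_FEATURE_LENGTH)]
    df = pd.DataFrame([r[3] for r in records], columns=columns)
    df.insert(0, "label", [r[2] for r in records])
    df.insert(0, "channel", [r[1] for r in records])
    df.insert(0, "trial_id", [r[0] for r in records])
    return df


def features_to_arrays(df: pd.DataFrame) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Group a feature table by trial: per-trial (n_channels, 1600) arrays,
    trial labels, and trial ids (first-appearance order)."""
    trial_ids = list(dict.fromkeys(df["trial_id"]))
    feature_cols = [c for c in df.columns if c.startswith("f")]
    X, y = [], []
    for tid in trial_ids:
        sub = df[df["trial_id"] == tid]
        X.append(sub[feature_cols].to_numpy(dtype=np.float64))
        y.append(int(sub["label"].iloc[0]))
    return X, np.asarray(y), trial_ids
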