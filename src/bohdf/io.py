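"""EEG trial data model and container I/O.

The native on-disk format is a directory with one ``.npy`` matrix per trial
(channels x samples, float64) plus a ``manifest.csv`` describing each trial
(``trial_id, subject_id, label, fs, seed, channel_names``).  It round-trips
bit-identically.  EDF files are read through :mod:`mne` when available.
Adapters for the DEAP and SEED benchmark layouts are provided behind the same
reader interface; they follow the published matrix layouts but the datasets
themselves are gated downloads, so the package builds and tests without them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UnsupportedFormatError

logger = logging.getLogger(__name__)

_CHANNEL_SEP = ";"


@dataclass
class EEGTrial:
    """One labeled multi-channel EEG recording.

    Parameters
    ----------
    samples : ndarray of shape (n_channels, n_samples)
        Signal matrix; units are arbitrary (the pipeline is scale-covariant
        up to the per-image normalisation of the spectrogram).
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per channel, same order as the rows of ``samples``.
    label : int or None
        Class index, or None for unlabeled trials.
    subject_id, trial_id : str
        Free-form identifiers carried through the pipeline.
    meta : dict
        Provenance (applied filters, generator seed, ...).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    label: int | None = None
    subject_id: str = ""
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a (n_channels, n_samples) matrix "
                             "with at least one channel")
        if self.samples.shape[1] < 2 * self.fs:
            raise ValueError(
                f"trial too short: {self.samples.shape[1]} samples at fs={self.fs} Hz; "
                f"need at least 2 s ({int(2 * self.fs)} samples) for a meaningful spectrogram")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.samples.shape[0]} channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


def write_trials(trials: list[EEGTrial], path: str | Path) -> None:
    """Write trials to the native container (``.npy`` per trial + manifest).

    ``read_trials(path, format="native")`` inverts this exactly; writing the
    result again produces byte-identical files.
    """
    path = Path(path)
    trial_dir = path / "trials"
    try:
        trial_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, t in enumerate(trials):
            trial_id = t.trial_id or f"trial_{i:04d}"
            np.save(trial_dir / f"{trial_id}.npy", t.samples)
            rows.append({
                "trial_id": trial_id,
                "subject_id": t.subject_id,
                "label": "" if t.label is None else int(t.label),
                "fs": repr(float(t.fs)),
                "seed": t.meta.get("seed", ""),
                "channel_names": _CHANNEL_SEP.join(t.channel_names),
            })
        with open(path / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[
                "trial_id", "subject_id", "label", "fs", "seed", "channel_names"])
            writer.writeheader()
            writer.writerows(rows)
    except OSError as exc:
        raise OSError(f"failed writing trial container at {path}: {exc}") from exc


def read_trials(path: str | Path, format: str = "native") -> list[EEGTrial]:
    """Read a list of trials from ``path``.

    Supported formats: ``native`` (package container), ``edf`` (via mne),
    ``deap_mat`` and ``seed_mat`` (benchmark .mat adapters).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trial source: {path}")
    if format == "native":
        return _read_native(path)
    if format == "edf":
        return _read_edf(path)
    if format == "deap_mat":
        return _read_deap_mat(path)
    if format == "seed_mat":
        return _read_seed_mat(path)
    raise UnsupportedFormatError(
        f"unknown trial format {format!r}; supported: native, edf, deap_mat, seed_mat")


def _read_native(path: Path) -> list[EEGTrial]:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise ValueError(f"malformed native container {path}: missing manifest.csv")
    trials = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        has_label = reader.fieldnames is not None and "label" in reader.fieldnames
        if not has_label:
            logger.warning("manifest %s has no label column; trials will be unlabeled",
                           manifest)
        for row in reader:
            npy = path / "trials" / f"{row['trial_id']}.npy"
            try:
                samples = np.load(npy)
            except (OSError, ValueError) as exc:
                raise ValueError(f"malformed trial file {npy}: {exc}") from exc
            label_str = row.get("label", "") if has_label else ""
            meta = {}
            if row.get("seed", ""):
                meta["seed"] = int(row["seed"])
            trials.append(EEGTrial(
                samples=samples,
                fs=float(row["fs"]),
                channel_names=row["channel_names"].split(_CHANNEL_SEP),
                label=int(label_str) if label_str != "" else None,
                subject_id=row.get("subject_id", ""),
                trial_id=row["trial_id"],
                meta=meta,
            ))
    return trials


def _read_edf(path: Path) -> list[EEGTrial]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc
    return [EEGTrial(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        label=None,
        trial_id=path.stem,
    )]


def _read_deap_mat(path: Path, valence_threshold: float = 5.0) -> list[EEGTrial]:
    """DEAP preprocessed .mat adapter: ``data`` (40 trials x 40 ch x 8064) at
    128 Hz with the first 32 rows the EEG electrodes, ``labels`` (40 x 4)
    continuous ratings.  Valence is binned at ``valence_threshold`` into
    low/high classes; make any other binning explicit in the pipeline config.
    Untested against the gated download; layout follows the published format.
    """
    from scipy.io import loadmat

    try:
        mat = loadmat(str(path))
        data, ratings = mat["data"], mat["labels"]
    except Exception as exc:
        raise ValueError(f"malformed DEAP .mat file {path}: {exc}") from exc
    names = [f"EEG{i + 1:02d}" for i in range(32)]
    return [EEGTrial(
        samples=data[i, :32, :],
        fs=128.0,
        channel_names=names,
        label=int(ratings[i, 0] >= valence_threshold),
        subject_id=path.stem,
        trial_id=f"{path.stem}_t{i:02d}",
    ) for i in range(data.shape[0])]


def _read_seed_mat(path: Path, fs: float = 200.0) -> list[EEGTrial]:
    """SEED .mat adapter: one 62-channel matrix per film-clip variable.
    Labels come from the separate session key file, so trials load unlabeled.
    Untested against the gated download; layout follows the published format.
    """
    from scipy.io import loadmat

    try:
        mat = loadmat(str(path))
    except Exception as exc:
        raise ValueError(f"malformed SEED .mat file {path}: {exc}") from exc
    names = [f"EEG{i + 1:02d}" for i in range(62)]
    trials = []
    for key in sorted(k for k in mat if not k.startswith("__")):
        arr = np.asarray(mat[key])
        if arr.ndim == 2 and arr.shape[0] == 62:
            trials.append(EEGTrial(samples=arr, fs=fs, channel_names=names,
                                   subject_id=path.stem, trial_id=f"{path.stem}_{key}"))
    if not trials:
        raise ValueError(f"no 62-channel trial matrices found in {path}")
    return trials
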