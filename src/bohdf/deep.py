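"""Pluggable deep-feature backends.

A backend maps a rendered 3-channel spectrogram image to a fixed-length
feature vector — canonically the 1000-way final fully-connected layer of an
ImageNet-pretrained GoogLeNet (pre-softmax).  Backends are inference-only:
the pipeline never trains or fine-tunes a network.

The ``mock`` backend is a deterministic seeded random projection of the
image, built so tests and the synthetic study run with no network weights or
torch installation: the image is average-pooled per channel to a small grid
and multiplied by a fixed Gaussian matrix.  Pooling keeps the projection
sensitive to any single-pixel change while keeping the matrix small.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .errors import BackendUnavailableError

DEEP_FEATURE_LENGTH = 1000


@dataclass
class DeepFeatureVector:
    """Deep half of a raw feature vector, with provenance."""

    values: np.ndarray
    backend_name: str
    input_hash: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


class DeepBackend:
    """Base class: subclasses implement ``_extract(image) -> 1D array`` and
    declare ``n_features`` and ``input_size``."""

    name: str = "base"
    n_features: int = DEEP_FEATURE_LENGTH
    input_size: int = 224

    def _check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        expected = (self.input_size, self.input_size, 3)
        if image.shape != expected:
            raise ValueError(
                f"backend {self.name!r} expects a {expected} image, "
                f"got shape {image.shape}")
        return image

    def extract(self, image: np.ndarray) -> np.ndarray:
        image = self._check_image(image)
        values = np.asarray(self._extract(image), dtype=np.float64).ravel()
        if values.size != self.n_features:
            raise RuntimeError(
                f"backend {self.name!r} declared {self.n_features} features "
                f"but produced {values.size}")
        return values

    def _extract(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MockProjectionBackend(DeepBackend):
    """Deterministic stand-in backend: per-channel average pooling to a
    ``pool x pool`` grid followed by a fixed seeded Gaussian projection to
    ``n_features`` values.  Linear, so a zero image maps to zero."""

    name = "mock"

    def __init__(self, seed: int = 0, pool: int = 28,
                 n_features: int = DEEP_FEATURE_LENGTH, input_size: int = 224):
        if input_size % pool != 0:
            raise ValueError(f"pool={pool} must divide input_size={input_size}")
        self.seed = seed
        self.pool = pool
        self.n_features = n_features
        self.input_size = input_size
        self._projection: Optional[np.ndarray] = None

    @property
    def projection(self) -> np.ndarray:
        if self._projection is None:
            rng = np.random.default_rng(self.seed)
            dim = self.pool * self.pool * 3
            self._projection = rng.standard_normal((dim, self.n_features)) / np.sqrt(dim)
        return self._projection

    def _extract(self, image: np.ndarray) -> np.ndarray:
        block = self.input_size // self.pool
        pooled = image.reshape(self.pool, block, self.pool, block, 3).mean(axis=(1, 3))
        return pooled.ravel() @ self.projection


class GoogLeNetBackend(DeepBackend):
    """ImageNet-pretrained GoogLeNet final fully-connected layer
    (1000-dimensional, pre-softmax by default).  Requires the optional
    torch/torchvision installation with downloaded weights."""

    name = "googlenet"

    def __init__(self, pre_softmax: bool = True):
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "the 'googlenet' backend requires torch and torchvision with "
                "pretrained weights; install them, or use the 'mock' backend "
                "for weight-free runs") from exc
        import torch
        from torchvision import models

        self._torch = torch
        self._model = models.googlenet(weights=models.GoogLeNet_Weights.IMAGENET1K_V1)
        self._model.eval()
        self._pre_softmax = pre_softmax
        # Published preprocessing convention of the pretrained weights.
        self.preprocessing = {"mean": [0.485, 0.456, 0.406],
                              "std": [0.229, 0.224, 0.225]}

    def _extract(self, image: np.ndarray) -> np.ndarray:
        torch = self._torch
        mean = np.array(self.preprocessing["mean"])
        std = np.array(self.preprocessing["std"])
        x = (image - mean) / std
        tensor = torch.from_numpy(x.transpose(2, 0, 1)[None]).float()
        with torch.no_grad():
            logits = self._model(tensor)[0]
            if not self._pre_softmax:
                logits = torch.softmax(logits, dim=0)
        return logits.numpy().astype(np.float64)


_REGISTRY: dict[str, Callable[..., DeepBackend]] = {}


def register_backend(name: str, factory: Callable[..., DeepBackend]) -> None:
    _REGISTRY[name] = factory


register_backend("mock", MockProjectionBackend)
register_backend("googlenet", GoogLeNetBackend)


def get_backend(name: str, **options) -> DeepBackend:
    """Instantiate a registered backend by name."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown deep backend {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**options)


def image_hash(image: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(image, dtype=np.float64).tobytes()).hexdigest()


def extract_deep(image: np.ndarray, backend: DeepBackend,
                 cache: "FeatureCache | None" = None) -> DeepFeatureVector:
    """Run a backend on one image, optionally through a disk cache keyed by
    the image digest (reruns of the same input are free)."""
    digest = image_hash(np.asarray(image, dtype=np.float64))
    if cache is not None:
        cached = cache.get(backend.name, digest)
        if cached is not None:
            return DeepFeatureVector(cached, backend.name, digest)
    values = backend.extract(image)
    if cache is not None:
        cache.put(backend.name, digest, values)
    return DeepFeatureVector(values, backend.name, digest)


@dataclass
class FeatureCache:
    """Flat on-disk cache of backend outputs, one ``.npy`` per image digest."""

    root: Path
    _hits: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, backend_name: str, digest: str) -> Path:
        return self.root / f"{backend_name}_{digest}.npy"

    def get(self, backend_name: str, digest: str) -> Optional[np.ndarray]:
        p = self._path(backend_name, digest)
        if p.exists():
            self._hits += 1
            return np.load(p)
        return None

    def put(self, backend_name: str, digest: str, values: np.ndarray) -> None:
        np.save(self._path(backend_name, digest), values)
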