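"""Embedding providers and PCA reduction of embedded eye-region features.

A pluggable provider maps an 84x84 RGB eye-region raster to a feature
vector.  The contract mirrors a ResNet-12 few-shot embedding network
(12,800-d output); since pre-training such a network is prior work at GPU
scale, the default provider is a deterministic seeded random projection of
the raw pixels — enough to carry the iris-position signal and to exercise
PCA, feature fusion, and classification.  External providers (e.g. a
pretrained network with supplied weights) register under a name.

Embedded features are reduced to k principal components (default k = 5,
the number of components whose eigenvalues exceed 1 on the standardized
scree — the Kaiser rule — exposed as a diagnostic) before fusion with the
geometric features, so the high-dimensional embedding cannot drown the
two position scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .eye_region import EMBEDDING_INPUT_SIZE
from .iris_segmentation import to_grayscale

RESNET12_OUTPUT_DIM = 12_800
DEFAULT_N_COMPONENTS = 5


class EmbeddingError(ValueError):
    pass


class EmbeddingProvider(Protocol):
    name: str
    output_dim: int
    deterministic: bool

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class RandomProjectionEmbedding:
    """Seeded Gaussian random projection of centred gray pixels.

    Fully deterministic (PCG64 with a fixed seed builds the projection
    matrix once), so identical images embed to byte-identical vectors in
    any process.
    """

    output_dim: int = 256
    seed: int = 20_220_805
    name: str = "random-projection"
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise EmbeddingError("output_dim must be positive")
        n_in = EMBEDDING_INPUT_SIZE[0] * EMBEDDING_INPUT_SIZE[1]
        rng = np.random.default_rng(self.seed)
        W = rng.standard_normal((self.output_dim, n_in)) / np.sqrt(n_in)
        object.__setattr__(self, "_matrix", W)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        gray = to_grayscale(np.asarray(image)).astype(float) / 255.0
        return self._matrix @ (gray.ravel() - 0.5)  # type: ignore[attr-defined]


_PROVIDERS: dict[str, Callable[..., EmbeddingProvider]] = {
    "random-projection": RandomProjectionEmbedding,
}


def register_provider(name: str, factory: Callable[..., EmbeddingProvider]) -> None:
    """Register an embedding-provider factory (e.g. a pretrained network
    wrapper constructed from a weights path) under ``name``."""
    _PROVIDERS[name] = factory


def get_provider(name: str = "random-projection", **kwargs) -> EmbeddingProvider:
    try:
        factory = _PROVIDERS[name]
    except KeyError:
        raise EmbeddingError(
            f"unknown embedding provider {name!r}; registered: {sorted(_PROVIDERS)}"
        ) from None
    return factory(**kwargs)


def embed(image: np.ndarray, provider: EmbeddingProvider) -> np.ndarray:
    """Embed one 84x84 eye-region raster."""
    image = np.asarray(image)
    if image.shape[:2] != EMBEDDING_INPUT_SIZE:
        raise EmbeddingError(
            f"expected a {EMBEDDING_INPUT_SIZE} input, got {image.shape[:2]}")
    vec = np.asarray(provider(image), dtype=float)
    if vec.shape != (provider.output_dim,):
        raise EmbeddingError(
            f"provider {provider.name!r} returned shape {vec.shape}, "
            f"declared output_dim {provider.output_dim}")
    if not np.all(np.isfinite(vec)):
        raise EmbeddingError("embedding contains non-finite values")
    return vec


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray          # (d,)
    components: np.ndarray    # (k, d), orthonormal rows
    eigenvalues: np.ndarray   # (k,), descending, sample variances (ddof=1)

    @property
    def k(self) -> int:
        return self.components.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each component's largest-magnitude
    entry is non-negative (first such entry on exact ties)."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(features: np.ndarray, k: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Mean-centred PCA keeping the top-k components by eigenvalue.

    Deterministic: full SVD plus the sign convention above.  ``k`` may not
    exceed the rank of the centred data matrix.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise PCAError("features must be a 2-D (n, d) array")
    n, d = X.shape
    if k < 1:
        raise PCAError("k must be at least 1")
    if n < k + 1:
        raise PCAError(f"need at least k+1={k + 1} samples, got {n}")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise PCAError(f"k={k} exceeds the data rank {rank}")
    pca = _SKPCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCAModel(mean=pca.mean_.copy(),
                    components=_fix_signs(pca.components_),
                    eigenvalues=pca.explained_variance_.copy())


def project(model: PCAModel, feature: np.ndarray) -> np.ndarray:
    """Project one vector (or an (n, d) batch) onto the model's components."""
    x = np.asarray(feature, dtype=float)
    if x.shape[-1] != model.mean.shape[0]:
        raise PCAError(
            f"feature dimension {x.shape[-1]} does not match model "
            f"dimension {model.mean.shape[0]}")
    return (x - model.mean) @ model.components.T


def choose_k_by_eigenvalue(features: np.ndarray, k_max: int = 20) -> int:
    """Kaiser-rule diagnostic: count principal components of the
    column-standardized (correlation) data with eigenvalue > 1.

    A component with eigenvalue above 1 explains more than one original
    variable's worth of variance.  Diagnostic only — the pipeline default
    is k = 5.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise PCAError("need at least 2 samples")
    if k_max < 0:
        raise PCAError("k_max must be non-negative")
    if k_max == 0:
        return 0
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PCAError("degenerate feature set: zero-variance column(s)")
    Z = (X - X.mean(axis=0)) / sd
    n_comp = min(k_max, X.shape[0] - 1, X.shape[1])
    pca = _SKPCA(n_components=n_comp, svd_solver="full")
    pca.fit(Z)
    return int(np.sum(pca.explained_variance_ > 1.0))
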