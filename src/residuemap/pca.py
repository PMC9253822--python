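"""Principal-component decorrelation of the spectral bands.

The four spectral bands of high-resolution imagery are strongly correlated;
an eigendecomposition of the d x d band covariance (raw digital numbers,
mean-centered, not standardized) rotates them into uncorrelated components
ordered by variance.  The first component (PC1) carries the bulk of the
spatial detail — typically well above 90 % of total variance — and is the
single layer fed to the multi-scale wavelet feature extractor.

Eigenvector sign is fixed so results are reproducible across linear-algebra
backends: the largest-magnitude entry of each rotation row is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import MultispectralImage


@dataclass
class PCAModel:
    """Fitted rotation: rows of ``rotation`` are eigenvectors (d' x d)."""

    rotation: np.ndarray        # (d', d), orthonormal rows
    eigenvalues: np.ndarray     # (d',), non-increasing, DN^2
    band_means: np.ndarray      # (d,)

    @property
    def n_components(self) -> int:
        return self.rotation.shape[0]


@dataclass
class ComponentImage:
    """One principal-component image on the source grid (0-based index)."""

    pixels: np.ndarray
    component_index: int


def _valid_pixels(image: MultispectralImage) -> np.ndarray:
    mask = image.valid_mask()
    return image.pixels[:, mask].T.astype(float)  # (n, d)


def fit_pca(image: MultispectralImage) -> PCAModel:
    """Eigendecompose the band covariance over all valid (non-nodata) pixels.

    Constant or perfectly correlated bands are allowed and yield zero
    eigenvalues; negative round-off eigenvalues are clamped to zero.
    """
    d = image.n_bands
    if d < 2:
        raise ValueError("PCA requires at least two bands")
    data = _valid_pixels(image)
    if data.shape[0] < d:
        raise ValueError(
            f"need at least {d} valid pixels to estimate a {d}x{d} covariance"
        )
    means = data.mean(axis=0)
    centered = data - means
    cov = centered.T @ centered / data.shape[0]  # population covariance
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    rotation = eigvecs[:, order].T
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for i in range(d):
        j = np.argmax(np.abs(rotation[i]))
        if rotation[i, j] < 0:
            rotation[i] = -rotation[i]
    return PCAModel(rotation=rotation, eigenvalues=eigvals, band_means=means)


def transform(
    image: MultispectralImage, model: PCAModel, k: int | None = None
) -> list[ComponentImage]:
    """Project onto the first ``k`` components (mean-centered)."""
    if k is None:
        k = model.n_components
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k must be in [1, {model.n_components}], got {k}")
    d, r, c = image.pixels.shape
    flat = image.pixels.reshape(d, -1).T.astype(float) - model.band_means
    comps = flat @ model.rotation[:k].T  # (n, k)
    return [
        ComponentImage(comps[:, i].reshape(r, c), component_index=i)
        for i in range(k)
    ]


def inverse_transform(
    components: list[ComponentImage], model: PCAModel
) -> np.ndarray:
    """Reconstruct the band grid from component images; lossless at full rank."""
    k = len(components)
    r, c = components[0].pixels.shape
    comp = np.stack([ci.pixels.ravel() for ci in components], axis=1)  # (n, k)
    bands = comp @ model.rotation[:k] + model.band_means
    return bands.T.reshape(model.rotation.shape[1], r, c)


def variance_contributions(model: PCAModel) -> np.ndarray:
    """Each eigenvalue divided by the eigenvalue total; sums to one."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; variance contributions undefined")
    return model.eigenvalues / total


def pc1_image(
    image: MultispectralImage, model: PCAModel | None = None, rescale: bool = True
) -> ComponentImage:
    """First component image, min-max rescaled to [0, 255] by default.

    Rescaling puts PC1 on the digital-number scale of the input bands so the
    windowed wavelet features are comparable across scenes.
    """
    if model is None:
        model = fit_pca(image)
    pc1 = transform(image, model, 1)[0]
    if rescale:
        lo, hi = pc1.pixels.min(), pc1.pixels.max()
        if hi > lo:
            pc1 = ComponentImage((pc1.pixels - lo) * (255.0 / (hi - lo)), 0)
        else:
            pc1 = ComponentImage(np.zeros_like(pc1.pixels), 0)
    return pc1
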