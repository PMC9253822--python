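"""Labeled synthetic multispectral scenes of corn-residue cover.

Real high-resolution residue imagery exhibits strong intra-object
heterogeneity: a single field of Type 1 cover (straw stacked in rows after
manual harvest) alternates bright straw rows and dark soil rows at a period
of a few pixels, so its pixel spectra span nearly the full digital-number
range and overlap both the homogeneous bright Type 2 (machine-harvest straw
mats, DN 130–255) and the dark Type 3 stubble (DN 25–175).  The "other"
class (roads, buildings, forest) is heterogeneous and wide-range.  This
module generates scenes with exactly that statistical structure so the
multi-scale feature pipeline can be exercised end to end: each patch draws a
latent texture from its class model, all bands share the latent field (plus
band-specific gain/offset and independent noise), which concentrates >90 %
of the variance in the first principal component as in real four-band
imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import ClassMap
from .raster_io import (
    DEFAULT_BAND_NAMES,
    DEFAULT_CLASS_NAMES,
    MultispectralImage,
    SampleSet,
    stratified_split,
)
import pandas as pd

TEXTURES = (
    "striped", "homogeneous_bright", "homogeneous_dark", "speckled", "smooth",
)


@dataclass
class ClassModel:
    """Gray-value range (pre-noise digital numbers) and texture of one class."""

    low: float
    high: float
    texture: str

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 255:
            raise ValueError("class gray range must satisfy 0 <= low < high <= 255")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")


#: Default class models mirroring the observed per-class gray ranges:
#: Type 1 spans 0–250 as alternating bright/dark rows, Type 2 is homogeneous
#: bright in 130–255, Type 3 dark stubble in 25–175, "other" wide-range.
DEFAULT_CLASS_MODELS: dict[int, ClassModel] = {
    1: ClassModel(0, 250, "striped"),
    2: ClassModel(130, 255, "homogeneous_bright"),
    3: ClassModel(25, 175, "homogeneous_dark"),
    4: ClassModel(0, 250, "speckled"),
}

# Per-band radiometric gain/offset applied to the shared latent texture; the
# values are near-unity so bands stay strongly correlated (PC1-dominant).
DEFAULT_BAND_GAINS: tuple[float, ...] = (0.96, 1.0, 1.02, 1.05)
DEFAULT_BAND_OFFSETS: tuple[float, ...] = (-6.0, 0.0, 4.0, 10.0)
# Small class-specific band signatures (e.g. vegetation in "other" lifts NIR)
# so spectral-only classification is informative but imperfect.
DEFAULT_CLASS_BAND_OFFSETS: dict[int, tuple[float, ...]] = {
    1: (0.0, 0.0, 0.0, 0.0),
    2: (2.0, 0.0, -2.0, -4.0),
    3: (-2.0, 0.0, 6.0, 4.0),
    4: (-4.0, 0.0, -6.0, 18.0),
}


@dataclass
class SceneSpec:
    """Recipe for one synthetic scene.

    ``layout`` is a sequence of ``(class_id, row0, col0, height, width)``
    rectangles that must tile the grid without overlap; when omitted, a
    checkerboard of equally sized patches cycling through the classes is
    generated.  ``noise_sd`` is additive Gaussian noise in digital numbers
    applied independently per band; ``stripe_period`` is the full bright+dark
    cycle length of the striped texture in pixels.
    """

    size: tuple[int, int] = (512, 512)
    n_bands: int = 4
    layout: Sequence[tuple[int, int, int, int, int]] | None = None
    class_models: dict[int, ClassModel] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MODELS)
    )
    stripe_period: int = 3
    noise_sd: float = 8.0
    seed: int = 0
    patch_grid: tuple[int, int] = (4, 4)
    band_gains: Sequence[float] = DEFAULT_BAND_GAINS
    band_offsets: Sequence[float] = DEFAULT_BAND_OFFSETS
    class_band_offsets: dict[int, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BAND_OFFSETS)
    )

    def __post_init__(self) -> None:
        if self.stripe_period < 1:
            raise ValueError("stripe_period must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def resolved_layout(self) -> list[tuple[int, int, int, int, int]]:
        if self.layout is not None:
            return [tuple(p) for p in self.layout]
        r, c = self.size
        pr, pc = self.patch_grid
        classes = sorted(self.class_models)
        rows = np.linspace(0, r, pr + 1, dtype=int)
        cols = np.linspace(0, c, pc + 1, dtype=int)
        layout = []
        for i in range(pr):
            for j in range(pc):
                cid = classes[(i * (len(classes) // 2 + 1) + j) % len(classes)]
                layout.append(
                    (cid, rows[i], cols[j], rows[i + 1] - rows[i], cols[j + 1] - cols[j])
                )
        return layout


def _latent_patch(
    model: ClassModel, shape: tuple[int, int], period: int, rng: np.random.Generator
) -> np.ndarray:
    """Pre-noise latent texture of one patch, within [model.low, model.high]."""
    h, w = shape
    span = model.high - model.low
    if model.texture == "striped":
        dark = model.low + 0.12 * span
        bright = model.high - 0.10 * span
        rows = np.arange(h) % period < math.ceil(period / 2)
        patch = np.where(rows, bright, dark)[:, None] * np.ones((1, w))
    elif model.texture in ("homogeneous_bright", "homogeneous_dark"):
        center = 0.5 * (model.low + model.high)
        base = center + rng.uniform(-0.15 * span, 0.15 * span)
        patch = np.full(shape, base)
    elif model.texture == "smooth":
        # low-frequency field min-max rescaled to span the full class range,
        # so single-pixel gray values are ambiguous across classes
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=8, mode="reflect"
        )
        lo, hi = field_.min(), field_.max()
        if hi > lo:
            patch = model.low + (field_ - lo) * (span / (hi - lo))
        else:
            patch = np.full(shape, 0.5 * (model.low + model.high))
    else:  # speckled: smoothed per-pixel uniform draw (smoothing is convex,
        # so values remain inside the configured range)
        patch = rng.uniform(model.low, model.high, size=shape)
        patch = ndimage.uniform_filter(patch, size=5, mode="reflect")
    return patch


def generate_scene(spec: SceneSpec) -> tuple[MultispectralImage, ClassMap]:
    """Render a scene and its exact class map, deterministic under the seed."""
    r, c = spec.size
    layout = spec.resolved_layout()
    labels = np.zeros((r, c), dtype=np.int64)
    covered = np.zeros((r, c), dtype=bool)
    for cid, r0, c0, h, w in layout:
        if cid not in spec.class_models:
            raise ValueError(f"layout references class {cid} with no class model")
        block = covered[r0 : r0 + h, c0 : c0 + w]
        if block.shape != (h, w):
            raise ValueError(f"patch {(cid, r0, c0, h, w)} extends beyond the grid")
        if block.any():
            raise ValueError(f"patch {(cid, r0, c0, h, w)} overlaps another patch")
        covered[r0 : r0 + h, c0 : c0 + w] = True
        labels[r0 : r0 + h, c0 : c0 + w] = cid
    if not covered.all():
        raise ValueError("layout does not tile the grid")

    rng = np.random.default_rng(spec.seed)
    latent = np.zeros((r, c))
    for cid, r0, c0, h, w in layout:
        latent[r0 : r0 + h, c0 : c0 + w] = _latent_patch(
            spec.class_models[cid], (h, w), spec.stripe_period, rng
        )
    gains = np.asarray(spec.band_gains[: spec.n_bands], dtype=float)
    offsets = np.asarray(spec.band_offsets[: spec.n_bands], dtype=float)
    if gains.size < spec.n_bands or offsets.size < spec.n_bands:
        raise ValueError("band_gains/band_offsets shorter than n_bands")
    class_off = np.zeros((r, c, spec.n_bands))
    for cid in spec.class_models:
        off = np.asarray(spec.class_band_offsets.get(cid, (0.0,) * spec.n_bands))
        class_off[labels == cid] = off[: spec.n_bands]
    pixels = (
        gains[:, None, None] * latent[None]
        + offsets[:, None, None]
        + np.moveaxis(class_off, -1, 0)
    )
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 255.0)
    band_names = tuple(
        DEFAULT_BAND_NAMES[i] if spec.n_bands == 4 else f"band_{i + 1}"
        for i in range(spec.n_bands)
    )
    # dummy north-up geotransform at 1 m resolution
    image = MultispectralImage(
        pixels, band_names, geotransform=(0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
    )
    cmap = ClassMap(
        labels, dict(DEFAULT_CLASS_NAMES),
        [f"synthetic scene seed={spec.seed}"],
        geotransform=image.geotransform,
    )
    return image, cmap


def overlap_scene_spec(
    size: tuple[int, int] = (256, 256), seed: int = 0, noise_sd: float = 8.0
) -> SceneSpec:
    """Scene where classes overlap spectrally but differ in texture.

    The striped class spans nearly the full digital-number range, the bright
    and dark classes drift smoothly across their whole ranges (which overlap
    each other and the stripe extremes), and no class-specific band
    signature is applied — so a single pixel's spectrum is ambiguous and
    only neighborhood texture disambiguates.  This isolates the benefit of
    the multi-scale features over the spectral-only baseline.
    """
    return SceneSpec(
        size=size,
        seed=seed,
        noise_sd=noise_sd,
        class_models={
            1: ClassModel(0, 250, "striped"),
            2: ClassModel(130, 255, "smooth"),
            3: ClassModel(25, 175, "smooth"),
            4: ClassModel(0, 250, "speckled"),
        },
        class_band_offsets={c: (0.0, 0.0, 0.0, 0.0) for c in (1, 2, 3, 4)},
    )


def generate_sample_set(
    class_map: ClassMap,
    n_per_class: int,
    seed: int = 0,
    train_fraction: float = 0.7,
    classes: Sequence[int] | None = None,
) -> SampleSet:
    """Sample labeled pixels uniformly without replacement per class.

    A stratified train/validation split at ``train_fraction`` is applied.
    """
    labels = class_map.labels
    if classes is None:
        classes = [c for c in np.unique(labels) if c != 0]
    if n_per_class == 0 or not classes:
        records = pd.DataFrame(columns=["row", "col", "label", "split"])
        return SampleSet(records, dict(class_map.class_names) or dict(DEFAULT_CLASS_NAMES))
    rng = np.random.default_rng(seed)
    rows, cols, labs = [], [], []
    for cid in classes:
        flat = np.flatnonzero(labels.ravel() == cid)
        if flat.size == 0:
            raise ValueError(f"class {cid} not present in map")
        if n_per_class > flat.size:
            raise ValueError(
                f"requested {n_per_class} samples for class {cid}, "
                f"only {flat.size} pixels available"
            )
        chosen = rng.choice(flat, size=n_per_class, replace=False)
        rows.append(chosen // labels.shape[1])
        cols.append(chosen % labels.shape[1])
        labs.append(np.full(n_per_class, cid))
    records = pd.DataFrame(
        {
            "row": np.concatenate(rows),
            "col": np.concatenate(cols),
            "label": np.concatenate(labs),
        }
    )
    records["split"] = stratified_split(
        records["label"].to_numpy(), train_fraction, seed
    )
    return SampleSet(records, dict(class_map.class_names) or dict(DEFAULT_CLASS_NAMES))
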