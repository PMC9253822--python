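"""GeoTIFF raster and sample-table I/O.

Every other module consumes the in-memory types defined here; nothing else
touches disk formats.  Rasters are read and written with :mod:`tifffile`:
multi-band images are stored band-sequential, the affine geotransform is
carried in the standard GeoTIFF ModelPixelScale/ModelTiepoint tags (plus a
JSON ImageDescription that also carries band names, nodata and class names),
and categorical maps are written as an unsigned-integer band.

Conventions: pixel coordinates are 0-based ``(row, col)``, row-major, origin
at the top-left.  Class ids are 1 = Type 1 (striped residue rows), 2 = Type 2
(homogeneous bright residue), 3 = Type 3 (dark stubble), 4 = other; 0 is
reserved for nodata / unclassified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .calibration import ClassMap

DEFAULT_CLASS_NAMES: dict[int, str] = {
    1: "Type 1", 2: "Type 2", 3: "Type 3", 4: "other",
}
DEFAULT_BAND_NAMES: tuple[str, ...] = ("B_blue", "B_green", "B_red", "B_nir")

_GEO_PIXEL_SCALE = 33550   # GeoTIFF ModelPixelScaleTag
_GEO_TIEPOINT = 33922      # GeoTIFF ModelTiepointTag


@dataclass
class MultispectralImage:
    """A d-band raster grid of digital numbers sharing one pixel grid."""

    pixels: np.ndarray                      # (d, r, c)
    band_names: Sequence[str] = ()
    geotransform: tuple[float, ...] | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (bands, rows, cols) grid")
        d, r, c = self.pixels.shape
        if min(d, r, c) < 1:
            raise ValueError("image must have at least one band and one pixel")
        if not self.band_names:
            self.band_names = tuple(
                DEFAULT_BAND_NAMES[i] if d == 4 else f"band_{i + 1}"
                for i in range(d)
            )
        if len(self.band_names) != d:
            raise ValueError("band_names length must equal band count")
        if len(set(self.band_names)) != d:
            raise ValueError("band_names must be unique")
        self.band_names = tuple(self.band_names)

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def valid_mask(self) -> np.ndarray:
        """True where no band equals the nodata sentinel."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return ~np.any(self.pixels == self.nodata, axis=0)

    def band(self, name: str) -> np.ndarray:
        return self.pixels[self.band_names.index(name)]


@dataclass
class SampleSet:
    """Labeled pixel coordinates with a train/validation split tag."""

    records: pd.DataFrame                   # columns: row, col, label, split
    class_names: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_NAMES)
    )

    def __post_init__(self) -> None:
        required = {"row", "col", "label", "split"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"sample records missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    @property
    def train(self) -> pd.DataFrame:
        return self.subset("train")

    @property
    def validation(self) -> pd.DataFrame:
        return self.subset("validation")

    def class_counts(self) -> pd.Series:
        return self.records["label"].value_counts().sort_index()


def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.7, seed: int = 0
) -> np.ndarray:
    """Assign 'train'/'validation' tags per class, ±1 record of the ratio.

    Deterministic under a fixed seed: each class's record indices are
    permuted with an independent child of one seeded generator and the first
    round(train_fraction * n) go to the training split.
    """
    labels = np.asarray(labels)
    out = np.empty(labels.shape, dtype=object)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        out[perm[:n_train]] = "train"
        out[perm[n_train:]] = "validation"
    return out.astype(str) if labels.size else np.empty(0, dtype=str)


def read_samples(
    path: str | Path,
    grid_shape: tuple[int, int],
    class_names: Mapping[int, str] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> SampleSet:
    """Read a ``row,col,label[,split]`` CSV into a validated SampleSet.

    Records outside the grid are rejected with the offending line number.
    When the split column is absent a seeded stratified split at
    ``train_fraction`` is generated.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["row", "col", "label"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"{path}: header must start with row,col,label; got {list(df.columns)}"
        )
    if df.empty:
        records = pd.DataFrame(columns=["row", "col", "label", "split"])
        return SampleSet(records, class_names or dict(DEFAULT_CLASS_NAMES))
    for col in expected:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = converted.astype(int)
    r, c = grid_shape
    outside = (df["row"] < 0) | (df["row"] >= r) | (df["col"] < 0) | (df["col"] >= c)
    if outside.any():
        line = int(outside.idxmax()) + 2
        raise ValueError(f"{path}: sample outside {r}x{c} grid at line {line}")
    if class_names is not None:
        unknown = ~df["label"].isin(list(class_names))
        if unknown.any():
            line = int(unknown.idxmax()) + 2
            raise ValueError(f"{path}: unknown class label at line {line}")
    if "split" in df.columns:
        tags = df["split"].astype(str)
        bad = ~tags.isin(["train", "validation"])
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: split must be train|validation at line {line}")
        df["split"] = tags
    else:
        df["split"] = stratified_split(df["label"].to_numpy(), train_fraction, seed)
    records = df[["row", "col", "label", "split"]].reset_index(drop=True)
    return SampleSet(records, class_names or dict(DEFAULT_CLASS_NAMES))


def write_samples(samples: SampleSet, path: str | Path) -> None:
    samples.records.to_csv(path, index=False)


def _geotags(geotransform: tuple[float, ...]):
    """GeoTIFF tags for a north-up affine (no rotation terms)."""
    x0, dx, rx, y0, ry, dy = geotransform
    if rx or ry:
        return []
    scale = (abs(dx), abs(dy), 0.0)
    tiepoint = (0.0, 0.0, 0.0, x0, y0, 0.0)
    return [
        (_GEO_PIXEL_SCALE, "d", 3, scale, True),
        (_GEO_TIEPOINT, "d", 6, tiepoint, True),
    ]


def write_raster(obj: MultispectralImage | ClassMap, path: str | Path) -> None:
    """Write an image or categorical map as a (Geo)TIFF.

    Categorical maps are stored as a single unsigned-integer band with the
    class-name table in the ImageDescription metadata.
    """
    path = Path(path)
    if isinstance(obj, ClassMap):
        data = obj.labels.astype(np.uint16)[None]
        meta = {
            "kind": "class_map",
            "class_names": {str(k): v for k, v in obj.class_names.items()},
            "provenance": obj.provenance,
            "geotransform": obj.geotransform,
        }
        geotransform = obj.geotransform
    elif isinstance(obj, MultispectralImage):
        data = obj.pixels
        if data.shape[1] == 0 or data.shape[2] == 0:
            raise ValueError("cannot write an empty-extent grid")
        meta = {
            "kind": "multispectral",
            "band_names": list(obj.band_names),
            "nodata": obj.nodata,
            "geotransform": obj.geotransform,
        }
        geotransform = obj.geotransform
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if data.shape[1] == 0 or data.shape[2] == 0:
        raise ValueError("cannot write an empty-extent grid")
    extratags = _geotags(geotransform) if geotransform else []
    try:
        tifffile.imwrite(
            path, data, description=json.dumps(meta), extratags=extratags,
            photometric="minisblack",
        )
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


def _read_meta(tif: tifffile.TiffFile) -> dict:
    page = tif.pages[0]
    desc = page.tags.get("ImageDescription")
    meta: dict = {}
    if desc is not None:
        try:
            parsed = json.loads(desc.value)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            pass
    if not meta.get("geotransform"):
        scale = page.tags.get(_GEO_PIXEL_SCALE)
        tie = page.tags.get(_GEO_TIEPOINT)
        if scale is not None and tie is not None:
            sx, sy = scale.value[0], scale.value[1]
            x0, y0 = tie.value[3], tie.value[4]
            meta["geotransform"] = (x0, sx, 0.0, y0, 0.0, -sy)
    return meta


def read_multispectral(path: str | Path) -> MultispectralImage:
    """Read all bands of a GeoTIFF, preserving band order and nodata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _read_meta(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError(f"{path}: expected one or more 2-D bands")
    geotransform = meta.get("geotransform")
    return MultispectralImage(
        pixels=data,
        band_names=tuple(meta.get("band_names") or ()),
        geotransform=tuple(geotransform) if geotransform else None,
        nodata=meta.get("nodata"),
    )


def read_class_map(path: str | Path) -> ClassMap:
    """Read a categorical map written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _read_meta(tif)
    if data.ndim == 3:
        data = data[0]
    class_names = {
        int(k): v for k, v in (meta.get("class_names") or {}).items()
    } or dict(DEFAULT_CLASS_NAMES)
    geotransform = meta.get("geotransform")
    return ClassMap(
        labels=data.astype(np.int64),
        class_names=class_names,
        provenance=list(meta.get("provenance") or []),
        geotransform=tuple(geotransform) if geotransform else None,
    )
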