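"""Connected-domain calibration of categorical classification maps.

Pixel-level classifiers leave salt-and-pepper speckle in residue-cover maps
even when per-pixel accuracy is high, because fields are large connected
objects while errors are isolated.  Calibration removes, class by class in a
configured order, every connected component of a class smaller than a pixel
threshold, reassigning its pixels to the dominant adjacent class.  The default
order cleans the homogeneous bright residue class first, then the stubble
class, then the striped class, with a 60-pixel threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

#: default per-class cleaning order: Type 2, Type 3, Type 1
DEFAULT_ORDER: tuple[int, ...] = (2, 3, 1)
#: default minimum surviving component size, in pixels
DEFAULT_THRESHOLD: int = 60

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ClassMap:
    """Single-band categorical raster of predicted cover types.

    Label 0 is reserved for nodata / unclassified; class ids are positive.
    ``provenance`` accumulates a human-readable record of the model that
    produced the map and any calibration steps applied.
    """

    labels: np.ndarray
    class_names: Mapping[int, str] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    geotransform: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("ClassMap labels must be a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ClassMap labels must be integer-valued")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "ClassMap":
        return ClassMap(
            self.labels.copy(), dict(self.class_names), list(self.provenance),
            self.geotransform,
        )


@dataclass
class ComponentLabeling:
    """Maximal same-class connected components of one class.

    ``component_ids`` is 0 where the pixel does not belong to the class and
    1..n_components elsewhere; ids are assigned in raster-scan order of each
    component's first pixel so labelings are deterministic.
    """

    component_ids: np.ndarray
    class_id: int
    sizes: np.ndarray          # pixel count per component, index = id - 1
    bounding_boxes: list[tuple[int, int, int, int]]  # (row0, col0, row1, col1) half-open

    @property
    def n_components(self) -> int:
        return int(self.sizes.size)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(
    class_map: ClassMap | np.ndarray, class_id: int, connectivity: int = 4
) -> ComponentLabeling:
    """Label maximal ``connectivity``-connected components of one class."""
    labels = class_map.labels if isinstance(class_map, ClassMap) else np.asarray(class_map)
    mask = labels == class_id
    ids, n = ndimage.label(mask, structure=_structure(connectivity))
    # scipy assigns ids in raster-scan order of first pixel already; sizes:
    sizes = np.bincount(ids.ravel(), minlength=n + 1)[1:]
    boxes: list[tuple[int, int, int, int]] = []
    for sl in ndimage.find_objects(ids):
        boxes.append((sl[0].start, sl[1].start, sl[0].stop, sl[1].stop))
    return ComponentLabeling(ids, class_id, sizes.astype(np.int64), boxes)


def _reassign_component(
    labels: np.ndarray, comp_mask: np.ndarray, connectivity: int
) -> bool:
    """Reassign one component's pixels to the majority adjacent class.

    Ties are broken by the larger adjacent same-class component, then by the
    lower class id.  Returns False (leaves the map unchanged) when every
    adjacent pixel is nodata or the component touches nothing.
    """
    dil = ndimage.binary_dilation(comp_mask, structure=_structure(connectivity))
    border = dil & ~comp_mask
    neighbor_vals = labels[border]
    neighbor_vals = neighbor_vals[neighbor_vals != 0]
    if neighbor_vals.size == 0:
        return False
    classes, counts = np.unique(neighbor_vals, return_counts=True)
    best = counts == counts.max()
    candidates = classes[best]
    if candidates.size > 1:
        # tie: larger adjacent component of the candidate class wins
        comp_sizes = []
        for cid in candidates:
            lab = label_components(labels, int(cid), connectivity)
            adj_ids = np.unique(lab.component_ids[border])
            adj_ids = adj_ids[adj_ids > 0]
            comp_sizes.append(lab.sizes[adj_ids - 1].max() if adj_ids.size else 0)
        comp_sizes = np.asarray(comp_sizes)
        candidates = candidates[comp_sizes == comp_sizes.max()]
    labels[comp_mask] = int(candidates.min())
    return True


def calibrate_map(
    class_map: ClassMap,
    order: Sequence[int] = DEFAULT_ORDER,
    threshold: int = DEFAULT_THRESHOLD,
    connectivity: int = 4,
    per_class_threshold: Mapping[int, int] | None = None,
    until_stable: bool = False,
    max_passes: int = 50,
) -> ClassMap:
    """Delete small connected components class by class.

    For each class in ``order``, every component with fewer than ``threshold``
    pixels is removed and its pixels absorbed into the majority class among
    the component's adjacent pixels.  Later classes in the order see earlier
    reassignments.  With ``until_stable`` the whole pass repeats until no
    component changes (guarding against reassignments re-creating small
    components).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if not order:
        raise ValueError("order must name at least one class")
    out = class_map.copy()
    labels = out.labels
    for _ in range(max_passes if until_stable else 1):
        changed = False
        for cid in order:
            if not np.any(labels == cid):
                warnings.warn(
                    f"class {cid} absent from map; skipping calibration step",
                    stacklevel=2,
                )
                continue
            thr = threshold
            if per_class_threshold and cid in per_class_threshold:
                thr = per_class_threshold[cid]
            lab = label_components(labels, cid, connectivity)
            small = np.flatnonzero(lab.sizes < thr) + 1
            for comp_id in small:
                comp_mask = lab.component_ids == comp_id
                changed |= _reassign_component(labels, comp_mask, connectivity)
        if not (until_stable and changed):
            break
    out.provenance.append(
        f"calibrated(order={tuple(order)}, threshold={threshold}, "
        f"connectivity={connectivity}, until_stable={until_stable})"
    )
    return out
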