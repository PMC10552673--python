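"""Primary-object identification: threshold, clean, declump, size-filter.

The central routine, :func:`identify_primary_objects`, is a native
equivalent of the classic primary-object identification step used in
high-content image analysis. Objects must appear *lighter* than the
background in the input (callers invert first when needed). Touching
objects are split by shape: a Euclidean distance transform of the
foreground is Gaussian-smoothed, its local maxima become watershed seeds,
and the watershed of the negated smoothed distance map partitions the
clump. Increasing the smoothing sigma suppresses seeds and therefore
merges over-segmented objects; decreasing it splits under-segmented ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .imgio import BinaryMask, GrayImage
from .thresholding import ThresholdConfig, apply_threshold, compute_threshold

__all__ = [
    "SegmentationParams",
    "LabelMap",
    "identify_primary_objects",
    "filter_by_diameter",
    "objects_to_binary",
    "build_object_table",
]

AutoOrFloat = Union[str, float]


@dataclass
class SegmentationParams:
    """Parameters for primary-object identification.

    min_diameter / max_diameter bound the *area-equivalent* diameter
    2·sqrt(area/pi), in pixels, inclusive on both ends. smoothing_sigma
    and min_seed_distance control shape-based declumping; the string
    ``"auto"`` resolves them to min_diameter/4 and min_diameter/2
    respectively.
    """

    min_diameter: float
    max_diameter: float
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    declump: bool = True
    smoothing_sigma: AutoOrFloat = "auto"
    min_seed_distance: AutoOrFloat = "auto"
    fill_holes: bool = True
    discard_border: bool = False

    def __post_init__(self) -> None:
        if not self.min_diameter > 0:
            raise ValueError("min_diameter must be > 0")
        if self.max_diameter < self.min_diameter:
            raise ValueError("max_diameter must be >= min_diameter")
        for name in ("smoothing_sigma", "min_seed_distance"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a number or 'auto'")
            elif v < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.min_seed_distance, (int, float)) and self.min_seed_distance == 0:
            raise ValueError("min_seed_distance must be > 0")

    @property
    def resolved_smoothing_sigma(self) -> float:
        if self.smoothing_sigma == "auto":
            return self.min_diameter / 4.0
        return float(self.smoothing_sigma)

    @property
    def resolved_min_seed_distance(self) -> float:
        if self.min_seed_distance == "auto":
            return self.min_diameter / 2.0
        return float(self.min_seed_distance)


@dataclass
class LabelMap:
    """Integer-labelled segmentation: 0 is background, 1..n_objects are objects.

    Labels are always consecutive from 1 with no gaps.
    """

    labels: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap labels must be H x W")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap labels must be integers")
        present = np.unique(self.labels)
        present = present[present > 0]
        expected = np.arange(1, self.n_objects + 1)
        if present.size != self.n_objects or not np.array_equal(present, expected):
            raise ValueError(
                f"labels must be exactly 1..{self.n_objects}; found {present[:10]}..."
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def build_object_table(labels: LabelMap) -> pd.DataFrame:
    """Per-object measurements: label, area, equivalent_diameter, centroid.

    equivalent_diameter is the diameter of the circle with the object's
    pixel area, 2·sqrt(area/pi).
    """
    columns = ["label", "area", "equivalent_diameter", "centroid_row", "centroid_col"]
    if labels.n_objects == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns}).astype(
            {"label": int}
        )
    props = regionprops_table(
        labels.labels, properties=("label", "area", "equivalent_diameter_area", "centroid")
    )
    table = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "area": props["area"].astype(float),
            "equivalent_diameter": props["equivalent_diameter_area"].astype(float),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
        }
    )
    return table.sort_values("label", ignore_index=True)


def _relabel_consecutive(raw: np.ndarray) -> LabelMap:
    """Relabel a nonneg-integer array to consecutive 1..k preserving order."""
    present = np.unique(raw)
    present = present[present > 0]
    lut = np.zeros(int(raw.max()) + 1 if raw.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return LabelMap(lut[raw], int(present.size))


def _declump_watershed(fg: np.ndarray, sigma: float, min_distance: float) -> np.ndarray:
    """Split a binary foreground by smoothed-distance-transform watershed.

    Every connected component receives at least one seed, so declumping
    can only split components, never merge or drop them. Watershed ridge
    pixels are assigned to a basin (no unlabeled ridge lines), conserving
    foreground area.
    """
    dist = ndi.distance_transform_edt(fg)
    smoothed = ndi.gaussian_filter(dist, sigma) if sigma > 0 else dist
    comps = cc_label(fg, connectivity=2)
    coords = peak_local_max(
        smoothed,
        min_distance=max(int(round(min_distance)), 1),
        labels=comps,
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    ws = watershed(-smoothed, markers=markers, mask=fg, connectivity=2)
    # components whose plateau yielded no usable peak keep their own label
    leftover = fg & (ws == 0)
    if leftover.any():
        extra = cc_label(leftover, connectivity=2)
        ws = np.where(extra > 0, extra + ws.max(), ws)
    return ws


def identify_primary_objects(
    gray: GrayImage, params: SegmentationParams
) -> tuple[LabelMap, pd.DataFrame]:
    """Identify bright objects in a grayscale image.

    Stages: automatic thresholding; hole filling; shape-based declumping
    (or plain 8-connected labelling); size filtering on area-equivalent
    diameter; optional removal of border-touching objects; consecutive
    relabelling. An image with no surviving objects is a valid result
    with n_objects = 0.
    """
    t = compute_threshold(gray, params.threshold)
    mask = apply_threshold(gray, t, smooth_sigma=params.threshold.pre_apply_sigma)
    fg = mask.pixels.astype(bool)
    if params.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        labels = LabelMap(np.zeros(fg.shape, dtype=np.int32), 0)
        return labels, build_object_table(labels)
    if params.declump:
        raw = _declump_watershed(
            fg, params.resolved_smoothing_sigma, params.resolved_min_seed_distance
        )
    else:
        raw = cc_label(fg, connectivity=2)
    labels = _relabel_consecutive(np.asarray(raw))
    table = build_object_table(labels)
    labels, table = filter_by_diameter(
        labels, table, params.min_diameter, params.max_diameter
    )
    if params.discard_border:
        edge = np.zeros(labels.shape, dtype=bool)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        border_labels = np.unique(labels.labels[edge])
        border_labels = border_labels[border_labels > 0]
        if border_labels.size:
            keep = labels.labels.copy()
            keep[np.isin(keep, border_labels)] = 0
            labels = _relabel_consecutive(keep)
            table = build_object_table(labels)
    return labels, table


def filter_by_diameter(
    labels: LabelMap, table: pd.DataFrame, min_d: float, max_d: float
) -> tuple[LabelMap, pd.DataFrame]:
    """Drop objects whose equivalent diameter falls outside [min_d, max_d].

    Survivors are relabelled 1..k preserving their original relative order.
    """
    if min_d > max_d:
        raise ValueError("min_d must be <= max_d")
    if len(table) != labels.n_objects:
        raise ValueError("object table does not match the label map")
    keep = table[
        (table["equivalent_diameter"] >= min_d) & (table["equivalent_diameter"] <= max_d)
    ]["label"].to_numpy()
    if keep.size == labels.n_objects:
        return labels, table
    out = labels.labels.copy()
    out[~np.isin(out, keep) & (out > 0)] = 0
    new_labels = _relabel_consecutive(out)
    return new_labels, build_object_table(new_labels)


def objects_to_binary(labels: LabelMap) -> BinaryMask:
    """Collapse a label map to a binary mask (1 wherever label > 0)."""
    return BinaryMask((labels.labels > 0).astype(np.uint8))
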