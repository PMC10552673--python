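"""The four assay pipelines.

Each pipeline consumes one multichannel image plus a configuration and
produces an :class:`AssayResult`:

* ``ebd`` — count membrane-damaged (dye-positive) fibers. Damaged fibers
  have poorly defined borders, so they are not segmented directly:
  the image is inverted, the marker and laminin channels are combined,
  and pixel intensities are squared so dye-positive interiors go dark and
  are *masked out*; the remaining (dye-negative) fibers are counted, a
  second pass on the inverted laminin channel counts *all* fibers, and
  the difference is the dye-positive count.
* ``emyhc`` — count and size regenerating fibers. All fibers are counted
  on the inverted laminin channel; marker-positive fibers are segmented
  directly on the (un-inverted) marker channel, since they are
  well-defined and bright, and their per-object areas are reported.
* ``cd68`` — percent area of macrophage staining. Aggregates make
  per-cell counting impossible, so coverage is reported instead:
  minimum-cross-entropy segmentation of the marker channel, collapsed to
  a binary mask, measured against the whole frame.
* ``collagen`` — percent area of collagen in a brightfield stain. The
  green channel shows collagen most clearly; it is inverted so collagen
  is bright, segmented at myofiber-scale diameters, and measured as
  percent of the whole frame.

Channel roles (which stain sits in which channel) are explicit
configuration, because staining conventions differ between assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import imageops
from .imgio import (
    MultichannelImage,
    read_image,
    write_image,
    write_object_sizes_csv,
    write_results_csv,
)
from .measure import area_occupied, count_objects, subtract_counts
from .segmentation import (
    SegmentationParams,
    identify_primary_objects,
    objects_to_binary,
)
from .thresholding import ThresholdConfig

__all__ = [
    "PipelineConfig",
    "AssayResult",
    "default_config",
    "load_config",
    "run_ebd",
    "run_emyhc",
    "run_cd68",
    "run_collagen",
    "run_assay",
    "run_batch",
    "qc_overlay",
    "ASSAYS",
    "ASSAY_CSV_COLUMNS",
]

ASSAYS = ("ebd", "emyhc", "cd68", "collagen")

# CSV schemas, one per assay; the emyhc assay additionally writes a
# per-object sizes file via write_object_sizes_csv.
ASSAY_CSV_COLUMNS = {
    "ebd": ["image_id", "total_cells", "not_ebd_cells", "ebd_pos_cells",
            "pct_ebd_pos", "warnings"],
    "emyhc": ["image_id", "total_cells", "emyhc_pos_cells", "pct_emyhc_pos",
              "warnings"],
    "cd68": ["image_id", "foreground_pixels", "total_pixels", "pct_area",
             "warnings"],
    "collagen": ["image_id", "foreground_pixels", "total_pixels", "pct_area",
                 "warnings"],
}


@dataclass
class AssayResult:
    """Per-image output of one assay pipeline."""

    image_id: str
    assay: str
    counts: dict = field(default_factory=dict)
    percent: dict = field(default_factory=dict)
    sizes: Optional[list] = None
    warnings: list = field(default_factory=list)
    failed: bool = False

    def csv_row(self, columns: Sequence[str]) -> list:
        row = []
        for col in columns:
            if col == "image_id":
                row.append(self.image_id)
            elif col == "warnings":
                row.append("; ".join(self.warnings))
            elif col in self.counts:
                row.append(self.counts[col])
            elif col in self.percent:
                row.append(self.percent[col])
            else:
                row.append("")
        return row


@dataclass
class PipelineConfig:
    """One assay's full configuration.

    ``cell_params`` governs fiber-scale identification; ``marker_params``
    governs marker-scale identification where the assay has one.
    ``channel_roles`` maps stain roles (laminin, ebd, marker, collagen)
    to channel names. ``square_exponent`` is the masking exponent of the
    ebd assay.
    """

    assay: str
    cell_params: SegmentationParams
    marker_params: SegmentationParams
    channel_roles: dict
    square_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; choose from {ASSAYS}")
        required = {
            "ebd": {"laminin", "ebd"},
            "emyhc": {"laminin", "marker"},
            "cd68": {"marker"},
            "collagen": {"collagen"},
        }[self.assay]
        missing = required - set(self.channel_roles)
        if missing:
            raise ValueError(
                f"channel_roles for assay {self.assay!r} missing {sorted(missing)}"
            )

    def require_channels(self, img: MultichannelImage) -> None:
        for role, chan in self.channel_roles.items():
            if chan not in img.channel_names:
                raise ValueError(
                    f"role {role!r} maps to channel {chan!r}, absent from image "
                    f"with channels {img.channel_names}"
                )


def _fiber_cell_params() -> SegmentationParams:
    # fiber-scale identification shared by the ebd and emyhc assays: the
    # laminin wall network separates fibers, so seeds are kept sparse to
    # avoid splitting irregular interiors; the clamp bounds place the
    # threshold between wall and interior intensity
    return SegmentationParams(
        min_diameter=8,
        max_diameter=250,
        threshold=ThresholdConfig(
            method="robust_background", n_sd=2.0,
            lower_bound=0.5, upper_bound=0.7,
        ),
        declump=True,
        smoothing_sigma=8.0,
        min_seed_distance=40.0,
        fill_holes=True,
        discard_border=False,
    )


def default_config(assay: str) -> PipelineConfig:
    """Annotated defaults live in configs/defaults.yaml; these mirror them."""
    if assay == "ebd":
        return PipelineConfig(
            assay="ebd",
            cell_params=_fiber_cell_params(),
            marker_params=_fiber_cell_params(),
            channel_roles={"laminin": "green", "ebd": "red"},
            square_exponent=2.0,
        )
    if assay == "emyhc":
        return PipelineConfig(
            assay="emyhc",
            cell_params=_fiber_cell_params(),
            marker_params=SegmentationParams(
                min_diameter=10,
                max_diameter=150,
                threshold=ThresholdConfig(
                    method="robust_background", n_sd=2.0,
                    lower_bound=0.3, upper_bound=0.6,
                ),
                declump=False,
                fill_holes=True,
            ),
            channel_roles={"laminin": "red", "marker": "green"},
        )
    if assay == "cd68":
        return PipelineConfig(
            assay="cd68",
            cell_params=_fiber_cell_params(),
            marker_params=SegmentationParams(
                min_diameter=6,
                max_diameter=10000,  # aggregates can merge arbitrarily; area is what counts
                # lower bound at the half-maximum midpoint between marker
                # background and blob intensity: a symmetric optical blur then
                # moves the recovered edge onto the true edge (no area bias)
                threshold=ThresholdConfig(
                    method="min_cross_entropy",
                    lower_bound=0.4, upper_bound=0.9,
                ),
                declump=False,
                fill_holes=True,
            ),
            channel_roles={"laminin": "red", "marker": "green"},
        )
    if assay == "collagen":
        return PipelineConfig(
            assay="collagen",
            cell_params=_fiber_cell_params(),
            marker_params=SegmentationParams(
                min_diameter=6,
                max_diameter=400,
                # half-maximum midpoint between inverted-green muscle and
                # collagen levels, for the same blur-unbiasedness reason
                threshold=ThresholdConfig(
                    method="min_cross_entropy",
                    lower_bound=0.575, upper_bound=0.9,
                ),
                declump=False,
                fill_holes=False,  # collagen encircles fibers; filling would engulf them
            ),
            channel_roles={"collagen": "green"},
        )
    raise ValueError(f"unknown assay {assay!r}")


def _params_from_dict(base: SegmentationParams, d: dict) -> SegmentationParams:
    d = dict(d)
    tcfg = base.threshold
    if "threshold" in d:
        tcfg = replace(tcfg, **d.pop("threshold"))
    return replace(base, threshold=tcfg, **d)


def load_config(path: str | Path, assay: Optional[str] = None) -> PipelineConfig:
    """Load a YAML config file, overriding the assay's defaults.

    The file may state the assay itself (key ``assay``) or it can be
    passed explicitly; explicit wins. Any omitted key keeps its default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    assay = assay or raw.get("assay")
    if assay is None:
        raise ValueError(f"config {path} does not state an assay and none was given")
    cfg = default_config(assay)
    if "channel_roles" in raw:
        cfg = replace(cfg, channel_roles=dict(raw["channel_roles"]))
    if "square_exponent" in raw:
        cfg = replace(cfg, square_exponent=float(raw["square_exponent"]))
    if "cell_params" in raw:
        cfg = replace(cfg, cell_params=_params_from_dict(cfg.cell_params, raw["cell_params"]))
    if "marker_params" in raw:
        cfg = replace(cfg, marker_params=_params_from_dict(cfg.marker_params, raw["marker_params"]))
    return cfg


def _image_id(img: MultichannelImage, fallback: str = "image") -> str:
    if img.source_path:
        return Path(img.source_path).stem
    return fallback


def run_ebd(img: MultichannelImage, cfg: PipelineConfig) -> AssayResult:
    """Count dye-positive (membrane-damaged) fibers by subtraction."""
    cfg.require_channels(img)
    result = AssayResult(image_id=_image_id(img), assay="ebd")

    inverted = imageops.invert(img)
    gray = imageops.combine_to_gray(
        inverted, [cfg.channel_roles["ebd"], cfg.channel_roles["laminin"]]
    )
    masked = imageops.power_transform(gray, cfg.square_exponent)
    not_labels, _ = identify_primary_objects(masked, cfg.cell_params)
    not_ebd = count_objects(not_labels)

    planes = imageops.split_channels(img)
    laminin_inv = imageops.invert(planes[cfg.channel_roles["laminin"]])
    total_labels, _ = identify_primary_objects(laminin_inv, cfg.cell_params)
    total = count_objects(total_labels)

    ebd_pos, warn = subtract_counts(total, not_ebd)
    if warn:
        result.warnings.append(warn)
    result.counts = {
        "total_cells": total,
        "not_ebd_cells": not_ebd,
        "ebd_pos_cells": ebd_pos,
    }
    if total > 0:
        result.percent["pct_ebd_pos"] = 100.0 * ebd_pos / total
    else:
        result.warnings.append("no muscle cells detected")
    return result


def run_emyhc(img: MultichannelImage, cfg: PipelineConfig) -> AssayResult:
    """Count and size regenerating (marker-positive) fibers."""
    cfg.require_channels(img)
    result = AssayResult(image_id=_image_id(img), assay="emyhc")

    planes = imageops.split_channels(img)
    laminin_inv = imageops.invert(planes[cfg.channel_roles["laminin"]])
    total_labels, _ = identify_primary_objects(laminin_inv, cfg.cell_params)
    total = count_objects(total_labels)

    marker_labels, marker_table = identify_primary_objects(
        planes[cfg.channel_roles["marker"]], cfg.marker_params
    )
    n_pos = count_objects(marker_labels)

    result.counts = {"total_cells": total, "emyhc_pos_cells": n_pos}
    result.sizes = [float(a) for a in marker_table["area"]]
    if total > 0:
        result.percent["pct_emyhc_pos"] = 100.0 * n_pos / total
    else:
        result.warnings.append("no muscle cells detected")
    return result


def _percent_area(img: MultichannelImage, cfg: PipelineConfig, assay: str,
                  gray) -> AssayResult:
    result = AssayResult(image_id=_image_id(img), assay=assay)
    labels, _ = identify_primary_objects(gray, cfg.marker_params)
    occ = area_occupied(objects_to_binary(labels))
    result.counts = {
        "foreground_pixels": occ.foreground_pixels,
        "total_pixels": occ.total_pixels,
    }
    result.percent["pct_area"] = occ.percent
    return result


def run_cd68(img: MultichannelImage, cfg: PipelineConfig) -> AssayResult:
    """Percent area of macrophage (marker) staining over the whole frame."""
    cfg.require_channels(img)
    planes = imageops.split_channels(img)
    return _percent_area(img, cfg, "cd68", planes[cfg.channel_roles["marker"]])


def run_collagen(img: MultichannelImage, cfg: PipelineConfig) -> AssayResult:
    """Percent area of collagen in a brightfield stain over the whole frame."""
    cfg.require_channels(img)
    planes = imageops.split_channels(img)
    collagen_bright = imageops.invert(planes[cfg.channel_roles["collagen"]])
    return _percent_area(img, cfg, "collagen", collagen_bright)


_RUNNERS = {"ebd": run_ebd, "emyhc": run_emyhc, "cd68": run_cd68,
            "collagen": run_collagen}


def run_assay(img: MultichannelImage, cfg: PipelineConfig) -> AssayResult:
    return _RUNNERS[cfg.assay](img, cfg)


def run_batch(
    paths: Sequence[str | Path], cfg: PipelineConfig, out_csv: str | Path
) -> list[AssayResult]:
    """Run the configured assay over many images and write one CSV.

    Per-image failures become warning rows rather than aborting the
    batch; if *no* image succeeds the batch raises. The emyhc assay also
    writes a per-object sizes file next to the CSV
    (``<out_csv stem>_objects.csv``).
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no input images given")
    results = []
    for p in paths:
        try:
            img = read_image(p)
            results.append(run_assay(img, cfg))
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            results.append(
                AssayResult(
                    image_id=Path(p).stem,
                    assay=cfg.assay,
                    warnings=[f"error: {exc}"],
                    failed=True,
                )
            )
    if all(r.failed for r in results):
        raise RuntimeError("no input image could be processed")
    write_results_csv(results, out_csv)
    if cfg.assay == "emyhc":
        out_csv = Path(out_csv)
        write_object_sizes_csv(
            results, out_csv.with_name(out_csv.stem + "_objects.csv")
        )
    return results


def qc_overlay(img: MultichannelImage, cfg: PipelineConfig) -> MultichannelImage:
    """Render object outlines over the image for visual quality control.

    Recomputes the assay's principal segmentation (fiber-scale for ebd
    and emyhc, marker-scale for cd68 and collagen) and marks its
    boundaries in yellow.
    """
    from skimage.segmentation import find_boundaries

    cfg.require_channels(img)
    planes = imageops.split_channels(img)
    if cfg.assay in ("ebd", "emyhc"):
        gray = imageops.invert(planes[cfg.channel_roles["laminin"]])
        labels, _ = identify_primary_objects(gray, cfg.cell_params)
    elif cfg.assay == "cd68":
        labels, _ = identify_primary_objects(
            planes[cfg.channel_roles["marker"]], cfg.marker_params
        )
    else:
        gray = imageops.invert(planes[cfg.channel_roles["collagen"]])
        labels, _ = identify_primary_objects(gray, cfg.marker_params)
    outline = find_boundaries(labels.labels, mode="outer")
    if img.pixels.shape[2] >= 3:
        rgb = img.pixels[:, :, :3].copy()
        names = img.channel_names[:3]
    else:
        rgb = np.repeat(img.pixels[:, :, :1], 3, axis=2)
        names = ("red", "green", "blue")
    rgb[outline] = (1.0, 1.0, 0.0)
    return MultichannelImage(rgb, names, img.source_path)
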