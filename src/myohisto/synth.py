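"""Synthetic muscle cross-section scenes with exact ground truth.

Real dystrophic-muscle micrographs are rarely published alongside their
annotations, so this module emulates them: a cross-section is modelled as
a Voronoi tessellation of jittered lattice points (the polygonal packing
of muscle fibers), whose inter-region walls carry the basement-membrane
(laminin) stain and whose interiors optionally carry a marker stain —
dye-positive damaged fibers, regenerating fibers, or nothing. Macrophage
aggregates are irregular bright blobs; interstitial collagen is grown
outward from the fiber-boundary network until a target coverage is met.
Rendering adds Gaussian blur and additive Gaussian noise.

Every scene is fully determined by its seed, and the ground truth
(fiber label map, per-fiber marker flags, painted pixel masks) is exact
by construction, which makes end-to-end recovery testable to the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .imgio import BinaryMask, MultichannelImage
from .segmentation import LabelMap, _relabel_consecutive

__all__ = [
    "SceneParams",
    "SceneTruth",
    "generate_scene",
    "render_fluorescence",
    "render_brightfield_collagen",
]

# rendering constants (all overridable by subclassing is deliberately not
# offered: the defaults are the contract the assay default configs assume)
LAMININ_HI = 0.8
INTERIOR_LO = 0.05
MARKER_BG = 0.02
MARKER_RANGE = (0.7, 0.9)
COLLAGEN_RGB = (0.75, 0.15, 0.2)
MUSCLE_RGB = (0.85, 0.7, 0.55)

_FLUOR_ASSAYS = ("ebd", "emyhc", "cd68")


@dataclass
class SceneParams:
    """Geometry, staining and imaging parameters of a synthetic scene.

    All sizes are in pixels. ``fiber_jitter`` perturbs each lattice point
    by a uniform fraction of the lattice spacing; ``boundary_width`` is
    the erosion depth that turns Voronoi regions into fiber interiors, so
    walls are roughly twice that wide. ``noise_sd`` is the additive
    Gaussian noise sigma in intensity units; ``blur_sigma`` the optical
    blur. The seed fully determines the scene and its rendering.
    """

    height: int = 512
    width: int = 512
    n_fibers: int = 100
    fiber_jitter: float = 0.35
    boundary_width: float = 3.0
    marker_fraction: float = 0.0
    marker_size_bias: str = "none"
    aggregate_count: int = 0
    aggregate_radius: float = 13.0
    collagen_fraction: float = 0.0
    noise_sd: float = 0.01
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("marker_fraction", "collagen_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.height < 1 or self.width < 1 or self.n_fibers < 1:
            raise ValueError("height, width and n_fibers must be positive")
        if self.boundary_width <= 0 or self.aggregate_radius <= 0:
            raise ValueError("sizes must be positive")
        if self.marker_size_bias not in ("none", "small"):
            raise ValueError("marker_size_bias must be 'none' or 'small'")
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.fiber_jitter < 0:
            raise ValueError("noise_sd, blur_sigma, fiber_jitter must be >= 0")
        mean_diam = 2.0 * np.sqrt((self.height * self.width / self.n_fibers) / np.pi)
        if mean_diam < 4.0 * self.boundary_width:
            raise ValueError(
                f"n_fibers too large for the frame: mean fiber diameter "
                f"{mean_diam:.1f} px < 4 x boundary_width"
            )


@dataclass
class SceneTruth:
    """Exact ground truth of a generated scene."""

    params: SceneParams
    fiber_label_map: LabelMap
    marker_flags: np.ndarray  # bool per fiber, index = label - 1
    fiber_areas: np.ndarray  # pixel counts per fiber
    marker_pixel_mask: Optional[BinaryMask] = None  # painted CD68 or collagen pixels
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        """Recompute the summary from the masks (internal consistency check)."""
        n = self.fiber_label_map.n_objects
        n_pos = int(self.marker_flags.sum())
        out = {
            "n_fibers": n,
            "n_positive": n_pos,
            "pct_positive": 100.0 * n_pos / n if n else 0.0,
        }
        if self.marker_pixel_mask is not None:
            m = self.marker_pixel_mask.pixels
            out["marker_pct_area"] = 100.0 * float(m.sum()) / m.size
        return out


def _voronoi_labels(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Nearest-point partition of the frame around jittered lattice points."""
    h, w, n = params.height, params.width, params.n_fibers
    aspect = h / w
    nr = max(int(round(np.sqrt(n * aspect))), 1)
    nc = int(np.ceil(n / nr))
    sy, sx = h / nr, w / nc
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    centers = np.column_stack(
        [(rows.ravel() + 0.5) * sy, (cols.ravel() + 0.5) * sx]
    )
    jitter = rng.uniform(-params.fiber_jitter, params.fiber_jitter, size=centers.shape)
    centers = centers + jitter * np.array([sy, sx])
    if centers.shape[0] > n:
        keep = rng.permutation(centers.shape[0])[:n]
        centers = centers[np.sort(keep)]
    tree = cKDTree(centers)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    _, nearest = tree.query(pts)
    return nearest.reshape(h, w).astype(np.int32)


def _interior_mask(voronoi: np.ndarray, boundary_width: float) -> np.ndarray:
    """Erode each Voronoi region by boundary_width (Euclidean) from the
    inter-region boundary only; the frame edge does not erode."""
    boundary = np.zeros(voronoi.shape, dtype=bool)
    boundary[:, :-1] |= voronoi[:, :-1] != voronoi[:, 1:]
    boundary[:, 1:] |= voronoi[:, :-1] != voronoi[:, 1:]
    boundary[:-1, :] |= voronoi[:-1, :] != voronoi[1:, :]
    boundary[1:, :] |= voronoi[:-1, :] != voronoi[1:, :]
    dist = ndi.distance_transform_edt(~boundary)
    return dist > boundary_width


def _paint_aggregates(shape: tuple[int, int], params: SceneParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Irregular bright blobs: unions of a few jittered disks per aggregate."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    r0 = params.aggregate_radius
    for _ in range(params.aggregate_count):
        cy = rng.uniform(r0, h - r0)
        cx = rng.uniform(r0, w - r0)
        for _ in range(3):
            oy, ox = rng.normal(0.0, r0 / 2.5, size=2)
            rad = r0 * rng.uniform(0.55, 0.95)
            mask |= (rr - (cy + oy)) ** 2 + (cc - (cx + ox)) ** 2 <= rad**2
    return mask


def _paint_collagen(interior_any: np.ndarray, params: SceneParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Grow collagen outward from the fiber-boundary network, staying
    interstitial, until collagen_fraction is met to within 0.5% of frame."""
    h, w = interior_any.shape
    total = h * w
    target = params.collagen_fraction * total
    tol = 0.005 * total
    wall = ~interior_any
    # seed line: pixels adjacent to two different interiors / the thinnest wall core
    dist_to_interior = ndi.distance_transform_edt(wall)
    seed = wall & (dist_to_interior >= max(dist_to_interior[wall].max() - 1.0, 1.0))
    mask = seed.copy()
    if mask.sum() > target + tol:
        # even the thinnest boundary line overshoots: thin it randomly
        idx = np.flatnonzero(mask)
        keep = rng.choice(idx, size=int(round(target)), replace=False)
        mask = np.zeros(total, dtype=bool)
        mask[keep] = True
        return mask.reshape(h, w)
    struct = ndi.generate_binary_structure(2, 2)
    while mask.sum() < target - tol:
        ring = ndi.binary_dilation(mask, structure=struct) & wall & ~mask
        n_ring = int(ring.sum())
        if n_ring == 0:
            achieved = mask.sum() / total
            raise ValueError(
                f"collagen_fraction {params.collagen_fraction} unreachable within "
                f"the interstitial space; achieved fraction {achieved:.4f}"
            )
        need = target - mask.sum()
        if n_ring <= need:
            mask |= ring
        else:
            idx = np.flatnonzero(ring.ravel())
            chosen = rng.choice(idx, size=int(round(need)), replace=False)
            flat = mask.ravel()
            flat[chosen] = True
            mask = flat.reshape(h, w)
    return mask


def generate_scene(params: SceneParams) -> SceneTruth:
    """Generate a scene's geometry, marker assignment and painted masks.

    Deterministic given ``params.seed``. Raises if any fiber's interior
    erodes away entirely (reduce n_fibers, fiber_jitter or
    boundary_width) or if the collagen target cannot be met.
    """
    rng = np.random.default_rng([params.seed, 0])
    voronoi = _voronoi_labels(params, rng)
    interior = _interior_mask(voronoi, params.boundary_width)
    raw_labels = np.where(interior, voronoi + 1, 0).astype(np.int32)
    n_present = np.unique(raw_labels[raw_labels > 0]).size
    if n_present != params.n_fibers:
        raise ValueError(
            f"{params.n_fibers - n_present} fiber interior(s) eroded away; "
            "reduce n_fibers, fiber_jitter or boundary_width"
        )
    label_map = _relabel_consecutive(raw_labels)
    areas = np.bincount(label_map.labels.ravel(), minlength=params.n_fibers + 1)[1:]

    # round-guard: 0.07 * 100 is 7.000000000000001 in binary floating point
    n_pos = int(np.ceil(round(params.marker_fraction * params.n_fibers, 9)))
    flags = np.zeros(params.n_fibers, dtype=bool)
    if n_pos > 0:
        if params.marker_size_bias == "small":
            pool_size = max(n_pos, int(np.ceil(0.25 * params.n_fibers)))
            pool = np.argsort(areas, kind="stable")[:pool_size]
        else:
            pool = np.arange(params.n_fibers)
        chosen = rng.choice(pool, size=n_pos, replace=False)
        flags[chosen] = True

    marker_mask = None
    if params.aggregate_count > 0 and params.collagen_fraction > 0:
        raise ValueError("a scene carries either aggregates or collagen, not both")
    if params.aggregate_count > 0:
        marker_mask = BinaryMask(
            _paint_aggregates(label_map.shape, params, rng).astype(np.uint8)
        )
    elif params.collagen_fraction > 0:
        marker_mask = BinaryMask(
            _paint_collagen(interior, params, rng).astype(np.uint8)
        )

    truth = SceneTruth(
        params=params,
        fiber_label_map=label_map,
        marker_flags=flags,
        fiber_areas=areas.astype(np.int64),
        marker_pixel_mask=marker_mask,
    )
    truth.summary = truth.recompute_summary()
    return truth


def _blur_noise(planes: dict[str, np.ndarray], params: SceneParams,
                rng: np.random.Generator) -> MultichannelImage:
    stack = []
    for name in ("red", "green", "blue"):
        p = planes[name]
        if params.blur_sigma > 0:
            p = ndi.gaussian_filter(p, params.blur_sigma)
        if params.noise_sd > 0:
            p = p + rng.normal(0.0, params.noise_sd, size=p.shape)
        stack.append(np.clip(p, 0.0, 1.0))
    return MultichannelImage(np.stack(stack, axis=-1), ("red", "green", "blue"))


def render_fluorescence(
    truth: SceneTruth, assay: str, params: SceneParams | None = None
) -> MultichannelImage:
    """Render a fluorescence image for the ebd, emyhc or cd68 assay.

    The laminin channel carries the boundary network at high intensity
    over dark interiors; the marker channel carries marker-positive fiber
    interiors (ebd, emyhc) or aggregate blobs (cd68) over a near-black
    background. Channel placement follows the staining conventions:
    ebd — laminin green / marker red; emyhc, cd68 — laminin red / marker
    green. Blur and noise are applied per channel, then clipped.
    """
    if assay not in _FLUOR_ASSAYS:
        raise ValueError(f"assay must be one of {_FLUOR_ASSAYS}, got {assay!r}")
    params = params or truth.params
    rng = np.random.default_rng([params.seed, 1])
    labels = truth.fiber_label_map.labels
    wall = labels == 0

    laminin = np.where(wall, LAMININ_HI, INTERIOR_LO)
    marker = np.full(labels.shape, MARKER_BG)
    if assay == "cd68":
        if truth.params.collagen_fraction > 0:
            raise ValueError("scene carries collagen, not macrophage aggregates")
        if truth.marker_pixel_mask is not None:
            blobs, n_blobs = ndi.label(truth.marker_pixel_mask.pixels)
            intensities = rng.uniform(*MARKER_RANGE, size=n_blobs + 1)
            marker = np.where(blobs > 0, intensities[blobs], marker)
    else:
        intensities = rng.uniform(*MARKER_RANGE, size=truth.marker_flags.size + 1)
        pos_labels = np.flatnonzero(truth.marker_flags) + 1
        pos = np.isin(labels, pos_labels)
        marker = np.where(pos, intensities[labels], marker)

    blue = np.full(labels.shape, MARKER_BG)
    if assay == "ebd":
        planes = {"red": marker, "green": laminin, "blue": blue}
    else:
        planes = {"red": laminin, "green": marker, "blue": blue}
    return _blur_noise(planes, params, rng)


def render_brightfield_collagen(
    truth: SceneTruth, params: SceneParams | None = None
) -> MultichannelImage:
    """Render a brightfield image of a Picrosirius-red-style stain.

    Collagen pixels are red-dominant and dark in green; muscle is pale,
    so the green plane carries the collagen contrast the quantification
    pipeline expects.
    """
    if truth.params.aggregate_count > 0:
        raise ValueError("scene carries macrophage aggregates, not collagen")
    params = params or truth.params
    rng = np.random.default_rng([params.seed, 2])
    if truth.marker_pixel_mask is not None:
        col = truth.marker_pixel_mask.pixels.astype(bool)
    else:  # collagen-free section: all muscle
        col = np.zeros(truth.fiber_label_map.shape, dtype=bool)
    planes = {}
    for i, name in enumerate(("red", "green", "blue")):
        planes[name] = np.where(col, COLLAGEN_RGB[i], MUSCLE_RGB[i])
    return _blur_noise(planes, params, rng)
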