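"""Pointwise image arithmetic and channel manipulation.

These are the building blocks the assay pipelines compose: inversion,
power-law masking, channel combination and channel splitting. All
operations are shape-preserving and keep intensities on [0, 1].
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .imgio import GrayImage, MultichannelImage

__all__ = ["invert", "power_transform", "combine_to_gray", "split_channels"]


def invert(img: MultichannelImage | GrayImage) -> MultichannelImage | GrayImage:
    """Map every intensity x to 1 - x, per channel."""
    if isinstance(img, MultichannelImage):
        return MultichannelImage(1.0 - img.pixels, img.channel_names, img.source_path)
    if isinstance(img, GrayImage):
        return GrayImage(1.0 - img.pixels)
    raise TypeError(f"invert expects an image, got {type(img).__name__}")


def power_transform(img: GrayImage, exponent: float = 2.0) -> GrayImage:
    """Raise every intensity to ``exponent`` (default: squaring).

    With exponent 2 this darkens mid-gray pixels while leaving values near
    1 nearly unchanged, which is how bright-marker fibers are masked out
    before object identification. The map is monotone, so pixel ordering
    is preserved.
    """
    if not exponent > 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    return GrayImage(np.power(img.pixels, exponent))


def combine_to_gray(
    img: MultichannelImage,
    channels: Sequence[str],
    weights: Sequence[float] | None = None,
) -> GrayImage:
    """Weighted mean of the selected channels.

    Weights are normalised to sum to 1 (default: equal), so the result
    cannot leave [0, 1].
    """
    channels = list(channels)
    if not channels:
        raise ValueError("at least one channel must be selected")
    for name in channels:
        if name not in img.channel_names:
            raise ValueError(f"unknown channel {name!r}; image has {img.channel_names}")
    if weights is None:
        w = np.full(len(channels), 1.0 / len(channels))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (len(channels),):
            raise ValueError("weights must match the number of selected channels")
        if not (w > 0).all():
            raise ValueError("weights must be positive")
        w = w / w.sum()
    planes = np.stack([img.pixels[:, :, img.channel_names.index(c)] for c in channels])
    return GrayImage(np.tensordot(w, planes, axes=1))


def split_channels(img: MultichannelImage) -> Mapping[str, GrayImage]:
    """Split into one GrayImage per channel, keyed by channel name."""
    return {name: img.channel(name) for name in img.channel_names}
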