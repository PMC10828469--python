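"""Slide-image preparation: downsampling, tissue masking, tiling, filtering,
channel normalization.

The working pipeline mirrors a standard histology preprocessing chain: a
high-magnification RGB image is block-mean downsampled to roughly 2x
context, cut into non-overlapping square tiles on a row-major grid, tiles
with too little tissue are discarded, and each colour channel is z-scored
so staining-batch intensity shifts do not dominate training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Tile",
    "PreprocessConfig",
    "downsample_image",
    "estimate_tissue_mask",
    "tile_image",
    "tissue_coverage",
    "filter_tiles",
    "normalize_channels",
    "pooled_channel_stats",
]


@dataclass
class Tile:
    """One RGB patch with its tissue mask and provenance.

    ``pixels`` is (H, W, 3), 8-bit for raw tiles or real-valued once
    normalized; ``tissue_mask`` is a (H, W) binary array of the same
    spatial shape; ``row``/``col`` are 0-based grid indices on the tile
    grid of the parent image.
    """

    pixels: np.ndarray
    tissue_mask: np.ndarray
    slide_id: str = ""
    row: int = 0
    col: int = 0
    age_months: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        mask = np.asarray(self.tissue_mask)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"tile pixels must be (H, W, 3), got {px.shape}")
        if mask.shape != px.shape[:2]:
            raise ValueError(
                f"tissue mask shape {mask.shape} does not match pixels {px.shape[:2]}"
            )
        self.pixels = px
        self.tissue_mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PreprocessConfig:
    tile_size: int = 512
    keep_every: int = 20
    downsample_factor: int = 20
    min_tissue_coverage: float = 0.90
    white_threshold: float = 220.0
    # z-score denominator: 0 -> population std (default), 1 -> sample std
    std_ddof: int = 0
    # normalize over the whole image (default) or per tile
    normalize_per_tile: bool = False

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.keep_every < 1:
            raise ValueError("keep_every must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if not 0.0 < self.min_tissue_coverage <= 1.0:
            raise ValueError("min_tissue_coverage must be in (0, 1]")


def downsample_image(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean pooling over ``factor`` x ``factor`` blocks per channel.

    Output dimensions are floor(input/factor) per axis; trailing rows and
    columns that do not fill a block are dropped.  Values are kept as reals
    internally; quantize to 8 bits only on export (``np.round`` applies
    round-half-to-even).
    """
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    px = np.asarray(pixels)
    if factor == 1:
        return px
    h, w = px.shape[:2]
    if h < factor or w < factor:
        raise ValueError(f"image {px.shape[:2]} smaller than downsample factor {factor}")
    hh, ww = h // factor, w // factor
    px = px[: hh * factor, : ww * factor].astype(np.float64)
    if px.ndim == 2:
        return px.reshape(hh, factor, ww, factor).mean(axis=(1, 3))
    return px.reshape(hh, factor, ww, factor, px.shape[2]).mean(axis=(1, 3))


def estimate_tissue_mask(pixels: np.ndarray, white_threshold: float = 220.0) -> np.ndarray:
    """Luminance-threshold tissue mask: tissue iff channel mean < threshold.

    A programmatic stand-in for interactive tissue outlining; on H&E-like
    images stained tissue is far darker than the near-white slide
    background, so a single luminance cut recovers the tissue region.
    """
    px = np.asarray(pixels, dtype=np.float64)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {px.shape}")
    return (px.mean(axis=2) < white_threshold).astype(np.uint8)


def tile_image(
    pixels: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig,
    slide_id: str = "",
    age_months: int | None = None,
) -> list[Tile]:
    """Cut a non-overlapping row-major tile grid and keep every k-th tile.

    Tiles cover half-open pixel intervals [r*s, (r+1)*s) x [c*s, (c+1)*s);
    partial edge tiles are discarded.  After gridding, tiles at row-major
    enumeration indices 0, k, 2k, ... (k = ``config.keep_every``) are
    retained.  An image smaller than the tile size yields an empty list.
    """
    px = np.asarray(pixels)
    mask = np.asarray(mask)
    if mask.shape[:2] != px.shape[:2]:
        raise ValueError("mask and image spatial shapes differ")
    s = config.tile_size
    n_rows, n_cols = px.shape[0] // s, px.shape[1] // s
    tiles: list[Tile] = []
    index = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if index % config.keep_every == 0:
                sl = (slice(r * s, (r + 1) * s), slice(c * s, (c + 1) * s))
                tiles.append(
                    Tile(
                        pixels=px[sl],
                        tissue_mask=mask[sl],
                        slide_id=slide_id,
                        row=r,
                        col=c,
                        age_months=age_months,
                    )
                )
            index += 1
    return tiles


def tissue_coverage(tile: Tile) -> float:
    """Fraction of tile pixels inside the tissue mask, in [0, 1]."""
    mask = np.asarray(tile.tissue_mask)
    return float((mask > 0).mean())


def filter_tiles(tiles: Sequence[Tile], min_coverage: float = 0.90) -> list[Tile]:
    """Keep tiles whose tissue coverage is >= ``min_coverage`` (inclusive).

    Order-preserving and idempotent; logs how many tiles were kept/dropped.
    """
    kept = [t for t in tiles if tissue_coverage(t) >= min_coverage]
    logger.info(
        "tissue-coverage filter (>= %.2f): kept %d of %d tiles",
        min_coverage,
        len(kept),
        len(tiles),
    )
    return kept


def normalize_channels(pixels: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Independently z-score each colour channel over all pixels.

    Returns a real-valued array whose non-constant channels have mean 0 and
    std 1 (population std by default).  A constant channel carries no
    intensity information and is set to all zeros with a logged warning.
    """
    px = np.asarray(pixels, dtype=np.float64)
    if px.ndim != 3:
        raise ValueError(f"expected (H, W, C), got {px.shape}")
    out = np.empty_like(px)
    for c in range(px.shape[2]):
        chan = px[:, :, c]
        mu = chan.mean()
        sd = chan.std(ddof=ddof)
        if sd == 0.0:
            logger.warning("channel %d is constant (value %g); normalized to all zeros", c, mu)
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = (chan - mu) / sd
    return out


def pooled_channel_stats(
    images: Sequence[np.ndarray], ddof: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std pooled over a collection of images.

    Used to normalize all tiles of one slide against the slide-wide
    statistics ("mean of all pixels in that channel") rather than per tile.
    """
    pooled = np.concatenate([np.asarray(im, dtype=np.float64).reshape(-1, 3) for im in images])
    return pooled.mean(axis=0), pooled.std(axis=0, ddof=ddof)
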