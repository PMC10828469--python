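"""Electronic Geropathology Scores from probability masks.

Each of the K-1 ordinal probability channels is rank-normalized to the
standard normal distribution (van der Waerden scores, Phi^-1(r/(n+1)) with
average ranks for ties), the normalized channels are averaged per pixel to
give the pixel-level eGPS, and a slide's score is the mean over its tissue
pixels.

The population the ranks are computed over matters.  Ranking each slide
against itself forces every slide mean toward zero (the scores are then a
permutation of fixed quantiles), destroying between-slide contrast.  The
reference distribution is therefore fitted once on the pooled tissue
pixels of a *cohort* (typically the training cohort, and storable in the
model checkpoint) and applied to each slide, which also lets single new
slides be scored without refitting anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "QuantileReference",
    "PixelEGPS",
    "SlideScore",
    "rank_to_normal",
    "fit_quantile_reference",
    "apply_reference",
    "pixel_egps",
    "slide_egps",
    "render_painting",
    "PAINTING_PALETTE",
]

# Fig-style legend palette: dark blue / royal blue / yellow / orange,
# youngest-looking to oldest-looking tissue.
PAINTING_PALETTE = (
    (0, 0, 139),
    (65, 105, 225),
    (255, 215, 0),
    (255, 140, 0),
)


def rank_to_normal(values: np.ndarray) -> np.ndarray:
    """Van der Waerden rank-normal scores: value with average-tie rank r
    among n maps to Phi^-1(r/(n+1)).

    Strictly increasing in value; ties map equal; extremes stay finite
    because r/(n+1) never reaches 0 or 1.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 1:
        raise ValueError("need at least one value")
    ranks = rankdata(v, method="average")
    return norm.ppf(ranks / (v.size + 1.0))


@dataclass(frozen=True)
class QuantileReference:
    """Per-channel empirical reference distributions for rank normalization.

    ``channels[i]`` is the sorted pooled sample of channel-i tissue-pixel
    probabilities from the reference cohort.
    """

    channels: tuple[np.ndarray, ...]
    cohort_id: str = ""

    def __post_init__(self) -> None:
        chans = tuple(np.ascontiguousarray(np.sort(np.asarray(c, dtype=np.float64).ravel())) for c in self.channels)
        if len(chans) < 1 or any(c.size < 1 for c in chans):
            raise ValueError("reference needs at least one value per channel")
        object.__setattr__(self, "channels", chans)

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def fit_quantile_reference(
    prob_masks: list[np.ndarray],
    tissue_masks: list[np.ndarray],
    cohort_id: str = "",
    max_size: int | None = None,
    seed: int = 0,
    min_pixels: int = 100,
) -> QuantileReference:
    """Pool tissue-pixel probabilities of a cohort per channel.

    ``prob_masks`` are (K-1, H, W) arrays, ``tissue_masks`` matching (H, W)
    binary arrays; one entry per tile (or per slide if already pooled).
    With ``max_size`` the pooled sample is deterministically subsampled.
    """
    if len(prob_masks) < 1 or len(prob_masks) != len(tissue_masks):
        raise ValueError("need equally many probability masks and tissue masks")
    k = prob_masks[0].shape[0]
    pooled: list[list[np.ndarray]] = [[] for _ in range(k)]
    for pm, tm in zip(prob_masks, tissue_masks):
        pm = np.asarray(pm, dtype=np.float64)
        sel = np.asarray(tm) > 0
        if pm.shape[0] != k or pm.shape[1:] != sel.shape:
            raise ValueError(f"mask shapes do not align: {pm.shape} vs {sel.shape}")
        for c in range(k):
            pooled[c].append(pm[c][sel])
    chans = []
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    for c in range(k):
        vals = np.concatenate(pooled[c]) if pooled[c] else np.empty(0)
        if vals.size < min_pixels:
            raise ValueError(
                f"channel {c}: only {vals.size} pooled tissue pixels (need >= {min_pixels})"
            )
        if max_size is not None and vals.size > max_size:
            vals = vals[rng.choice(vals.size, size=max_size, replace=False)]
        chans.append(np.sort(vals))
    return QuantileReference(tuple(chans), cohort_id=cohort_id)


def apply_reference(values: np.ndarray, ref_channel: np.ndarray) -> np.ndarray:
    """Map values to normal scores through a reference empirical CDF.

    Uses the mid-point convention: a value v with c_lt reference points
    below it and c_eq equal to it gets F(v) = (c_lt + (c_eq+1)/2)/(m+1),
    clipped to [1/(m+1), m/(m+1)], then Phi^-1.  Applying a reference to
    its own sample reproduces :func:`rank_to_normal` exactly; values
    outside the reference range hit the finite extreme quantiles rather
    than +/-inf.
    """
    a = np.asarray(ref_channel, dtype=np.float64).ravel()
    if a.size < 1:
        raise ValueError("empty reference channel")
    if not np.all(a[:-1] <= a[1:]):
        a = np.sort(a)
    v = np.asarray(values, dtype=np.float64)
    m = a.size
    lt = np.searchsorted(a, v, side="left")
    le = np.searchsorted(a, v, side="right")
    f = (lt + (le - lt + 1) / 2.0) / (m + 1.0)
    f = np.clip(f, 1.0 / (m + 1.0), m / (m + 1.0))
    return norm.ppf(f)


@dataclass
class PixelEGPS:
    """Pixel-level eGPS map (standard-normal scale) with its tissue mask.

    ``scores`` is (H, W); entries off tissue are NaN and excluded from all
    aggregation.
    """

    scores: np.ndarray
    tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        m = np.asarray(self.tissue_mask) > 0
        if s.shape != m.shape:
            raise ValueError(f"scores {s.shape} and mask {m.shape} differ")
        if m.any() and not np.isfinite(s[m]).all():
            raise ValueError("non-finite eGPS on tissue pixels")
        self.scores = s
        self.tissue_mask = m.astype(np.uint8)


@dataclass(frozen=True)
class SlideScore:
    slide_id: str
    egps: float
    age_months: int | None = None
    group: str | None = None
    treatment: str | None = None
    n_tissue_pixels: int = 0


def pixel_egps(
    prob_mask: np.ndarray, ref: QuantileReference, tissue_mask: np.ndarray
) -> PixelEGPS:
    """Rank-normalize each channel against the reference and average.

    Tissue-pixel probabilities of channel c are mapped through the
    reference CDF of channel c; the pixel score is the arithmetic mean of
    the K-1 normalized channels.  Non-tissue pixels are NaN-masked.
    """
    pm = np.asarray(prob_mask, dtype=np.float64)
    if pm.ndim != 3:
        raise ValueError(f"probability mask must be (K-1, H, W), got {pm.shape}")
    if pm.shape[0] != ref.n_channels:
        raise ValueError(
            f"probability mask has {pm.shape[0]} channels, reference has {ref.n_channels}"
        )
    sel = np.asarray(tissue_mask) > 0
    if sel.shape != pm.shape[1:]:
        raise ValueError("tissue mask shape does not match the probability mask")
    scores = np.full(sel.shape, np.nan)
    if sel.any():
        acc = np.zeros(int(sel.sum()))
        for c in range(ref.n_channels):
            acc += apply_reference(pm[c][sel], ref.channels[c])
        scores[sel] = acc / ref.n_channels
    return PixelEGPS(scores=scores, tissue_mask=sel)


def slide_egps(pixel_maps: PixelEGPS | list[PixelEGPS]) -> float:
    """Mean eGPS over tissue pixels (of one map or across a slide's tiles)."""
    maps = [pixel_maps] if isinstance(pixel_maps, PixelEGPS) else list(pixel_maps)
    total, count = 0.0, 0
    for pm in maps:
        sel = pm.tissue_mask > 0
        total += float(pm.scores[sel].sum())
        count += int(sel.sum())
    if count == 0:
        raise ValueError("slide has no tissue pixels to score")
    return total / count


def render_painting(
    pixel: PixelEGPS,
    breakpoints: tuple[float, float, float] | None = None,
    palette: tuple[tuple[int, int, int], ...] = PAINTING_PALETTE,
    continuous: bool = False,
) -> np.ndarray:
    """Colour heat map ("painting") of a pixel eGPS map; returns (H, W, 3) uint8.

    In the default quantized mode the three ``breakpoints`` split the score
    range into four bands rendered with the legend palette (dark blue ->
    royal blue -> yellow -> orange, youngest to oldest); breakpoints are
    typically the quartiles of the reference cohort's slide scores, and
    default to this map's own tissue-score quartiles.  In continuous mode
    scores are ramped linearly through the palette between the 1st and
    99th tissue percentile.  Non-tissue pixels render white.
    """
    sel = pixel.tissue_mask > 0
    out = np.full(pixel.scores.shape + (3,), 255, dtype=np.uint8)
    if not sel.any():
        return out
    s = pixel.scores[sel]
    pal = np.asarray(palette, dtype=np.float64)
    if continuous:
        lo, hi = np.percentile(s, [1, 99])
        t = np.clip((s - lo) / (hi - lo) if hi > lo else np.zeros_like(s), 0.0, 1.0)
        pos = t * (len(pal) - 1)
        i = np.minimum(pos.astype(int), len(pal) - 2)
        frac = (pos - i)[:, None]
        colors = (pal[i] * (1 - frac) + pal[i + 1] * frac).round().astype(np.uint8)
    else:
        if breakpoints is None:
            breakpoints = tuple(np.percentile(s, [25, 50, 75]))
        bands = np.searchsorted(np.asarray(breakpoints, dtype=np.float64), s, side="right")
        colors = pal[bands].astype(np.uint8)
    out[sel] = colors
    return out
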