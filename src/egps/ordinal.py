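"""Ordinal age labels and pixel-level ordinal masks.

Chronological age is encoded as a cumulative binary chain over an ordered
schedule of K age groups: the label has K-1 bits and bit ``i`` is set iff
the sample is *older than* the i-th schedule age.  Under the default murine
schedule (8, 16, 20, 32 months) an 8-month sample encodes to (0,0,0) and a
20-month sample to (1,1,0).  Valid labels are exactly the chain vectors
whose ones form a prefix, so ``sum(bits)`` is the 0-based age-group index.

The pixel-level training target (the *ordinal mask*) broadcasts the slide
label over the tissue mask: channel ``i`` equals the tissue mask wherever
``bits[i] = 1`` and is zero elsewhere; background pixels are zero in every
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgeSchedule",
    "OrdinalLabel",
    "encode_ordinal",
    "label_to_group",
    "build_ordinal_mask",
    "save_ordinal_mask",
    "load_ordinal_mask",
]


@dataclass(frozen=True)
class AgeSchedule:
    """Ordered chronological age groups, in months."""

    ages: tuple[int, ...] = (8, 16, 20, 32)

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.ages)
        if len(ages) < 2:
            raise ValueError("an age schedule needs at least 2 groups")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"schedule ages must be strictly increasing, got {ages}")
        object.__setattr__(self, "ages", ages)

    @property
    def n_groups(self) -> int:
        return len(self.ages)

    @property
    def n_channels(self) -> int:
        """Number of ordinal channels (K-1)."""
        return len(self.ages) - 1

    def group_index(self, age_months: int) -> int:
        if age_months not in self.ages:
            raise ValueError(f"age {age_months} months is not in the schedule {self.ages}")
        return self.ages.index(age_months)


@dataclass(frozen=True)
class OrdinalLabel:
    """Cumulative binary chain vector of length K-1 (ones form a prefix)."""

    bits: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"label bits must be binary, got {bits}")
        if any(a < b for a, b in zip(bits, bits[1:])):
            raise ValueError(f"label {bits} violates the chain invariant (ones must form a prefix)")
        object.__setattr__(self, "bits", bits)

    def __iter__(self):
        return iter(self.bits)

    def __len__(self) -> int:
        return len(self.bits)


def encode_ordinal(age_months: int, schedule: AgeSchedule = AgeSchedule()) -> OrdinalLabel:
    """Encode a chronological age as its cumulative chain label.

    Bit ``i`` is 1 iff ``age_months > schedule.ages[i]`` for the first K-1
    schedule ages.  (The alternative "less-than-or-equal" reading would give
    a 20-month sample the all-ones label, which contradicts the convention
    fixed here; strict greater-than reproduces (0,0,0) for the youngest and
    (1,1,0) for the third of four groups.)
    """
    if age_months not in schedule.ages:
        raise ValueError(f"age {age_months} months is not in the schedule {schedule.ages}")
    return OrdinalLabel(tuple(1 if age_months > a else 0 for a in schedule.ages[:-1]))


def label_to_group(label: OrdinalLabel | tuple[int, ...], schedule: AgeSchedule = AgeSchedule()) -> int:
    """Inverse of :func:`encode_ordinal`: chain label -> age in months."""
    if not isinstance(label, OrdinalLabel):
        label = OrdinalLabel(tuple(label))
    if len(label) != schedule.n_channels:
        raise ValueError(
            f"label has {len(label)} bits but the schedule {schedule.ages} needs {schedule.n_channels}"
        )
    return schedule.ages[sum(label.bits)]


def build_ordinal_mask(tissue_mask: np.ndarray, label: OrdinalLabel | tuple[int, ...]) -> np.ndarray:
    """Expand a slide-level chain label into a (K-1, H, W) binary target.

    Channel ``i`` equals the tissue mask where ``bits[i] = 1`` and is all
    zero otherwise, so non-tissue pixels are zero in every channel and the
    per-pixel channel values are non-increasing (the chain is preserved
    pixelwise).
    """
    if not isinstance(label, OrdinalLabel):
        label = OrdinalLabel(tuple(label))
    mask = np.asarray(tissue_mask)
    if mask.ndim != 2:
        raise ValueError(f"tissue mask must be 2-D, got shape {mask.shape}")
    binary = (mask > 0).astype(np.uint8)
    bits = np.asarray(label.bits, dtype=np.uint8)
    return bits[:, None, None] * binary[None, :, :]


def save_ordinal_mask(path, mask: np.ndarray) -> None:
    """Persist a (K-1, H, W) binary ordinal mask as a multi-page TIFF."""
    import tifffile

    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"ordinal mask must be (K-1, H, W), got {mask.shape}")
    tifffile.imwrite(path, (mask > 0).astype(np.uint8), photometric="minisblack")


def load_ordinal_mask(path) -> np.ndarray:
    """Load a multi-page TIFF ordinal mask back as (K-1, H, W) uint8."""
    import tifffile

    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    return (arr > 0).astype(np.uint8)
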