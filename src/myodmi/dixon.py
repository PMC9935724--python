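"""Two-point Dixon water-fat separation and fat-fraction mapping.

At 3 T, echoes at TE = 1.23 ms (opposed-phase) and 2.46 ms (in-phase) give
magnitude images where in-phase = water + fat and opposed-phase =
|water - fat|. Under the water-dominant convention the separation is

    water = (IP + OP) / 2,    fat = (IP - OP) / 2,

and the fat fraction is FF = 100 * fat / (fat + water). Magnitude-only
separation caps FF at 50% physically; fat-water swap resolution is out of
scope. Noise can push OP above IP, in which case fat is clamped to zero and
the voxel flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: voxels whose water+fat signal falls below this fraction of the image's
#: 99th-percentile intensity are treated as background (FF undefined)
BACKGROUND_FRACTION = 0.01


@dataclass
class FatFractionMap:
    """Fat fraction in percent; NaN outside ``valid_mask``."""

    ff: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        ff = np.asarray(self.ff, dtype=float)
        vals = ff[self.valid_mask]
        if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
            raise ValidationError("fat fraction outside [0, 100] at valid voxels")
        self.ff = ff


def separate_water_fat(in_phase, opposed_phase):
    """Magnitude two-point separation.

    Returns ``(water, fat, clamped)`` where ``clamped`` flags voxels with
    OP > IP (noise), whose fat was clipped to 0.
    """
    ip = np.asarray(in_phase, dtype=float)
    op = np.asarray(opposed_phase, dtype=float)
    if ip.shape != op.shape:
        raise ValidationError(
            f"grid mismatch: in-phase {ip.shape} vs opposed-phase {op.shape}"
        )
    if np.any(ip < 0) or np.any(op < 0):
        raise ValidationError("Dixon magnitudes must be nonnegative")
    water = (ip + op) / 2.0
    fat = (ip - op) / 2.0
    clamped = fat < 0
    fat = np.where(clamped, 0.0, fat)
    return water, fat, clamped


def fat_fraction(water, fat, background_threshold=None) -> FatFractionMap:
    """FF = 100 * fat / (fat + water), NaN where total signal is background.

    ``background_threshold`` is an absolute water+fat level; by default it is
    :data:`BACKGROUND_FRACTION` of the 99th percentile of water+fat.
    """
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if water.shape != fat.shape:
        raise ValidationError(f"grid mismatch: water {water.shape} vs fat {fat.shape}")
    if np.any(water < 0) or np.any(fat < 0):
        raise ValidationError("water/fat images must be nonnegative")
    total = water + fat
    if background_threshold is None:
        scale = np.percentile(total, 99) if total.size else 0.0
        background_threshold = BACKGROUND_FRACTION * scale
    valid = total > max(background_threshold, 0.0)
    ff = np.full(total.shape, np.nan)
    ff[valid] = 100.0 * fat[valid] / total[valid]
    return FatFractionMap(ff=ff, valid_mask=valid)


def fat_fraction_from_echoes(in_phase, opposed_phase,
                             background_threshold=None) -> FatFractionMap:
    """Convenience entry point: echo pair straight to the FF map."""
    water, fat, _ = separate_water_fat(in_phase, opposed_phase)
    return fat_fraction(water, fat, background_threshold=background_threshold)


__all__ = [
    "FatFractionMap",
    "separate_water_fat",
    "fat_fraction",
    "fat_fraction_from_echoes",
    "BACKGROUND_FRACTION",
]
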