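"""Volume-of-interest reduction and per-subject derived ratios.

Voxel maps are reduced to per-muscle means over labeled VOIs; subject rows
are completed with the external/internal rotation strength ratios (the
clinical imbalance measure, grouped at the 0.95 cutoff) and the
infraspinatus/subscapularis ratio of each imaging metric.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .io_formats import MuscleMask

#: ER/IR mean-strength ratio separating "low" (relative external-rotator
#: weakness) from "high"; the exact-cutoff tie goes to "high".
ER_IR_CUTOFF = 0.95

IMAGING_METRICS = ("v_intra", "v_extra", "v_iso", "ff")


def voi_mean(map_data, mask: MuscleMask, label: int) -> float:
    """Mean of a 3D map over one labeled VOI, ignoring NaN voxels."""
    data = np.asarray(map_data, dtype=float)
    if data.shape != mask.labels.shape:
        raise ValidationError(
            f"grid mismatch: map {data.shape} vs mask {mask.labels.shape}"
        )
    sel = mask.labels == label
    if not sel.any():
        raise ValidationError(f"label {label} has no voxels in the mask")
    vals = data[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"all voxels of label {label} are invalid (NaN)")
    return float(vals.mean())


def extract_subject_metrics(compartments, ff_map, mask: MuscleMask) -> dict:
    """Per-muscle VOI means of the fraction and FF maps.

    Returns ``{"<muscle>_v_intra": ..., ..., "<muscle>_ff": ...}`` keyed by
    lower-cased muscle names from the mask's label map.
    """
    out = {}
    for label, name in mask.muscles().items():
        key = name.lower()
        out[f"{key}_v_intra"] = voi_mean(compartments.v_intra, mask, label)
        out[f"{key}_v_extra"] = voi_mean(compartments.v_extra, mask, label)
        out[f"{key}_v_iso"] = voi_mean(compartments.v_iso, mask, label)
        out[f"{key}_ff"] = voi_mean(ff_map.ff, mask, label)
    return out


def derive_ratios(record: dict) -> dict:
    """Complete a subject record with ER/IR and ISP/SSC ratios.

    ``er_ir_ratio_mean`` (and ``_max``) divide external- by internal-rotation
    strength; the group split uses the mean-strength ratio with ties at the
    cutoff assigned to "high". ``isp_ssc_<metric>`` divides the ISP value by
    the SSC value for each imaging metric present. The input mapping is not
    mutated.
    """
    out = dict(record)
    for kind in ("mean", "max"):
        er = out.get(f"external_rotation_{kind}_kg")
        ir = out.get(f"internal_rotation_{kind}_kg")
        if er is not None and ir is not None:
            if ir <= 0 or er <= 0:
                raise ValidationError("strength values must be positive")
            out[f"er_ir_ratio_{kind}"] = er / ir
    if "er_ir_ratio_mean" in out:
        out["er_ir_group"] = (
            "high" if out["er_ir_ratio_mean"] >= ER_IR_CUTOFF else "low"
        )
    for metric in IMAGING_METRICS:
        isp = out.get(f"isp_{metric}")
        ssc = out.get(f"ssc_{metric}")
        if isp is not None and ssc is not None:
            if ssc == 0:
                raise ValidationError(f"zero SSC {metric} in ISP/SSC ratio")
            out[f"isp_ssc_{metric}"] = isp / ssc
    return out


__all__ = [
    "ER_IR_CUTOFF",
    "IMAGING_METRICS",
    "voi_mean",
    "extract_subject_metrics",
    "derive_ratios",
]
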