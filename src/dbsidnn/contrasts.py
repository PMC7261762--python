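"""Magnetization-transfer ratio, CSF-baseline normalization, and
intensity-ratio (IR) lesion typing.

Lesion classes
--------------
White-matter lesions are graded by how dark they are on T1-weighted images
relative to CSF. The intensity ratio IR = lesion T1 / CSF T1 falls into
three printed bands: 1.00-1.70 (black hole), 1.71-2.60 (gray hole),
> 2.60 (neither). Holes inside a contrast-enhancing lesion are *acute*
(ABH/AGH); holes persisting >= 12 months without enhancement are
*persistent* (PBH/PGH). T2-hyperintense lesions without T1 hypointensity
are NBH; normal-appearing white matter (NAWM) is neither hypointense on T1
nor hyperintense on T2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: the five modelled classes, in canonical order (ABH is recognized by the
#: labeler but excluded from modelling)
CLASSES = ("PBH", "PGH", "AGH", "NBH", "NAWM")
UNCLASSIFIED = "unclassified"

# printed IR bands, closed on both ends; values are rounded to 2 decimals
# before comparison so the bins are contiguous
BLACK_HOLE_RANGE = (1.00, 1.70)
GRAY_HOLE_RANGE = (1.71, 2.60)

CSF_MIN_VOXELS = 100


@dataclass
class LesionRecord:
    """One labeled ROI: identity, class, IR, flags, and its voxel rows."""

    lesion_id: str
    lesion_class: str
    ir_t1: float
    enhancing: bool = False
    persistent_12mo: bool = False
    t2_hyperintense: bool = False
    n_voxels: int = 0
    voxel_rows: object = None  # DataFrame slice or None

    def __post_init__(self):
        if self.ir_t1 <= 0:
            raise ValidationError(f"lesion {self.lesion_id}: ir_t1 must be > 0")
        valid = CLASSES + ("ABH", UNCLASSIFIED)
        if self.lesion_class not in valid:
            raise ValidationError(
                f"lesion {self.lesion_id}: unknown class {self.lesion_class!r}"
            )


def compute_mtr(s_off, s_on):
    """Magnetization transfer ratio in percent: (S_off - S_on) / S_off * 100.

    Scalars map to a float; arrays map elementwise, with voxels where
    ``s_off <= 0`` masked to NaN (they carry no MT information).
    """
    scalar = np.isscalar(s_off) and np.isscalar(s_on)
    s_off = np.asarray(s_off, dtype=float)
    s_on = np.asarray(s_on, dtype=float)
    if s_off.shape != s_on.shape:
        raise ValidationError(
            f"MT-off shape {s_off.shape} does not match MT-on shape {s_on.shape}"
        )
    if scalar:
        if s_off <= 0:
            raise ValidationError("s_off must be > 0")
        return float((s_off - s_on) / s_off * 100.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (s_off - s_on) / s_off * 100.0
    return np.where(s_off > 0, mtr, np.nan)


def csf_baseline(intensities, min_voxels: int = CSF_MIN_VOXELS, statistic: str = "mean") -> float:
    """Baseline intensity of a CSF region (default: mean of >= 100 voxels).

    Constructing the anatomical mask (widest anterior-horn slices,
    choroid-plexus and 2-voxel ventricle-edge exclusion) is the caller's
    responsibility; this function only summarizes the sampled intensities.
    """
    values = np.asarray(intensities, dtype=float).ravel()
    if values.size < min_voxels:
        raise ValidationError(
            f"CSF region has {values.size} voxels; at least {min_voxels} are required"
        )
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    raise ValidationError(f"unknown CSF statistic {statistic!r}")


def normalize_to_csf(volume, baseline: float):
    """Divide intensities by the CSF baseline (applied identically to b0,
    T1-weighted, and T2-weighted volumes)."""
    if baseline <= 0:
        raise ValidationError(f"CSF baseline must be > 0, got {baseline}")
    return np.asarray(volume, dtype=float) / baseline


def classify_lesion(
    ir_t1: float,
    enhancing: bool = False,
    persistent_12mo: bool = False,
    t2_hyperintense: bool = False,
) -> str:
    """Assign a lesion class from its T1 intensity ratio and flags.

    IR is rounded to 2 decimals so the printed bands tile the line. IR below
    1.00 (darker than CSF) maps to the black-hole band with a warning. Holes
    with neither the enhancing nor the persistence flag get the explicit
    ``"unclassified"`` code rather than being dropped.
    """
    if ir_t1 <= 0:
        raise ValidationError(f"ir_t1 must be > 0, got {ir_t1}")
    ir = round(float(ir_t1), 2)
    if ir < BLACK_HOLE_RANGE[0]:
        warnings.warn(
            f"IR = {ir_t1:.3g} is below 1.00 (darker than CSF); treating as black-hole range",
            stacklevel=2,
        )
        ir = BLACK_HOLE_RANGE[0]
    if ir <= BLACK_HOLE_RANGE[1]:
        hole = "BH"
    elif ir <= GRAY_HOLE_RANGE[1]:
        hole = "GH"
    else:
        return "NBH" if t2_hyperintense else "NAWM"
    if enhancing:
        return "A" + hole
    if persistent_12mo:
        return "P" + hole
    return UNCLASSIFIED


@dataclass
class LesionTable:
    """Convenience container for a set of lesion records."""

    lesions: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "lesion_id": l.lesion_id,
                    "lesion_class": l.lesion_class,
                    "ir_t1": l.ir_t1,
                    "enhancing": l.enhancing,
                    "persistent_12mo": l.persistent_12mo,
                    "t2_hyperintense": l.t2_hyperintense,
                    "n_voxels": l.n_voxels,
                }
                for l in self.lesions
            ]
        )
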