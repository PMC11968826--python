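"""Per-nucleus p-c-Jun quantification in retinal ganglion cells.

Retrograde DLK signaling after optic nerve injury is read out as the
phospho-c-Jun intensity inside RGC nuclei of retinal flat mounts. RGC
nuclei are the connected components of the intersection of the
auto-thresholded DAPI and Brn3a masks; per-nucleus mean p-c-Jun
intensities are averaged per field, and exactly three fields average
to one value per eye (the experimental *n*). Inputs are 2-D
maximum-intensity projections, which the caller prepares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .imaging_core import (
    ImageGrid,
    LabelMap,
    channel_mask_or_empty,
    label_and_measure,
    mask_and,
)

__all__ = ["RGCFieldResult", "EyeResult", "rgc_nuclear_mask", "pcjun_field_means", "pcjun_per_eye"]

FIELDS_PER_EYE = 3


@dataclass(frozen=True)
class RGCFieldResult:
    field_id: str
    n_rgc: int
    per_nucleus_means: tuple[float, ...]
    field_mean: float


@dataclass(frozen=True)
class EyeResult:
    eye_id: str
    field_means: tuple[float, ...]
    eye_value: float
    undefined: bool = False


def rgc_nuclear_mask(
    dapi: ImageGrid,
    brn3a: ImageGrid,
    threshold_method: str = "default_isodata",
) -> LabelMap:
    """Label RGC nuclei: connected components of the DAPI AND Brn3a
    foreground masks (each channel auto-thresholded, IsoData by
    default). Nuclei touching the field border are included."""
    if dapi.shape != brn3a.shape:
        raise ValueError("dapi/brn3a shape mismatch")
    both = mask_and(
        channel_mask_or_empty(dapi, threshold_method),
        channel_mask_or_empty(brn3a, threshold_method),
    )
    labels, _ = label_and_measure(both)
    return labels


def pcjun_field_means(
    pcjun: ImageGrid, nuclei: LabelMap, field_id: str = "field"
) -> RGCFieldResult:
    """Mean p-c-Jun intensity within each labeled RGC nucleus, plus the
    unweighted field mean over nuclei."""
    if pcjun.shape != nuclei.shape:
        raise ValueError("pcjun/nuclei shape mismatch")
    px = pcjun.pixels
    means = []
    lab = nuclei.labels
    for k in range(1, nuclei.n_objects + 1):
        means.append(float(px[lab == k].mean()))
    field_mean = math.nan if not means else sum(means) / len(means)
    return RGCFieldResult(
        field_id=field_id,
        n_rgc=len(means),
        per_nucleus_means=tuple(means),
        field_mean=field_mean,
    )


def pcjun_per_eye(
    pcjun_fields: list[ImageGrid],
    nuclei: list[LabelMap],
    eye_id: str = "eye",
) -> EyeResult:
    """Aggregate exactly three fields to one per-eye value.

    Field means are unweighted by nucleus count; a field with zero
    nuclei is excluded with a warning, and an eye with no nuclei in any
    field is undefined (NaN), never silently zero.
    """
    if len(pcjun_fields) != FIELDS_PER_EYE or len(nuclei) != FIELDS_PER_EYE:
        raise ValueError(f"exactly {FIELDS_PER_EYE} (field, labelmap) pairs are required")
    field_means = []
    for i, (img, lab) in enumerate(zip(pcjun_fields, nuclei)):
        res = pcjun_field_means(img, lab, field_id=f"{eye_id}_f{i}")
        if res.n_rgc == 0:
            warnings.warn(f"{eye_id}: field {i} has no RGC nuclei; excluded", stacklevel=2)
            continue
        field_means.append(res.field_mean)
    if not field_means:
        return EyeResult(eye_id, (), math.nan, undefined=True)
    return EyeResult(
        eye_id=eye_id,
        field_means=tuple(field_means),
        eye_value=sum(field_means) / len(field_means),
    )
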