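"""Axon-level readouts from cultured DRG neuron fields.

Three assays quantify the axonal phenotypes of DLK-pathway
perturbation: the fraction of axonal area occupied by marker
accumulations, the density of vesicle-scale puncta normalized to axon
coverage, and a watershed-based axon integrity index that counts long,
continuous, low-circularity structures in inverted phase-contrast
images (high in healthy cultures, falling as axons bleb and fragment).
Cell bodies are removed via an explicit mask input — the manual
deletion step of the bench protocol made reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging_core import (
    ImageGrid,
    channel_mask_or_empty,
    h_watershed_segment,
    label_and_measure,
)

__all__ = [
    "AxonFieldResult",
    "accumulation_fraction",
    "axonal_puncta_density",
    "axon_integrity_index",
    "ACCUM_CIRC_DLK_VAMP2",
    "ACCUM_CIRC_NF200_TUJ1",
]

# Circularity windows for accumulation detection, by marker class.
ACCUM_CIRC_DLK_VAMP2 = (0.2, 1.0)
ACCUM_CIRC_NF200_TUJ1 = (0.4, 1.0)


@dataclass(frozen=True)
class AxonFieldResult:
    """One assay value for one field."""

    assay: str
    value: float
    n_objects: int
    axon_area_fraction: float
    undefined: bool = False


def accumulation_fraction(
    marker: ImageGrid,
    circ_window: tuple[float, float] = ACCUM_CIRC_DLK_VAMP2,
    min_area: int = 200,
    max_area: float = 1500,
    threshold_method: str = "default_isodata",
) -> AxonFieldResult:
    """Fraction of thresholded axonal area occupied by marker
    accumulations (particles of 200-1500 px within the marker class's
    circularity window: 0.2-1.0 for DLK/VAMP2, 0.4-1.0 for NF200/Tuj1).

    The denominator is the total thresholded area of the same channel.
    An empty thresholded channel yields an undefined result.
    """
    mask = channel_mask_or_empty(marker, method=threshold_method)
    axon_area = int(mask.sum())
    total = marker.pixels.size
    if axon_area == 0:
        return AxonFieldResult("accumulation_fraction", math.nan, 0, 0.0, undefined=True)
    _, stats = label_and_measure(
        mask,
        min_area=min_area,
        max_area=max_area,
        min_circ=circ_window[0],
        max_circ=circ_window[1],
    )
    accum_area = sum(s.area_px for s in stats)
    return AxonFieldResult(
        assay="accumulation_fraction",
        value=accum_area / axon_area,
        n_objects=len(stats),
        axon_area_fraction=axon_area / total,
    )


def axonal_puncta_density(
    myc: ImageGrid,
    tuj1: ImageGrid,
    cellbody_mask: np.ndarray,
    min_area: int = 4,
    max_area: float = 10,
    min_circ: float = 0.70,
    max_circ: float = 1.00,
    threshold_method: str = "default_isodata",
) -> AxonFieldResult:
    """Vesicle-scale puncta (4-10 px, circularity 0.70-1.00) in the myc
    channel outside the cell-body mask, normalized to the fraction of
    the field occupied by axons (auto-thresholded Tuj1 channel)."""
    if cellbody_mask.shape != myc.shape:
        raise ValueError("cellbody_mask/myc shape mismatch")
    if tuj1.shape != myc.shape:
        raise ValueError("tuj1/myc shape mismatch")
    axon_mask = channel_mask_or_empty(tuj1, method=threshold_method)
    axon_fraction = float(axon_mask.sum()) / tuj1.pixels.size
    if axon_fraction == 0:
        return AxonFieldResult("puncta_density", math.nan, 0, 0.0, undefined=True)
    myc_mask = channel_mask_or_empty(myc, method=threshold_method)
    myc_mask &= ~np.asarray(cellbody_mask, dtype=bool)
    _, stats = label_and_measure(
        myc_mask,
        min_area=min_area,
        max_area=max_area,
        min_circ=min_circ,
        max_circ=max_circ,
    )
    return AxonFieldResult(
        assay="puncta_density",
        value=len(stats) / axon_fraction,
        n_objects=len(stats),
        axon_area_fraction=axon_fraction,
    )


def axon_integrity_index(
    phase: ImageGrid,
    cellbody_mask: np.ndarray,
    seed_dynamics: float = 40.0,
    intensity_threshold: float = 200.0,
    peak_flooding: float = 100.0,
    min_area: int = 400,
    max_circ: float = 0.3,
) -> AxonFieldResult:
    """Axon integrity index from a phase-contrast field.

    Pipeline: blank out cell bodies, invert the 8-bit image (axons are
    dark in phase contrast; inversion makes them bright ridges), run
    the H-maxima watershed (seed dynamics 40, intensity threshold 200,
    peak flooding 100%, splitting disabled), then keep elongated
    continuous structures (area >= 400 px, circularity 0.0-0.3). The
    index is the surviving-structure count per megapixel of field.
    """
    if phase.bit_depth != 8:
        raise ValueError("axon integrity expects an 8-bit phase image")
    if cellbody_mask.shape != phase.shape:
        raise ValueError("cellbody_mask/phase shape mismatch")
    px = phase.pixels.copy()
    px[np.asarray(cellbody_mask, dtype=bool)] = 255  # bright background in phase
    inverted = ImageGrid(px).invert()
    labels = h_watershed_segment(
        inverted,
        seed_dynamics=seed_dynamics,
        intensity_threshold=intensity_threshold,
        peak_flooding=peak_flooding,
        allow_splitting=False,
    )
    support = labels.labels > 0
    _, stats = label_and_measure(
        support, min_area=min_area, max_area=math.inf, min_circ=0.0, max_circ=max_circ
    )
    megapixels = phase.pixels.size / 1e6
    return AxonFieldResult(
        assay="integrity_index",
        value=len(stats) / megapixels,
        n_objects=len(stats),
        axon_area_fraction=float(support.sum()) / phase.pixels.size,
    )
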