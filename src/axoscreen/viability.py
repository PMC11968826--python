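"""Calcein-AM / Hoechst viable-cell counting and 4-parameter-logistic
IC50 estimation for dose-response viability assays."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .imaging_core import (
    ImageGrid,
    channel_mask_or_empty,
    label_and_measure,
    mask_and,
)

__all__ = [
    "ViabilityResult",
    "DoseResponse",
    "IC50Fit",
    "count_viable_cells",
    "fit_dose_response_ic50",
    "dose_response_from_frame",
]


@dataclass(frozen=True)
class ViabilityResult:
    field_id: str
    viable_count: int


def count_viable_cells(
    calcein: ImageGrid,
    hoechst: ImageGrid,
    field_id: str = "field",
    min_area: int = 500,
    max_area: float = math.inf,
    min_circ: float = 0.8,
    max_circ: float = 1.0,
) -> ViabilityResult:
    """Count Calcein/Hoechst double-positive (viable) somata.

    The Calcein channel is auto-thresholded in the *Default* (IsoData)
    mode and the Hoechst channel in the *Moments* mode; the masks are
    intersected and particles of 500 px to infinity with circularity
    0.8-1.0 are counted.
    """
    if calcein.shape != hoechst.shape:
        raise ValueError("calcein/hoechst shape mismatch")
    both = mask_and(
        channel_mask_or_empty(calcein, "default_isodata"),
        channel_mask_or_empty(hoechst, "moments"),
    )
    _, stats = label_and_measure(
        both, min_area=min_area, max_area=max_area, min_circ=min_circ, max_circ=max_circ
    )
    return ViabilityResult(field_id=field_id, viable_count=len(stats))


@dataclass(frozen=True)
class DoseResponse:
    """Mean viable counts per dose for one compound.

    ``doses`` in µM (the bench format is an 8-point 2-fold serial
    dilution, 0.3125-20 µM); ``responses`` are the per-dose mean viable
    counts after averaging technical replicates (and biological
    replicates, in that order).
    """

    compound_id: str
    doses: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.doses)) < 4:
            raise ValueError("4PL fitting requires >= 4 distinct doses")
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must align")
        if any(r < 0 for r in self.responses):
            raise ValueError("responses must be non-negative")


@dataclass(frozen=True)
class IC50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool


def _four_pl(x: np.ndarray, log_ic50: float, hill: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(x) - log_ic50)))


def dose_response_from_frame(frame: pd.DataFrame, compound_id: str) -> DoseResponse:
    """Aggregate a replicate-level table (compound_id, dose_uM,
    replicate, viable_count) into per-dose means for one compound.
    Technical replicates are averaged within each (dose, replicate
    batch) and batches averaged per dose, mirroring the bench
    aggregation order."""
    sub = frame[frame["compound_id"] == compound_id]
    if sub.empty:
        raise ValueError(f"no rows for compound {compound_id!r}")
    if "replicate" in sub.columns:
        per_rep = sub.groupby(["dose_uM", "replicate"])["viable_count"].mean()
        per_dose = per_rep.groupby("dose_uM").mean()
    else:
        per_dose = sub.groupby("dose_uM")["viable_count"].mean()
    per_dose = per_dose.sort_index(ascending=False)
    return DoseResponse(
        compound_id=compound_id,
        doses=tuple(float(d) for d in per_dose.index),
        responses=tuple(float(v) for v in per_dose.to_numpy()),
    )


def fit_dose_response_ic50(
    data: DoseResponse,
    dynamic_range_frac: float = 0.10,
) -> IC50Fit:
    """Least-squares 4PL fit ``y = bottom + (top-bottom)/(1+(x/ic50)^hill)``
    on log-dose, with a variable Hill slope.

    The IC50 is constrained to [min dose / 10, max dose x 10].
    Initialization: top/bottom from the max/min responses, IC50 at the
    dose bracketing half-range, hill = 1. Data whose dynamic range is
    below ``dynamic_range_frac`` of the top response (monotone-flat
    curves) yield an undefined IC50 with ``converged=False``.
    """
    x = np.asarray(data.doses, dtype=float)
    y = np.asarray(data.responses, dtype=float)
    top0 = float(y.max())
    bot0 = float(y.min())
    if top0 <= 0 or (top0 - bot0) < dynamic_range_frac * top0:
        return IC50Fit(math.nan, math.nan, top0, bot0, converged=False)
    half = (top0 + bot0) / 2.0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    below = np.nonzero(ys <= half)[0]
    ic50_0 = float(xs[below[0]]) if below.size else float(np.sqrt(xs[0] * xs[-1]))
    lo, hi = x.min() / 10.0, x.max() * 10.0
    ic50_0 = min(max(ic50_0, lo), hi)
    try:
        popt, _ = curve_fit(
            _four_pl,
            x,
            y,
            p0=[np.log(ic50_0), 1.0, top0, bot0],
            bounds=(
                [np.log(lo), 0.1, 0.0, 0.0],
                [np.log(hi), 10.0, 10.0 * max(top0, 1.0), top0],
            ),
            maxfev=20000,
        )
    except RuntimeError:
        return IC50Fit(math.nan, math.nan, top0, bot0, converged=False)
    resid = y - _four_pl(x, *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    converged = ss_tot == 0 or ss_res < 0.9 * ss_tot
    return IC50Fit(
        ic50=float(np.exp(popt[0])),
        hill=float(popt[1]),
        top=float(popt[2]),
        bottom=float(popt[3]),
        converged=bool(converged),
    )
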