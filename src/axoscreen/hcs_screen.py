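"""Per-well screen readouts and the hit-calling cascade of the
high-content DLK-GFP localization screen.

The screen watches the palmitoylation-dependent localization of
DLK-GFP in cotransfected HEK293T cells. Each well yields three
metrics: the number of mCherry-NLS-positive (transfected) cells, the
pooled DLK-GFP punctum count, and their ratio P/NLS, plus the vesicle
average intensity VAI (mean brightness of the detected puncta).
Compound calling proceeds as a cascade: wells that lose >30% of
transfected cells versus same-run vehicle are excluded as toxic, wells
that increase P/NLS >1.8-fold are excluded as aggregation artifacts,
and the survivors are called hits when both vehicle-normalized
readouts fall more than 2 sample standard deviations below the mean of
all remaining determinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging_core import ImageGrid, channel_mask_or_empty, label_and_measure

__all__ = [
    "WellMetrics",
    "DoseSeries",
    "PunctaParams",
    "NucleusParams",
    "quantify_well",
    "z_factor",
    "apply_exclusion_cascade",
    "call_hits",
    "confirm_dose_dependence",
    "read_screen_table",
    "write_screen_table",
]

SCREEN_TABLE_COLUMNS = [
    "compound_id",
    "run_id",
    "nls_count",
    "puncta_count",
    "p_nls",
    "vai",
    "p_nls_norm",
    "vai_norm",
    "exclusion_flag",
    "hit_flag",
]


@dataclass(frozen=True)
class PunctaParams:
    """Detection window for DLK-GFP puncta (5-500 px, circularity
    0.6-1.0, Intermodes threshold by default)."""

    min_area: int = 5
    max_area: float = 500
    min_circ: float = 0.6
    max_circ: float = 1.0
    threshold_method: str = "intermodes"
    fixed_value: float | None = None


@dataclass(frozen=True)
class NucleusParams:
    """Detection window for NLS-positive nuclei (500 px to infinity,
    circularity 0.8-1.0, fixed threshold 160 by default)."""

    min_area: int = 500
    max_area: float = math.inf
    min_circ: float = 0.8
    max_circ: float = 1.0
    threshold_method: str = "fixed"
    fixed_value: float | None = 160.0


@dataclass(frozen=True)
class WellMetrics:
    """The per-well readout triple plus provenance.

    ``p_nls`` is NaN with ``pnls_undefined`` set when no transfected
    cells were detected; ``vai`` is NaN with ``vai_undefined`` set when
    no puncta were detected. Undefined metrics are never silently 0.
    """

    well_id: str
    nls_count: int
    puncta_count: int
    p_nls: float
    vai: float
    n_fields: int
    pnls_undefined: bool = False
    vai_undefined: bool = False


def _count_field(
    image: ImageGrid,
    method: str,
    fixed_value: float | None,
    min_area: int,
    max_area: float,
    min_circ: float,
    max_circ: float,
    intensity: ImageGrid | None = None,
):
    mask = channel_mask_or_empty(image, method=method, fixed_value=fixed_value)
    _, stats = label_and_measure(
        mask,
        intensity=intensity,
        min_area=min_area,
        max_area=max_area,
        min_circ=min_circ,
        max_circ=max_circ,
    )
    return stats


def quantify_well(
    gfp_fields: Sequence[ImageGrid],
    nls_fields: Sequence[ImageGrid],
    puncta_params: PunctaParams | None = None,
    nucleus_params: NucleusParams | None = None,
    well_id: str = "well",
) -> WellMetrics:
    """Compute the screen readouts for one well from its imaged fields.

    Counts are pooled across fields before forming P/NLS, and VAI is
    the mean of per-punctum mean GFP intensities over all detected
    puncta in the well (puncta pooled directly, not per cell).
    """
    if len(gfp_fields) != len(nls_fields):
        raise ValueError("gfp_fields and nls_fields must have equal length")
    if not gfp_fields:
        raise ValueError("at least one field is required")
    pp = puncta_params or PunctaParams()
    npar = nucleus_params or NucleusParams()
    punctum_means: list[float] = []
    nls_count = 0
    for gfp, nls in zip(gfp_fields, nls_fields):
        stats = _count_field(
            gfp, pp.threshold_method, pp.fixed_value,
            pp.min_area, pp.max_area, pp.min_circ, pp.max_circ, intensity=gfp,
        )
        punctum_means.extend(s.mean_intensity for s in stats)
        nuclei = _count_field(
            nls, npar.threshold_method, npar.fixed_value,
            npar.min_area, npar.max_area, npar.min_circ, npar.max_circ,
        )
        nls_count += len(nuclei)
    puncta_count = len(punctum_means)
    pnls_undefined = nls_count == 0
    vai_undefined = puncta_count == 0
    return WellMetrics(
        well_id=well_id,
        nls_count=nls_count,
        puncta_count=puncta_count,
        p_nls=math.nan if pnls_undefined else puncta_count / nls_count,
        vai=math.nan if vai_undefined else float(np.mean(punctum_means)),
        n_fields=len(gfp_fields),
        pnls_undefined=pnls_undefined,
        vai_undefined=vai_undefined,
    )


def z_factor(
    positive_values: Iterable[float], negative_values: Iterable[float]
) -> float:
    """Plate-quality Z-factor: ``1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|``
    with sample standard deviations. Returns NaN (undefined) when the
    arm means coincide. Z <= 1 always; Z >= 0.5 is conventionally an
    excellent assay."""
    pos = np.asarray(list(positive_values), dtype=float)
    neg = np.asarray(list(negative_values), dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each arm needs at least 2 values")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return math.nan
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def _vehicle_references(table: pd.DataFrame) -> pd.DataFrame:
    veh = table[table["role"] == "vehicle"]
    runs = table.loc[table["role"] == "compound", "run_id"].unique()
    missing = sorted(set(runs) - set(veh["run_id"].unique()))
    if missing:
        raise ValueError(f"missing vehicle wells for run(s): {missing}")
    return veh.groupby("run_id")[["nls_count", "p_nls", "vai"]].mean()


def apply_exclusion_cascade(
    table: pd.DataFrame,
    toxicity_cut: float = 0.30,
    increase_cut: float = 1.8,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Normalize to same-run vehicle and apply the two exclusion filters.

    Input rows need columns (compound_id, run_id, role, nls_count,
    p_nls, vai) with ``role`` in {compound, vehicle}. A compound is
    *toxic* when its transfected-cell count falls strictly below
    ``(1 - toxicity_cut)`` times the same-run vehicle mean (wells with
    an undefined P/NLS, i.e. zero transfected cells, are routed to the
    toxic bin); a surviving compound is an *increaser* when its
    vehicle-normalized P/NLS strictly exceeds ``increase_cut``.

    Returns the annotated compound table (with p_nls_norm, vai_norm,
    exclusion_flag) and the cascade summary. Bookkeeping is conserved:
    ``n_toxic + n_increasers + n_remaining == n_total``.
    """
    refs = _vehicle_references(table)
    out = table[table["role"] == "compound"].copy()
    ref = refs.loc[out["run_id"]]
    veh_nls = ref["nls_count"].to_numpy()
    out["p_nls_norm"] = out["p_nls"].to_numpy() / ref["p_nls"].to_numpy()
    out["vai_norm"] = out["vai"].to_numpy() / ref["vai"].to_numpy()
    nls = out["nls_count"].to_numpy(dtype=float)
    toxic = (nls < (1.0 - toxicity_cut) * veh_nls) | (nls == 0) | ~np.isfinite(
        out["p_nls"].to_numpy(dtype=float)
    )
    increaser = ~toxic & (out["p_nls_norm"].to_numpy() > increase_cut)
    flags = np.where(toxic, "toxic", np.where(increaser, "pnls_increase", "none"))
    out["exclusion_flag"] = flags
    n_total = len(out)
    n_toxic = int(toxic.sum())
    n_incr = int(increaser.sum())
    summary = {
        "n_total": n_total,
        "n_toxic": n_toxic,
        "n_after_toxic": n_total - n_toxic,
        "n_increasers": n_incr,
        "n_remaining": n_total - n_toxic - n_incr,
    }
    return out, summary


def call_hits(
    table: pd.DataFrame,
    sd_cutoff: float = 2.0,
    basis: str = "final",
) -> tuple[pd.DataFrame, list[str]]:
    """Call hits among post-cascade determinations.

    A compound is a hit when *both* vehicle-normalized readouts fall
    strictly below ``mean - sd_cutoff * sd``, with the mean and sample
    SD computed per readout over all post-cascade determinations of the
    completed screen (``basis="final"``, the default). The
    ``basis="running"`` variant recomputes the statistics over the
    determinations seen so far, in table order, as was done mid-screen.

    Requires the exclusion cascade to have been applied (an
    ``exclusion_flag`` column); fewer than 3 post-cascade
    determinations is an error.
    """
    if "exclusion_flag" not in table.columns:
        raise ValueError("apply_exclusion_cascade must run before call_hits")
    out = table.copy()
    keep = out["exclusion_flag"] == "none"
    sub = out[keep]
    if len(sub) < 3:
        raise ValueError("need at least 3 post-cascade determinations")
    pn = sub["p_nls_norm"].to_numpy(dtype=float)
    va = sub["vai_norm"].to_numpy(dtype=float)
    if basis == "final":
        cut_p = pn.mean() - sd_cutoff * pn.std(ddof=1)
        cut_v = va.mean() - sd_cutoff * va.std(ddof=1)
        hit = keep.to_numpy() & (
            (out["p_nls_norm"].to_numpy(dtype=float) < cut_p)
            & (out["vai_norm"].to_numpy(dtype=float) < cut_v)
        )
    elif basis == "running":
        hit = np.zeros(len(out), dtype=bool)
        seen_p: list[float] = []
        seen_v: list[float] = []
        keep_arr = keep.to_numpy()
        pn_all = out["p_nls_norm"].to_numpy(dtype=float)
        va_all = out["vai_norm"].to_numpy(dtype=float)
        for i in range(len(out)):
            if not keep_arr[i]:
                continue
            seen_p.append(pn_all[i])
            seen_v.append(va_all[i])
            if len(seen_p) < 3:
                continue
            mp, sp = np.mean(seen_p), np.std(seen_p, ddof=1)
            mv, sv = np.mean(seen_v), np.std(seen_v, ddof=1)
            hit[i] = pn_all[i] < mp - sd_cutoff * sp and va_all[i] < mv - sd_cutoff * sv
    else:
        raise ValueError("basis must be 'final' or 'running'")
    out["hit_flag"] = hit
    return out, out.loc[out["hit_flag"], "compound_id"].tolist()


@dataclass(frozen=True)
class DoseSeries:
    """Triplicate 3-dose confirmation data for one compound/readout.

    ``doses`` are strictly decreasing concentrations (µM; the
    confirmation format is 10, 3, 1); ``responses[i]`` holds the
    vehicle-normalized replicate readouts at ``doses[i]``.
    """

    compound_id: str
    doses: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]
    readout: str = "p_nls"

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must align")
        if any(b >= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly decreasing")
        if any(len(r) < 2 for r in self.responses):
            raise ValueError("need >= 2 replicates per dose")


def confirm_dose_dependence(
    series: DoseSeries,
    hit_threshold: float,
    tolerance_frac: float = 0.10,
    n_doses: int = 3,
) -> bool:
    """Dose-dependence call for one readout.

    Positive iff the mean normalized readout at the top dose falls
    strictly below ``hit_threshold`` (the effect clears the hit
    cutoff) *and* the per-dose mean effects (1 - normalized readout)
    are monotone non-increasing with dilution, within a tolerance of
    ``tolerance_frac`` of the top-dose effect. A compound passes
    confirmation when either readout's series passes.
    """
    if len(series.doses) != n_doses:
        raise ValueError(f"expected {n_doses} dose levels, got {len(series.doses)}")
    means = np.array([float(np.mean(r)) for r in series.responses])
    top_effect = 1.0 - means[0]
    if not means[0] < hit_threshold:
        return False
    tol = tolerance_frac * abs(top_effect)
    effects = 1.0 - means
    return bool(np.all(np.diff(effects) <= tol))


# ---------------------------------------------------------------------------
# ScreenTable CSV I/O
# ---------------------------------------------------------------------------


def write_screen_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_screen_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"compound_id", "run_id", "nls_count", "p_nls", "vai"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    if "role" not in table.columns:
        table["role"] = "compound"
    return table
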