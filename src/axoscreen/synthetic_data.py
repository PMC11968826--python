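"""Ground-truthed synthetic microscopy for every image class the
pipeline consumes, plus a metric-level screen simulator.

Each generator is a pure function of its parameters and a seed: the
same call is bit-identical on repeat. Every rendered object carries a
truth record, so detection stages can be scored against known answers
without any external data.

Rendering model
---------------
Fields are 8-bit, default 1024x1024 px (the scale at which the fixed
intensity cutoffs 160 and 200 used by the assays are meaningful).
Objects are painted as intensity plateaus over a flat background
(default 20 gray levels) with generous contrast, so that the detection
windows from the assay definitions separate object classes cleanly.
The noise model is additive Gaussian read noise (default sigma = 6 gray
levels) with optional Poisson shot noise; defaults keep every planted
object several sigma away from the operative thresholds. Pass
``noise_sd=0`` for idealized, exactly recoverable renders.

What is emulated (and what is not): punctate-vs-diffuse GFP cells with
nuclear-marker cotransfection; phase-contrast axon fields whose
degeneration follows a dying-back rule (a distal fraction of each axon
fragments into sub-window beads); Calcein/Hoechst viability fields;
axonal marker channels with planted accumulations and vesicle-scale
puncta; and retinal DAPI/Brn3a/p-c-Jun fields. Optical realism (PSF,
uneven illumination, phase optics) is deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .imaging_core import ImageGrid

__all__ = [
    "SceneTruth",
    "ScreenSimParams",
    "generate_hcs_field",
    "generate_screen_metrics",
    "generate_axon_field",
    "generate_viability_field",
    "generate_retina_field",
]

DEFAULT_SHAPE = (1024, 1024)
DEFAULT_BACKGROUND = 20
DEFAULT_NOISE_SD = 6.0


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SceneTruth:
    """Ground truth for one generated scene.

    ``objects`` holds one record per rendered object (kind, centroid,
    geometry, intensity and class labels); ``summary`` holds scene-level
    derived quantities (e.g. total planted accumulation area) that the
    assays are scored against; ``params`` echoes the generator call.
    """

    kind: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    objects: list[dict[str, Any]] = field(default_factory=list)
    summary: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SceneTruth":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _py(value: Any) -> Any:
    """Coerce numpy scalars to plain Python for lossless JSON round-trips."""
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------


def _blank(shape: tuple[int, int], background: float) -> np.ndarray:
    return np.full(shape, float(background), dtype=np.float64)


def _finish(
    canvas: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    poisson_shot: bool,
) -> ImageGrid:
    img = canvas.copy()
    if poisson_shot:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return ImageGrid(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = (yy**2 + xx**2) <= radius**2
    return yy[keep], xx[keep]


def _paint_disk(
    canvas: np.ndarray, row: float, col: float, radius: float, value: float
) -> int:
    """Paint a hard disk (max blend); returns painted pixel count."""
    dy, dx = _disk_offsets(radius)
    rr = np.rint(row + dy).astype(int)
    cc = np.rint(col + dx).astype(int)
    keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    rr, cc = rr[keep], cc[keep]
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)
    return int(len(rr))


def _paint_ellipse(
    canvas: np.ndarray, row: float, col: float, a: float, b: float, value: float
) -> np.ndarray:
    """Paint an axis-aligned ellipse (semi-axes a along columns, b along
    rows); returns the boolean footprint painted."""
    ra = int(np.ceil(a))
    rb = int(np.ceil(b))
    yy, xx = np.mgrid[-rb : rb + 1, -ra : ra + 1]
    keep = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    rr = np.rint(row + yy[keep]).astype(int)
    cc = np.rint(col + xx[keep]).astype(int)
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    rr, cc = rr[ok], cc[ok]
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)
    out = np.zeros(canvas.shape, dtype=bool)
    out[rr, cc] = True
    return out


def _paint_soft_disk(
    canvas: np.ndarray, row: float, col: float, radius: float, value: float, rim: float = 2.0
) -> None:
    """Disk with a linear intensity roll-off over ``rim`` pixels at the
    edge, blended by maximum."""
    r = int(np.ceil(radius + rim))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(yy, xx)
    prof = np.clip((radius + rim - dist) / rim, 0.0, 1.0)
    rr = np.rint(row + yy).astype(int)
    cc = np.rint(col + xx).astype(int)
    keep = (prof > 0) & (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[keep], cc[keep]] = np.maximum(
        canvas[rr[keep], cc[keep]], value * prof[keep]
    )


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    max_tries_per_point: int = 2000,
) -> list[tuple[float, float]]:
    """Dart-throwing placement with a minimum pairwise separation."""
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max(1, n) * max_tries_per_point
    while len(pts) < n:
        if tries > budget:
            raise RuntimeError(
                f"could not place {n} objects with separation {min_sep} in a "
                f"{shape} field; use a larger field or fewer objects"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in pts):
            pts.append((r, c))
    return pts


# ---------------------------------------------------------------------------
# HCS transfection fields (GFP puncta / NLS nuclei)
# ---------------------------------------------------------------------------


def generate_hcs_field(
    n_cells: int,
    punctate_fraction: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    poisson_shot: bool = False,
    puncta_per_cell: tuple[int, int] = (2, 5),
    cell_radius: float = 16.0,
    nucleus_radius: float = 14.0,
    cell_intensity: float = 60.0,
    punctum_intensity: float = 200.0,
    punctum_radius: float = 2.0,
    punctum_profile: str = "flat",
    nucleus_intensity: float = 220.0,
    background: float = DEFAULT_BACKGROUND,
) -> tuple[ImageGrid, ImageGrid, SceneTruth]:
    """Render one transfected-cell field: a GFP channel with punctate or
    diffuse cells and an NLS channel with one nucleus per cell.

    Punctate cells carry bright puncta (footprints inside the 5-500 px
    detection window) on a dim diffuse disk; diffuse cells spread the
    same integrated punctum flux uniformly over the cell, staying well
    below the puncta threshold. Every cell has a nucleus (area >= 500
    px) in the NLS channel.
    """
    rng = np.random.default_rng(seed)
    gfp = _blank(shape, background)
    nls = _blank(shape, background)
    truth = SceneTruth(
        kind="hcs_field",
        seed=seed,
        params={
            "n_cells": n_cells,
            "punctate_fraction": punctate_fraction,
            "shape": list(shape),
            "noise_sd": noise_sd,
            "punctum_profile": punctum_profile,
        },
    )
    if n_cells > 0:
        centers = _place_points(
            rng, n_cells, shape, margin=cell_radius + 8, min_sep=2 * cell_radius + 10
        )
        is_punctate = rng.random(n_cells) < punctate_fraction
        for i, (r, c) in enumerate(centers):
            n_puncta = int(rng.integers(puncta_per_cell[0], puncta_per_cell[1] + 1))
            punctum_flux = n_puncta * 13 * (punctum_intensity - cell_intensity)
            cell_area = np.pi * cell_radius**2
            if is_punctate[i]:
                _paint_soft_disk(gfp, r, c, cell_radius, cell_intensity)
                placed = _place_points(
                    rng, n_puncta, (int(2 * cell_radius), int(2 * cell_radius)),
                    margin=punctum_radius + 2.5, min_sep=2 * punctum_radius + 3,
                )
                for pr, pc in placed:
                    prow = r - cell_radius + pr
                    pcol = c - cell_radius + pc
                    if punctum_profile == "flat":
                        _paint_disk(gfp, prow, pcol, punctum_radius, punctum_intensity)
                    else:
                        _paint_gaussian(gfp, prow, pcol, punctum_radius, punctum_intensity)
                    truth.objects.append(
                        {
                            "kind": "punctum",
                            "cell": i,
                            "centroid": [float(prow), float(pcol)],
                            "intensity": _py(punctum_intensity),
                        }
                    )
            else:
                diffuse = min(cell_intensity + punctum_flux / cell_area, 95.0)
                _paint_soft_disk(gfp, r, c, cell_radius, diffuse)
            _paint_disk(nls, r, c, nucleus_radius, nucleus_intensity)
            truth.objects.append(
                {
                    "kind": "cell",
                    "index": i,
                    "centroid": [float(r), float(c)],
                    "punctate": bool(is_punctate[i]),
                }
            )
            truth.objects.append(
                {"kind": "nucleus", "cell": i, "centroid": [float(r), float(c)]}
            )
    truth.summary = {
        "n_nuclei": sum(1 for o in truth.objects if o["kind"] == "nucleus"),
        "n_puncta": sum(1 for o in truth.objects if o["kind"] == "punctum"),
    }
    return (
        _finish(gfp, rng, noise_sd, poisson_shot),
        _finish(nls, rng, noise_sd, poisson_shot),
        truth,
    )


def _paint_gaussian(
    canvas: np.ndarray, row: float, col: float, sigma: float, peak: float
) -> None:
    """Gaussian spot truncated at 3 sigma, blended by maximum."""
    r = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    prof = peak * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    rr = np.rint(row + yy).astype(int)
    cc = np.rint(col + xx).astype(int)
    keep = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[keep], cc[keep]] = np.maximum(canvas[rr[keep], cc[keep]], prof[keep])


# ---------------------------------------------------------------------------
# Metric-level screen simulator
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimParams:
    """Conditions for a simulated primary screen.

    Normalized readouts of inactive compounds are ``1 + eps`` with
    ``eps ~ N(0, noise_sd)``. Planted hits realize a displacement of
    ``effect_sd_* x noise_sd`` below vehicle in both readouts, with a
    small potency jitter (``hit_jitter_sd x noise_sd``) between hits;
    toxic compounds depress the transfected-cell count below the 30%
    line and increasers scale P/NLS above the 1.8-fold line.
    """

    n_compounds: int = 2000
    hit_fraction: float = 0.01
    effect_sd_pnls: float = 4.0
    effect_sd_vai: float = 4.0
    toxic_fraction: float = 0.0
    increaser_fraction: float = 0.0
    n_runs: int = 4
    vehicle_wells_per_run: int = 16
    noise_sd: float = 0.1
    hit_jitter_sd: float = 0.25
    vehicle_nls_mean: float = 200.0
    vehicle_nls_sd: float = 10.0
    vehicle_pnls_mean: float = 3.0
    vehicle_vai_mean: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be >= 10")
        if self.hit_fraction + self.toxic_fraction + self.increaser_fraction > 1:
            raise ValueError("planted fractions must sum to <= 1")


def generate_screen_metrics(
    params: ScreenSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-well screen metrics and truth labels.

    Returns ``(table, truth)``: ``table`` has one row per well with
    columns (compound_id, run_id, role, nls_count, puncta_count, p_nls,
    vai) including vehicle wells; ``truth`` has one row per compound
    with boolean columns is_hit / is_toxic / is_increaser.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_compounds
    n_hits = int(round(p.hit_fraction * n))
    n_toxic = int(round(p.toxic_fraction * n))
    n_incr = int(round(p.increaser_fraction * n))
    roles = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    roles[order[:n_hits]] = "hit"
    roles[order[n_hits : n_hits + n_toxic]] = "toxic"
    roles[order[n_hits + n_toxic : n_hits + n_toxic + n_incr]] = "increaser"

    run_ids = np.array([f"run{1 + i % p.n_runs}" for i in range(n)], dtype=object)

    rows: list[dict[str, Any]] = []
    # Vehicle wells, per run.
    for r in range(1, p.n_runs + 1):
        for w in range(p.vehicle_wells_per_run):
            nls = p.vehicle_nls_mean + rng.normal(0, p.vehicle_nls_sd)
            pnls = p.vehicle_pnls_mean * (1 + rng.normal(0, p.noise_sd))
            vai = p.vehicle_vai_mean * (1 + rng.normal(0, p.noise_sd))
            rows.append(
                {
                    "compound_id": f"vehicle_run{r}_{w:02d}",
                    "run_id": f"run{r}",
                    "role": "vehicle",
                    "nls_count": max(0, int(round(nls))),
                    "p_nls": pnls,
                    "vai": vai,
                }
            )
    for i in range(n):
        role = roles[i]
        nls = p.vehicle_nls_mean + rng.normal(0, p.vehicle_nls_sd)
        pnls_factor = 1 + rng.normal(0, p.noise_sd)
        vai_factor = 1 + rng.normal(0, p.noise_sd)
        if role == "toxic":
            nls = 0.4 * p.vehicle_nls_mean + rng.normal(0, p.vehicle_nls_sd)
        elif role == "increaser":
            pnls_factor = 2.5 + rng.normal(0, p.noise_sd)
        elif role == "hit":
            pnls_factor = (
                1
                - p.effect_sd_pnls * p.noise_sd
                + rng.normal(0, p.hit_jitter_sd * p.noise_sd)
            )
            vai_factor = (
                1
                - p.effect_sd_vai * p.noise_sd
                + rng.normal(0, p.hit_jitter_sd * p.noise_sd)
            )
        rows.append(
            {
                "compound_id": f"cmpd{i:06d}",
                "run_id": run_ids[i],
                "role": "compound",
                "nls_count": max(0, int(round(nls))),
                "p_nls": max(0.0, p.vehicle_pnls_mean * pnls_factor),
                "vai": max(0.0, p.vehicle_vai_mean * vai_factor),
            }
        )
    table = pd.DataFrame(rows)
    table["puncta_count"] = np.rint(table["p_nls"] * table["nls_count"]).astype(int)
    table = table[
        ["compound_id", "run_id", "role", "nls_count", "puncta_count", "p_nls", "vai"]
    ]
    truth = pd.DataFrame(
        {
            "compound_id": [f"cmpd{i:06d}" for i in range(n)],
            "is_hit": roles == "hit",
            "is_toxic": roles == "toxic",
            "is_increaser": roles == "increaser",
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# Axon fields (phase contrast + marker channels)
# ---------------------------------------------------------------------------


def generate_axon_field(
    n_axons: int = 8,
    bleb_density: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    poisson_shot: bool = False,
    n_accumulations: int = 8,
    n_myc_puncta: int = 12,
    axon_halfwidth: float = 1.5,
    phase_background: float = 230.0,
    axon_phase_intensity: float = 30.0,
    marker_shaft_intensity: float = 150.0,
    accumulation_intensity: float = 200.0,
    myc_intensity: float = 200.0,
    tuj1_intensity: float = 180.0,
    background: float = DEFAULT_BACKGROUND,
) -> tuple[ImageGrid, np.ndarray, dict[str, ImageGrid], SceneTruth]:
    """Render one axon field: a phase-contrast channel (dark axons on a
    bright background, somata at the proximal edge), the cell-body mask,
    and marker channels (``marker`` with planted accumulations, ``myc``
    with vesicle-scale puncta, ``tuj1`` as the axon-area reference).

    Degeneration follows a dying-back rule: a distal fraction of each
    axon (``bleb_density`` scaled by a per-axon susceptibility fixed by
    the seed) is replaced by beads whose areas sit below the 400-px
    integrity window, so the index is monotone non-increasing in
    ``bleb_density`` for a fixed seed. Marker channels are rendered on
    the intact geometry (they emulate the accumulation phenotype, not
    fragmentation).
    """
    if not (0.0 <= bleb_density <= 1.0):
        raise ValueError("bleb_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    H, W = shape
    phase = _blank(shape, phase_background)
    cellbody_mask = np.zeros(shape, dtype=bool)
    marker = _blank(shape, background)
    myc = _blank(shape, background)
    tuj1 = _blank(shape, background)
    truth = SceneTruth(
        kind="axon_field",
        seed=seed,
        params={
            "n_axons": n_axons,
            "bleb_density": bleb_density,
            "shape": list(shape),
            "noise_sd": noise_sd,
        },
    )

    band_h = H / max(n_axons, 1)
    axon_cols: list[np.ndarray] = []
    axon_rows: list[np.ndarray] = []
    intact_count = 0
    dy_off, dx_off = _disk_offsets(axon_halfwidth)
    bead_spacing = 14
    for i in range(n_axons):
        band_lo = i * band_h + 6
        band_hi = (i + 1) * band_h - 6
        length = int(rng.uniform(0.45, 0.92) * (W - 48))
        x0 = int(rng.uniform(20, max(21, W - 24 - length)))
        xs = np.arange(x0, x0 + length)
        drift = rng.normal(0, 0.6, size=length)
        kernel = np.ones(41) / 41.0
        drift = np.convolve(drift, kernel, mode="same")
        ys = (band_lo + band_hi) / 2 + np.cumsum(drift)
        ys = np.clip(ys, band_lo, band_hi)
        susceptibility = rng.uniform(0.4, 1.6)
        degen_frac = min(1.0, bleb_density * susceptibility)
        n_intact = int(round((1.0 - degen_frac) * length))
        axon_cols.append(xs)
        axon_rows.append(ys)

        def _stamp(canvas: np.ndarray, cols: np.ndarray, rows: np.ndarray, value: float) -> None:
            for dy, dx in zip(dy_off, dx_off):
                rr = np.clip(np.rint(rows + dy).astype(int), 0, H - 1)
                cc = np.clip(np.rint(cols + dx).astype(int), 0, W - 1)
                canvas[rr, cc] = value if canvas is phase else np.maximum(canvas[rr, cc], value)

        # Phase channel: proximal intact stretch, then beads distally.
        if n_intact > 0:
            _stamp(phase, xs[:n_intact], ys[:n_intact], axon_phase_intensity)
        n_beads = 0
        dy2, dx2 = _disk_offsets(2.8)
        for k in range(n_intact + bead_spacing, length, bead_spacing):
            rr = np.clip(np.rint(ys[k] + dy2).astype(int), 0, H - 1)
            cc = np.clip(np.rint(xs[k] + dx2).astype(int), 0, W - 1)
            phase[rr, cc] = axon_phase_intensity  # dark beads
            n_beads += 1
        intact_area = n_intact * 3  # ~3 px cross-section per unit length
        counted = n_intact > 0 and intact_area >= 400
        if counted:
            intact_count += 1
        truth.objects.append(
            {
                "kind": "axon",
                "index": i,
                "length_px": int(length),
                "degenerate_fraction": float(degen_frac),
                "intact_length_px": int(n_intact),
                "n_beads": int(n_beads),
                "counted_in_integrity_index": bool(counted),
            }
        )
        # Marker channels use the intact geometry.
        _stamp(marker, xs, ys, marker_shaft_intensity)
        _stamp(tuj1, xs, ys, tuj1_intensity)

        # Soma at the proximal end, recorded in the cell-body mask.
        soma_r = 11.0
        dy3, dx3 = _disk_offsets(soma_r)
        rr = np.clip(np.rint(ys[0] + dy3).astype(int), 0, H - 1)
        cc = np.clip(np.rint(xs[0] - 4 + dx3).astype(int), 0, W - 1)
        cellbody_mask[rr, cc] = True
        phase[rr, cc] = 40.0
        truth.objects.append(
            {"kind": "soma", "axon": i, "centroid": [float(ys[0]), float(xs[0] - 4)]}
        )

    # Planted accumulations on the marker channel: erase a shaft halo so
    # each blob is its own particle (marker drains from flanking shaft).
    accum_area = 0
    if n_axons > 0 and n_accumulations > 0:
        placed = 0
        centers: list[tuple[float, float]] = []
        tries = 0
        while placed < n_accumulations and tries < 200 * n_accumulations:
            tries += 1
            ai = int(rng.integers(0, n_axons))
            xs, ys = axon_cols[ai], axon_rows[ai]
            k = int(rng.integers(40, max(41, len(xs) - 40)))
            r0, c0 = float(ys[k]), float(xs[k])
            if any((r0 - pr) ** 2 + (c0 - pc) ** 2 < 70**2 for pr, pc in centers):
                continue
            b = rng.uniform(8.0, 11.0)
            ratio = rng.uniform(1.1, 2.0)
            a = b * ratio
            # halo: clear any shaft signal around the blob site
            dyh, dxh = _disk_offsets(a + 5)
            rr = np.clip(np.rint(r0 + dyh).astype(int), 0, H - 1)
            cc = np.clip(np.rint(c0 + dxh).astype(int), 0, W - 1)
            marker[rr, cc] = background
            foot = _paint_ellipse(marker, r0, c0, a, b, accumulation_intensity)
            area = int(foot.sum())
            accum_area += area
            centers.append((r0, c0))
            truth.objects.append(
                {
                    "kind": "accumulation",
                    "centroid": [r0, c0],
                    "area_px": area,
                    "semi_axes": [float(a), float(b)],
                }
            )
            placed += 1

    # Vesicle-scale myc puncta along the axons, outside the cell bodies.
    puncta_placed = 0
    if n_axons > 0 and n_myc_puncta > 0:
        centers = []
        tries = 0
        while puncta_placed < n_myc_puncta and tries < 500 * n_myc_puncta:
            tries += 1
            ai = int(rng.integers(0, n_axons))
            xs, ys = axon_cols[ai], axon_rows[ai]
            k = int(rng.integers(20, len(xs) - 5))
            r0 = float(ys[k]) + rng.uniform(-3, 3)
            c0 = float(xs[k])
            if cellbody_mask[int(round(r0)), int(round(c0))]:
                continue
            if any((r0 - pr) ** 2 + (c0 - pc) ** 2 < 9**2 for pr, pc in centers):
                continue
            radius = rng.uniform(1.1, 1.55)
            area = _paint_disk(myc, r0, c0, radius, myc_intensity)
            centers.append((r0, c0))
            truth.objects.append(
                {"kind": "punctum", "centroid": [r0, c0], "area_px": area}
            )
            puncta_placed += 1

    marker_area = int((marker > background).sum())
    tuj1_area = int((tuj1 > background).sum())
    truth.summary = {
        "n_intact_structures": intact_count,
        "accumulation_area_px": accum_area,
        "marker_positive_area_px": marker_area,
        "tuj1_axon_area_px": tuj1_area,
        "tuj1_axon_area_fraction": tuj1_area / (H * W),
        "n_myc_puncta": puncta_placed,
    }
    channels = {
        "marker": _finish(marker, rng, noise_sd, poisson_shot),
        "myc": _finish(myc, rng, noise_sd, poisson_shot),
        "tuj1": _finish(tuj1, rng, noise_sd, poisson_shot),
    }
    phase_img = _finish(phase, rng, noise_sd, poisson_shot)
    return phase_img, cellbody_mask, channels, truth


# ---------------------------------------------------------------------------
# Viability fields (Calcein-AM / Hoechst)
# ---------------------------------------------------------------------------


def generate_viability_field(
    n_viable: int,
    n_calcein_only: int = 0,
    n_hoechst_only: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    poisson_shot: bool = False,
    soma_radius: float = 17.0,
    nucleus_radius: float = 14.0,
    calcein_intensity: float = 190.0,
    hoechst_intensity: float = 200.0,
    background: float = DEFAULT_BACKGROUND,
) -> tuple[ImageGrid, ImageGrid, SceneTruth]:
    """Render paired Calcein-AM / Hoechst fields.

    Viable (double-positive) cells appear as a Calcein soma with a
    concentric Hoechst nucleus whose intersection exceeds the 500-px
    soma window; calcein-only and hoechst-only cells populate exactly
    one channel. Placement is dart-throwing with a minimum separation.
    """
    rng = np.random.default_rng(seed)
    calcein = _blank(shape, background)
    hoechst = _blank(shape, background)
    n_total = n_viable + n_calcein_only + n_hoechst_only
    truth = SceneTruth(
        kind="viability_field",
        seed=seed,
        params={
            "n_viable": n_viable,
            "n_calcein_only": n_calcein_only,
            "n_hoechst_only": n_hoechst_only,
            "shape": list(shape),
            "noise_sd": noise_sd,
        },
    )
    if n_total > 0:
        pts = _place_points(
            rng, n_total, shape, margin=soma_radius + 6, min_sep=2 * soma_radius + 8
        )
        kinds = (
            ["double_positive"] * n_viable
            + ["calcein_only"] * n_calcein_only
            + ["hoechst_only"] * n_hoechst_only
        )
        for (r, c), kind in zip(pts, kinds):
            if kind in ("double_positive", "calcein_only"):
                _paint_disk(calcein, r, c, soma_radius, calcein_intensity)
            if kind in ("double_positive", "hoechst_only"):
                _paint_disk(hoechst, r, c, nucleus_radius, hoechst_intensity)
            truth.objects.append(
                {"kind": "soma", "class": kind, "centroid": [float(r), float(c)]}
            )
    truth.summary = {"n_viable": n_viable}
    return (
        _finish(calcein, rng, noise_sd, poisson_shot),
        _finish(hoechst, rng, noise_sd, poisson_shot),
        truth,
    )


# ---------------------------------------------------------------------------
# Retinal flat-mount fields (DAPI / Brn3a / p-c-Jun)
# ---------------------------------------------------------------------------


def generate_retina_field(
    n_rgc: int,
    n_nonrgc: int = 0,
    pcjun_shift: float = 60.0,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    poisson_shot: bool = False,
    nucleus_radius: float = 11.0,
    dapi_intensity: float = 200.0,
    brn3a_intensity: float = 180.0,
    pcjun_baseline: float = 50.0,
    background: float = DEFAULT_BACKGROUND,
) -> tuple[ImageGrid, ImageGrid, ImageGrid, SceneTruth]:
    """Render one retinal field: all nuclei in DAPI, the RGC subset in
    Brn3a, and a p-c-Jun channel at ``baseline`` everywhere except RGC
    nuclei, which carry ``baseline + pcjun_shift``."""
    if pcjun_shift < 0:
        raise ValueError("pcjun_shift must be >= 0")
    rng = np.random.default_rng(seed)
    dapi = _blank(shape, background)
    brn3a = _blank(shape, background)
    pcjun = _blank(shape, pcjun_baseline)
    n_total = n_rgc + n_nonrgc
    truth = SceneTruth(
        kind="retina_field",
        seed=seed,
        params={
            "n_rgc": n_rgc,
            "n_nonrgc": n_nonrgc,
            "pcjun_shift": pcjun_shift,
            "shape": list(shape),
            "noise_sd": noise_sd,
        },
    )
    if n_total > 0:
        pts = _place_points(
            rng, n_total, shape, margin=nucleus_radius + 5, min_sep=2 * nucleus_radius + 7
        )
        for i, (r, c) in enumerate(pts):
            is_rgc = i < n_rgc
            _paint_disk(dapi, r, c, nucleus_radius, dapi_intensity)
            if is_rgc:
                _paint_disk(brn3a, r, c, nucleus_radius, brn3a_intensity)
                _paint_disk(pcjun, r, c, nucleus_radius, pcjun_baseline + pcjun_shift)
            truth.objects.append(
                {
                    "kind": "nucleus",
                    "brn3a_positive": bool(is_rgc),
                    "centroid": [float(r), float(c)],
                    "pcjun_intensity": float(
                        pcjun_baseline + (pcjun_shift if is_rgc else 0.0)
                    ),
                }
            )
    truth.summary = {"n_rgc": n_rgc, "n_nuclei": n_total}
    return (
        _finish(dapi, rng, noise_sd, poisson_shot),
        _finish(brn3a, rng, noise_sd, poisson_shot),
        _finish(pcjun, rng, noise_sd, poisson_shot),
        truth,
    )
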