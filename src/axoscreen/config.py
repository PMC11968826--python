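"""Run configuration and batch orchestration.

A :class:`RunConfig` pins every numeric parameter of every stage to the
bench-protocol defaults (threshold modes, particle windows, watershed
parameters, cascade cutoffs); any override is logged. ``run_batch``
executes the selected assay over a directory of fields laid out as
``well_<ID>_field<k>_<channel>.tif``, writes a per-field CSV and a
summary JSON embedding the config hash and seed, and keeps going past
per-field failures (recording them) — only malformed configuration is
a hard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import hcs_screen, neurite_assays, retina_quant, viability
from .imaging_core import read_tiff

logger = logging.getLogger("axoscreen")

__all__ = ["RunConfig", "run_batch", "load_config", "save_config"]

Assay = Literal[
    "hcs-quant", "axon-index", "accumulation", "puncta", "viability", "retina", "screen-call"
]

_FIELD_RE = re.compile(
    r"well_(?P<well>[A-Za-z0-9-]+)_field(?P<k>\d+)_(?P<channel>[A-Za-z0-9]+)\.tiff?$"
)


class RunConfig(BaseModel):
    """All tunables of a batch run; defaults are the protocol values."""

    assay: Assay = "hcs-quant"
    input_dir: str = "."
    input_table: str | None = None  # screen-call input CSV
    output_dir: str = "axoscreen_out"
    seed: int = 0

    # Screen cascade / hit calling
    toxicity_cut: float = 0.30
    increase_cut: float = 1.8
    sd_cutoff: float = 2.0
    hit_basis: Literal["final", "running"] = "final"

    # HCS particle windows
    puncta_min_area: int = 5
    puncta_max_area: float = 500
    puncta_min_circ: float = 0.6
    puncta_max_circ: float = 1.0
    puncta_threshold_method: str = "intermodes"
    nucleus_min_area: int = 500
    nucleus_min_circ: float = 0.8
    nucleus_max_circ: float = 1.0
    nucleus_threshold_method: str = "fixed"
    nucleus_fixed_threshold: float = 160.0

    # Axon integrity (H-watershed)
    seed_dynamics: float = 40.0
    intensity_threshold: float = 200.0
    peak_flooding: float = 100.0
    structure_min_area: int = 400
    structure_max_circ: float = 0.3

    # Accumulations / axonal puncta
    accum_min_area: int = 200
    accum_max_area: float = 1500
    accum_circ_min: float = 0.2
    accum_circ_max: float = 1.0

    # Viability
    soma_min_area: int = 500
    soma_min_circ: float = 0.8
    soma_max_circ: float = 1.0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def log_overrides(self) -> None:
        defaults = RunConfig(assay=self.assay).model_dump()
        for key, value in self.model_dump().items():
            if key in ("assay", "input_dir", "input_table", "output_dir", "seed"):
                continue
            if defaults[key] != value:
                logger.info("config override: %s = %r (default %r)", key, value, defaults[key])


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if data.get("defaults") == "protocol":
        data.pop("defaults")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def _scan_fields(input_dir: Path) -> dict[tuple[str, int], dict[str, Path]]:
    """Map (well, field) -> {channel: path} for the naming scheme
    ``well_<ID>_field<k>_<channel>.tif``."""
    out: dict[tuple[str, int], dict[str, Path]] = {}
    for p in sorted(input_dir.glob("*.tif*")):
        m = _FIELD_RE.match(p.name)
        if not m:
            continue
        key = (m.group("well"), int(m.group("k")))
        out.setdefault(key, {})[m.group("channel").lower()] = p
    return out


def _mask_from_tiff(path: Path) -> np.ndarray:
    return read_tiff(path).pixels > 0


def run_batch(config: RunConfig) -> dict[str, Any]:
    """Execute the configured assay over all fields/wells.

    Writes ``fields.csv`` (per-field/per-well rows) and ``summary.json``
    (aggregate metrics, config echo, config hash, seed) under
    ``config.output_dir`` and returns the summary. Per-field failures
    are recorded under ``errors`` and do not abort the batch.
    """
    config.log_overrides()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Any]] = []
    errors: list[dict[str, str]] = []

    if config.assay == "screen-call":
        if not config.input_table:
            raise ValueError("screen-call requires input_table")
        table = hcs_screen.read_screen_table(config.input_table)
        annotated, summary_counts = hcs_screen.apply_exclusion_cascade(
            table, toxicity_cut=config.toxicity_cut, increase_cut=config.increase_cut
        )
        annotated, hits = hcs_screen.call_hits(
            annotated, sd_cutoff=config.sd_cutoff, basis=config.hit_basis
        )
        annotated.to_csv(out_dir / "screen_annotated.csv", index=False)
        summary: dict[str, Any] = {"cascade": summary_counts, "n_hits": len(hits), "hits": hits}
    else:
        fields = _scan_fields(Path(config.input_dir))
        handler = _FIELD_HANDLERS[config.assay]
        grouped = config.assay in ("hcs-quant", "retina")
        if grouped:
            by_well: dict[str, list[tuple[int, dict[str, Path]]]] = {}
            for (well, k), chans in sorted(fields.items()):
                by_well.setdefault(well, []).append((k, chans))
            for well, entries in by_well.items():
                try:
                    rows.extend(handler(config, well, entries))
                except Exception as exc:  # noqa: BLE001 - batch keeps going
                    errors.append({"well": well, "error": str(exc)})
        else:
            for (well, k), chans in sorted(fields.items()):
                try:
                    rows.extend(handler(config, f"{well}_f{k}", [(k, chans)]))
                except Exception as exc:  # noqa: BLE001
                    errors.append({"well": f"{well}_f{k}", "error": str(exc)})
        frame = pd.DataFrame(rows)
        frame.to_csv(out_dir / "fields.csv", index=False)
        summary = {"n_rows": len(rows), "errors": errors}
        if rows and "value" in frame.columns:
            summary["mean_value"] = float(frame["value"].mean())

    summary["assay"] = config.assay
    summary["seed"] = config.seed
    summary["config"] = config.model_dump()
    summary["config_hash"] = config.config_hash()
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("run_batch %s: %d rows, %d errors [config %s]",
                config.assay, len(rows), len(errors), config.config_hash())
    return summary


# --- per-assay field handlers ------------------------------------------------


def _need(chans: dict[str, Path], *names: str) -> list[Path]:
    missing = [n for n in names if n not in chans]
    if missing:
        raise ValueError(f"missing channel(s) {missing}; have {sorted(chans)}")
    return [chans[n] for n in names]


def _handle_hcs(config: RunConfig, well: str, entries) -> list[dict[str, Any]]:
    gfp, nls = [], []
    for _, chans in entries:
        g, n = _need(chans, "gfp", "nls")
        gfp.append(read_tiff(g))
        nls.append(read_tiff(n))
    pp = hcs_screen.PunctaParams(
        min_area=config.puncta_min_area,
        max_area=config.puncta_max_area,
        min_circ=config.puncta_min_circ,
        max_circ=config.puncta_max_circ,
        threshold_method=config.puncta_threshold_method,
    )
    npar = hcs_screen.NucleusParams(
        min_area=config.nucleus_min_area,
        min_circ=config.nucleus_min_circ,
        max_circ=config.nucleus_max_circ,
        threshold_method=config.nucleus_threshold_method,
        fixed_value=config.nucleus_fixed_threshold,
    )
    m = hcs_screen.quantify_well(gfp, nls, pp, npar, well_id=well)
    return [
        {
            "well": well,
            "assay": "hcs-quant",
            "nls_count": m.nls_count,
            "puncta_count": m.puncta_count,
            "p_nls": m.p_nls,
            "vai": m.vai,
            "n_fields": m.n_fields,
        }
    ]


def _handle_axon(config: RunConfig, fid: str, entries) -> list[dict[str, Any]]:
    _, chans = entries[0]
    phase, mask = _need(chans, "phase", "cellmask")
    res = neurite_assays.axon_integrity_index(
        read_tiff(phase),
        _mask_from_tiff(mask),
        seed_dynamics=config.seed_dynamics,
        intensity_threshold=config.intensity_threshold,
        peak_flooding=config.peak_flooding,
        min_area=config.structure_min_area,
        max_circ=config.structure_max_circ,
    )
    return [_axon_row(fid, res)]


def _handle_accum(config: RunConfig, fid: str, entries) -> list[dict[str, Any]]:
    _, chans = entries[0]
    (marker,) = _need(chans, "marker")
    res = neurite_assays.accumulation_fraction(
        read_tiff(marker),
        circ_window=(config.accum_circ_min, config.accum_circ_max),
        min_area=config.accum_min_area,
        max_area=config.accum_max_area,
    )
    return [_axon_row(fid, res)]


def _handle_puncta(config: RunConfig, fid: str, entries) -> list[dict[str, Any]]:
    _, chans = entries[0]
    myc, tuj1, mask = _need(chans, "myc", "tuj1", "cellmask")
    res = neurite_assays.axonal_puncta_density(
        read_tiff(myc), read_tiff(tuj1), _mask_from_tiff(mask)
    )
    return [_axon_row(fid, res)]


def _handle_viability(config: RunConfig, fid: str, entries) -> list[dict[str, Any]]:
    _, chans = entries[0]
    cal, hoe = _need(chans, "calcein", "hoechst")
    res = viability.count_viable_cells(
        read_tiff(cal),
        read_tiff(hoe),
        field_id=fid,
        min_area=config.soma_min_area,
        min_circ=config.soma_min_circ,
        max_circ=config.soma_max_circ,
    )
    return [{"well": fid, "assay": "viability", "value": res.viable_count}]


def _handle_retina(config: RunConfig, eye: str, entries) -> list[dict[str, Any]]:
    pcjun_fields, labelmaps = [], []
    for _, chans in entries:
        d, b, p = _need(chans, "dapi", "brn3a", "pcjun")
        labelmaps.append(retina_quant.rgc_nuclear_mask(read_tiff(d), read_tiff(b)))
        pcjun_fields.append(read_tiff(p))
    res = retina_quant.pcjun_per_eye(pcjun_fields, labelmaps, eye_id=eye)
    return [
        {
            "well": eye,
            "assay": "retina",
            "value": res.eye_value,
            "n_fields": len(res.field_means),
        }
    ]


def _axon_row(fid: str, res: neurite_assays.AxonFieldResult) -> dict[str, Any]:
    return {
        "well": fid,
        "assay": res.assay,
        "value": res.value,
        "n_objects": res.n_objects,
        "axon_area_fraction": res.axon_area_fraction,
    }


_FIELD_HANDLERS = {
    "hcs-quant": _handle_hcs,
    "axon-index": _handle_axon,
    "accumulation": _handle_accum,
    "puncta": _handle_puncta,
    "viability": _handle_viability,
    "retina": _handle_retina,
}
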