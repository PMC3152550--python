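"""End-to-end pipeline: simulate -> segment -> quantify -> screen.

``run_pipeline`` executes the whole chain for one simulated plate and writes
per-well metrics, per-extract calls and a JSON report embedding the exact
configuration and seed, so reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import write_plate_images, write_plate_map
from .quantify import per_cell_measurements, summarize_well, WellSummary
from .screen import (
    QCRecord,
    assay_window,
    average_duplicates,
    call_hits,
    co_occurrence,
    default_plate_layout,
    hit_rate,
    plate_normal_range,
)
from .segment import SegmentationParams, segment_field
from .synth import (
    FieldData,
    PlateSpec,
    ScenarioConfig,
    scenario_library,
    screen_plate_scenario,
)

log = logging.getLogger("ldscreen")

__all__ = ["process_well", "analyze_plate", "run_pipeline"]


def process_well(
    field_images: List[Tuple[np.ndarray, np.ndarray]],
    params: SegmentationParams,
    well_id: str = "",
    background: str = "median",
    histogram_cap: int = 80,
) -> WellSummary:
    """Segment and quantify one well given (nuclei, droplets) image pairs."""
    records = []
    for nuclei_img, droplet_img in field_images:
        seg = segment_field(nuclei_img, droplet_img, params)
        records.append(per_cell_measurements(seg, droplet_img, background=background))
    return summarize_well(records, well_id=well_id, histogram_cap=histogram_cap)


def analyze_plate(
    fields: Dict[str, List[FieldData]],
    layout: pd.DataFrame,
    params: SegmentationParams,
    k: float = 1.0,
    sd_ddof: int = 0,
    background: str = "median",
    histogram_cap: int = 80,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict, Dict[str, WellSummary]]:
    """Well metrics -> duplicate averaging -> hit calling -> QC for one plate.

    Returns (well_metrics, calls, report, summaries).
    """
    summaries: Dict[str, WellSummary] = {}
    rows = []
    for well, fdata in fields.items():
        try:
            ws = process_well(
                [(fd.nuclei, fd.droplets) for fd in fdata],
                params,
                well_id=well,
                background=background,
                histogram_cap=histogram_cap,
            )
        except Exception as err:  # explicit well context on stage failure
            raise RuntimeError(f"well {well}: segmentation/quantification failed") from err
        summaries[well] = ws
        rows.append(
            {
                "well_id": well,
                "n_cells": ws.n_cells,
                "mean_lds_per_cell": ws.mean_lds_per_cell,
                "nuclei_per_field": ws.nuclei_per_field,
                "mean_integrated_intensity": ws.mean_integrated_intensity,
            }
        )
    well_metrics = pd.DataFrame(rows)

    extract_metrics = average_duplicates(well_metrics, layout)
    extracts_only = extract_metrics[~extract_metrics["is_control"]]
    ld_range = plate_normal_range(extracts_only["mean_lds_per_cell"], k=k, ddof=sd_ddof)
    nuc_range = plate_normal_range(extracts_only["nuclei_per_field"], k=k, ddof=sd_ddof)
    calls = call_hits(extract_metrics, ld_range, nuc_range)

    n_extracts = int((~calls["is_control"]).sum())
    cooc = co_occurrence(calls[~calls["is_control"]])

    # control-based QC on mean LDs/cell: triacsin-C (inhibited) vs inactive extract (loaded)
    qc: Optional[QCRecord] = None
    pos = well_metrics.merge(layout, on="well_id")
    tri = pos.loc[pos["role"] == "triacsin-C", "mean_lds_per_cell"].dropna()
    ina = pos.loc[pos["role"] == "inactive-extract", "mean_lds_per_cell"].dropna()
    if len(tri) >= 2 and len(ina) >= 2:
        qc = assay_window(tri, ina, ddof=sd_ddof)

    report = {
        "n_extracts": n_extracts,
        "hit_counts": cooc,
        "hit_rate_increase_pct": hit_rate(cooc["n_ld_increase"], n_extracts),
        "hit_rate_decrease_pct": hit_rate(cooc["n_ld_decrease"], n_extracts),
        "hit_rate_cytotoxic_pct": hit_rate(cooc["n_cytotoxic"], n_extracts),
        "ld_normal_range": dataclasses.asdict(ld_range),
        "nuclei_normal_range": dataclasses.asdict(nuc_range),
        "qc": dataclasses.asdict(qc) if qc is not None else None,
    }
    return well_metrics, calls, report, summaries


def _resolve_scenario(config: RunConfig) -> ScenarioConfig:
    if config.scenario == "primary-screen":
        return screen_plate_scenario(n_extracts=config.n_extracts, ld_rate=35.0)
    lib = scenario_library()
    if config.scenario not in lib:
        raise KeyError(f"unknown scenario {config.scenario!r}; known: {sorted(lib)}")
    return lib[config.scenario]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate one plate under ``config`` and screen it end-to-end.

    Writes plate map, per-well metrics, per-extract calls, per-well truth and
    a JSON report (with the embedded config and seed) under
    ``config.out_dir``; returns the report dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_pipeline: scenario=%s seed=%d", config.scenario, config.seed)

    scenario = _resolve_scenario(config)
    rng = np.random.default_rng(config.seed) if config.shuffle_layout else None
    layout = default_plate_layout(n_extracts=config.n_extracts, rng=rng)
    spec = PlateSpec(
        layout=layout,
        scenario=scenario,
        fields_per_well=config.fields_per_well,
        base_params=config.scene,
        seed=config.seed,
    )
    fields, well_truth = render_plate_logged(spec)
    if config.write_images:
        write_plate_images(out / "images", "001", fields)

    well_metrics, calls, report, _ = analyze_plate(
        fields,
        layout,
        config.segmentation,
        k=config.k,
        sd_ddof=config.sd_ddof,
        background=config.background,
        histogram_cap=config.histogram_cap,
    )

    write_plate_map(layout, out / "plate_map.csv")
    well_metrics.to_csv(out / "well_metrics.csv", index=False)
    calls.to_csv(out / "extract_calls.csv", index=False)
    well_truth.to_csv(out / "well_truth.csv", index=False)
    report_full = {
        "config": config.to_dict(),
        "seed": config.seed,
        **report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report_full, fh, indent=2, sort_keys=True, default=float)
    log.info(
        "hits: +%d / -%d / tox %d of %d extracts",
        report["hit_counts"]["n_ld_increase"],
        report["hit_counts"]["n_ld_decrease"],
        report["hit_counts"]["n_cytotoxic"],
        report["n_extracts"],
    )
    return report_full


def render_plate_logged(spec: PlateSpec):
    from .synth import render_plate

    try:
        return render_plate(spec)
    except Exception as err:
        raise RuntimeError(f"plate simulation failed: {err}") from err
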