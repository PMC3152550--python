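"""Ground-truth validation experiments.

Each function simulates a known condition, runs the full measurement chain
on the rendered images, and compares the result against the planted truth.
They back both the acceptance test suite and ``scripts/acceptance.py``.
Problem sizes are desk-scale stand-ins (documented in the methods note); the
seed argument drives every source of randomness.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import RunConfig
from .pipeline import analyze_plate
from .quantify import distribution_shift, ld_histogram, per_cell_measurements
from .screen import default_plate_layout, fit_uptake, fold_change, percent_inhibition
from .segment import SegmentationParams, segment_field
from .synth import (
    OLEIC_RATE,
    TRIACSIN_LADDER,
    PlateSpec,
    SceneParams,
    UptakeKinetics,
    render_scene,
    scenario_library,
    screen_plate_scenario,
    simulate_uptake_series,
)

__all__ = [
    "measure_field",
    "count_recovery",
    "regime_recovery",
    "triacsin_ladder",
    "inhibitor_inhibition",
    "plate_screen",
    "kinetics_recovery",
]


def _child_seeds(seed: int, n: int, tag: int) -> List[int]:
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]


def measure_field(params: SceneParams, seg_params: Optional[SegmentationParams] = None):
    """Render one field and measure it; returns (truth, per-cell records)."""
    if seg_params is None:
        seg_params = SegmentationParams(cytoplasm_radius_px=params.cytoplasm_radius_px)
    nuc, drp, truth = render_scene(params)
    seg = segment_field(nuc, drp, seg_params)
    records = per_cell_measurements(seg, drp)
    return truth, records


def count_recovery(
    seed: int,
    n_fields: int = 20,
    params: Optional[SceneParams] = None,
) -> Dict[str, float]:
    """Mean-LDs/cell recovery on fields with known Poisson rate.

    Default condition: 30 cells per 512x512 field at rate 20, spot SNR well
    above 5. Cells are pooled over fields; reports the measured and true
    pooled means and their relative error.
    """
    if params is None:
        params = SceneParams(n_cells=30, ld_rate=20.0)
    true_total = 0
    true_cells = 0
    meas_total = 0
    meas_cells = 0
    for s in _child_seeds(seed, n_fields, tag=2):
        truth, records = measure_field(replace(params, seed=s))
        true_total += int(truth.cells["ld_count"].sum())
        true_cells += truth.n_cells
        meas_total += int(records["ld_count"].sum())
        meas_cells += len(records)
    true_mean = true_total / true_cells
    meas_mean = meas_total / meas_cells
    return {
        "true_mean": true_mean,
        "measured_mean": meas_mean,
        "rel_error_pct": 100.0 * abs(meas_mean - true_mean) / true_mean,
        "n_fields": n_fields,
        "n_cells": meas_cells,
    }


def regime_recovery(seed: int, n_seeds: int = 20, params: Optional[SceneParams] = None) -> Dict[str, float]:
    """Delipidated vs oleic-loaded regime: measured baseline and fold change.

    One delipidated and one loaded field per seed at the default scenario
    rates; cells pooled across seeds before the fold change is taken. Loaded
    cells are rendered at the spread-cell imaging scale (cytoplasm radius
    60 px) so that individual droplets stay resolvable at ~35 LDs/cell.
    """
    if params is None:
        params = SceneParams(n_cells=30, cytoplasm_radius_px=60.0)
    lib = scenario_library()["oleic-loading"]
    lam_d = lib.ld_rate("delipidated")
    lam_o = lib.ld_rate("oleic")
    totals = {"delipidated": [0, 0], "oleic": [0, 0]}
    seeds = _child_seeds(seed, 2 * n_seeds, tag=3)
    for i in range(n_seeds):
        for j, (name, lam) in enumerate((("delipidated", lam_d), ("oleic", lam_o))):
            _, records = measure_field(replace(params, ld_rate=lam, seed=seeds[2 * i + j]))
            totals[name][0] += int(records["ld_count"].sum())
            totals[name][1] += len(records)
    mean_d = totals["delipidated"][0] / totals["delipidated"][1]
    mean_o = totals["oleic"][0] / totals["oleic"][1]
    return {
        "delipidated_mean": mean_d,
        "oleic_mean": mean_o,
        "fold_change": fold_change(mean_o, mean_d),
        "n_seeds": n_seeds,
    }


def triacsin_ladder(seed: int, n_seeds: int = 20, params: Optional[SceneParams] = None) -> Dict[str, object]:
    """Dose ladder of the triacsin-C scenario: monotone means and left shifts.

    For each seed one well per dose is rendered and measured; reports per-seed
    whether measured means strictly decrease along the ladder and whether every
    dose step shifts the LD-count histogram left (negative shift). Uses the
    spread-cell imaging scale (see :func:`regime_recovery`).
    """
    if params is None:
        params = SceneParams(n_cells=30, cytoplasm_radius_px=60.0)
    concs = sorted(TRIACSIN_LADDER)
    rates = [OLEIC_RATE * TRIACSIN_LADDER[c] for c in concs]
    seeds = _child_seeds(seed, n_seeds * len(rates), tag=4)
    monotone: List[bool] = []
    left_shift: List[bool] = []
    mean_by_dose = np.zeros(len(rates))
    k = 0
    for _ in range(n_seeds):
        means = []
        hists = []
        for lam in rates:
            _, records = measure_field(replace(params, ld_rate=lam, seed=seeds[k]))
            k += 1
            means.append(float(records["ld_count"].mean()))
            hists.append(ld_histogram(records["ld_count"]))
        means = np.array(means)
        mean_by_dose += means
        monotone.append(bool(np.all(np.diff(means) < 0)))
        shifts = [distribution_shift(hists[i], hists[i + 1]) for i in range(len(hists) - 1)]
        left_shift.append(bool(np.all(np.array(shifts) < 0)))
    return {
        "concentrations_uM": concs,
        "mean_response": (mean_by_dose / n_seeds).tolist(),
        "monotone_fraction": float(np.mean(monotone)),
        "left_shift_fraction": float(np.mean(left_shift)),
        "n_seeds": n_seeds,
    }


def inhibitor_inhibition(
    seed: int,
    n_seeds: int = 5,
    at_concentration: float = 20.0,
    params: Optional[SceneParams] = None,
) -> Dict[str, float]:
    """Measured percent inhibition of an inhibitor ladder at one dose.

    Controls: oleic-loaded (positive, 0% inhibition) and delipidated
    (baseline, 100%); cells pooled over seeds. Uses the spread-cell imaging
    scale (see :func:`regime_recovery`).
    """
    if params is None:
        params = SceneParams(n_cells=30, cytoplasm_radius_px=60.0)
    lib = scenario_library()["inhibitor-dose-series"]
    lam_t = lib.ld_rate("inhibitor", at_concentration)
    lam_d = lib.ld_rate("delipidated")
    lam_o = lib.ld_rate("oleic")
    sums = {"treated": [0, 0], "delip": [0, 0], "oleic": [0, 0]}
    seeds = _child_seeds(seed, 3 * n_seeds, tag=5)
    for i in range(n_seeds):
        for j, (key, lam) in enumerate(
            (("treated", lam_t), ("delip", lam_d), ("oleic", lam_o))
        ):
            _, records = measure_field(replace(params, ld_rate=lam, seed=seeds[3 * i + j]))
            sums[key][0] += int(records["ld_count"].sum())
            sums[key][1] += len(records)
    means = {k: v[0] / v[1] for k, v in sums.items()}
    return {
        "concentration_uM": at_concentration,
        "inhibition_pct": percent_inhibition(means["treated"], means["oleic"], means["delip"]),
        "planted_inhibition_pct": percent_inhibition(lam_t, lam_o, lam_d),
        "n_seeds": n_seeds,
    }


PLANTED_FLAGS = {
    "EXT01": "ld_increase",
    "EXT02": "ld_decrease",
    "EXT03": "ld_decrease",
    "EXT04": "cytotoxic",
    "EXT05": "cytotoxic",
}


def plate_screen(seed: int, n_seeds: int = 20, config: Optional[RunConfig] = None) -> Dict[str, object]:
    """Whole-plate screen with planted actives, repeated over seeds.

    Each plate: 42 extracts in duplicate plus control wells, with one LD
    increaser (3x rate), two decreasers (0.4x) and two cytotoxic extracts
    (survival 0.3) planted at known identities. Sensitivity is the fraction
    of planted actives receiving their correct flag; false positives count
    plain extracts receiving any flag (extra LD flags on planted actives are
    co-occurrence, not errors).
    """
    if config is None:
        config = RunConfig()
    scenario = screen_plate_scenario(n_extracts=config.n_extracts)
    sens: List[float] = []
    fps: List[int] = []
    zprimes: List[float] = []
    for s in _child_seeds(seed, n_seeds, tag=6):
        from .synth import render_plate

        layout = default_plate_layout(
            n_extracts=config.n_extracts, rng=np.random.default_rng(s)
        )
        spec = PlateSpec(
            layout=layout,
            scenario=scenario,
            fields_per_well=config.fields_per_well,
            base_params=config.scene,
            seed=s,
        )
        fields, _truth = render_plate(spec)
        _wm, calls, report, _ = analyze_plate(
            fields,
            layout,
            config.segmentation,
            k=config.k,
            sd_ddof=config.sd_ddof,
            background=config.background,
        )
        ext = calls[~calls["is_control"]].set_index("treatment")
        correct = sum(
            bool(ext.loc[eid, flag]) for eid, flag in PLANTED_FLAGS.items()
        )
        plain = ext.drop(index=list(PLANTED_FLAGS))
        fp = int((plain["ld_increase"] | plain["ld_decrease"] | plain["cytotoxic"]).sum())
        sens.append(correct / len(PLANTED_FLAGS))
        fps.append(fp)
        if report["qc"] is not None:
            zprimes.append(report["qc"]["z_prime"])
    return {
        "sensitivity_per_seed": sens,
        "false_positives_per_seed": fps,
        "median_sensitivity_pct": float(100.0 * np.median(sens)),
        "median_false_positives": float(np.median(fps)),
        "median_z_prime": float(np.median(zprimes)) if zprimes else float("nan"),
        "n_seeds": n_seeds,
        "n_extracts": config.n_extracts,
    }


def kinetics_recovery(
    seed: int,
    n_seeds: int = 20,
    noise_frac: float = 0.02,
    kinetics: Optional[UptakeKinetics] = None,
    times: Optional[Sequence[float]] = None,
) -> Dict[str, float]:
    """Uptake-fit parameter recovery: exact on noiseless data, robust at 2% noise."""
    if kinetics is None:
        kinetics = UptakeKinetics(i_max=100.0, tau_min=10.0 / 3.0)
    if times is None:
        times = np.arange(1.0, 61.0)
    times = np.asarray(times, dtype=float)

    clean = simulate_uptake_series(kinetics, times)
    fit0 = fit_uptake(times, clean)
    noiseless_err = max(
        abs(fit0.i_max - kinetics.i_max) / kinetics.i_max,
        abs(fit0.tau - kinetics.tau_min) / kinetics.tau_min,
    )
    tau_errs = []
    imax_errs = []
    for s in _child_seeds(seed, n_seeds, tag=7):
        y = simulate_uptake_series(kinetics, times, noise_frac=noise_frac, rng=np.random.default_rng(s))
        fit = fit_uptake(times, y)
        if not fit.success:
            tau_errs.append(np.inf)
            imax_errs.append(np.inf)
            continue
        tau_errs.append(abs(fit.tau - kinetics.tau_min) / kinetics.tau_min)
        imax_errs.append(abs(fit.i_max - kinetics.i_max) / kinetics.i_max)
    return {
        "noiseless_max_rel_error": noiseless_err,
        "tau_median_rel_error_pct": float(100.0 * np.median(tau_errs)),
        "imax_median_rel_error_pct": float(100.0 * np.median(imax_errs)),
        "t_plateau_min": fit0.t_plateau,
        "n_seeds": n_seeds,
    }
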