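"""Plate-level analytics: duplicate averaging, normal-range hit calling,
percent inhibition, dose-response, uptake kinetics and assay QC.

The hit-calling rule is plate-wise: every extract is duplicate-averaged, the
mean +/- k*SD "normal range" is computed over the extract-level values of the
plate (controls excluded), and an extract is flagged when its metric falls
outside that range -- above the upper bound for an LD increase, below the
lower bound for an LD decrease, and below the lower nuclei-per-field bound
for cytotoxicity (a loss of cells; elevated counts are not treated as toxic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NormalRange",
    "DoseResponseResult",
    "KineticsFit",
    "QCRecord",
    "default_plate_layout",
    "average_duplicates",
    "plate_normal_range",
    "call_hits",
    "co_occurrence",
    "hit_rate",
    "percent_inhibition",
    "fold_change",
    "dose_response",
    "fit_uptake",
    "assay_window",
]

CONTROL_ROLES = ("inactive-extract", "triacsin-C", "media-only", "delipidated", "oleic")

LAYOUT_COLUMNS = ["well_id", "extract_id", "role", "concentration", "conc_units", "replicate"]


def default_plate_layout(
    n_extracts: int = 42,
    n_replicates: int = 2,
    n_inactive: int = 6,
    n_triacsin: int = 6,
    extract_concentration: float = 50.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """96-well screening layout: extracts in duplicate plus on-plate controls.

    Defaults follow the standard screening plate (42 extracts in duplicate at
    50 ug/mL plus inactive-extract and triacsin-C control wells). Pass an
    ``rng`` to shuffle the well assignment.
    """
    n_wells = n_extracts * n_replicates + n_inactive + n_triacsin
    if n_wells > 96:
        raise ValueError("layout exceeds a 96-well plate")
    wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)][:n_wells]
    rows = []
    for i in range(1, n_extracts + 1):
        for rep in range(1, n_replicates + 1):
            rows.append(
                dict(
                    extract_id=f"EXT{i:02d}",
                    role="extract",
                    concentration=extract_concentration,
                    conc_units="ug/mL",
                    replicate=rep,
                )
            )
    for rep in range(1, n_inactive + 1):
        rows.append(
            dict(extract_id="", role="inactive-extract", concentration=50.0, conc_units="ug/mL", replicate=rep)
        )
    for rep in range(1, n_triacsin + 1):
        rows.append(
            dict(extract_id="", role="triacsin-C", concentration=1.0, conc_units="uM", replicate=rep)
        )
    if rng is not None:
        order = rng.permutation(len(rows))
        rows = [rows[i] for i in order]
    df = pd.DataFrame(rows)
    df.insert(0, "well_id", wells)
    return df[LAYOUT_COLUMNS]


def average_duplicates(well_metrics: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Average per-well metrics over replicate wells of the same treatment.

    ``well_metrics`` needs ``well_id`` plus metric columns (any of
    mean_lds_per_cell, nuclei_per_field, mean_integrated_intensity).
    Returns one row per treatment with NaN-skipping arithmetic means; a
    treatment whose wells are all unusable (NaN) keeps NaN as an explicit
    missing value.
    """
    merged = well_metrics.merge(layout, on="well_id", how="inner", validate="one_to_one")
    if len(merged) == 0:
        raise ValueError("no well metrics matched the layout")
    merged["treatment"] = [
        str(r["extract_id"]) if r["role"] == "extract" else str(r["role"])
        for _, r in merged.iterrows()
    ]
    metric_cols = [
        c
        for c in ("mean_lds_per_cell", "nuclei_per_field", "mean_integrated_intensity")
        if c in merged.columns
    ]
    grouped = merged.groupby("treatment", sort=True)
    out = grouped[metric_cols].mean()  # pandas mean skips NaN
    out["n_wells"] = grouped.size()
    out["role"] = grouped["role"].first()
    out["is_control"] = out["role"] != "extract"
    return out.reset_index()


@dataclass(frozen=True)
class NormalRange:
    """Plate normal range: mean +/- k*sd over extract-level values."""

    mean: float
    sd: float
    lower: float
    upper: float
    k: float
    n: int
    ddof: int


def plate_normal_range(values: Sequence[float], k: float = 1.0, ddof: int = 0) -> NormalRange:
    """Mean and SD over duplicate-averaged extract values; bounds mean +/- k*sd.

    The SD convention is population SD by default (``ddof=0``); at typical
    plate sizes the difference from the sample SD is immaterial but the
    choice is pinned for reproducibility.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(vals) < 3:
        raise ValueError("plate normal range requires at least 3 finite values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    return NormalRange(mean=mean, sd=sd, lower=mean - k * sd, upper=mean + k * sd, k=k, n=len(vals), ddof=ddof)


def call_hits(
    extract_metrics: pd.DataFrame,
    ld_range: NormalRange,
    nuclei_range: NormalRange,
) -> pd.DataFrame:
    """Flag extracts outside the plate normal ranges.

    Adds boolean columns ``ld_increase``, ``ld_decrease`` (LDs/cell above or
    below the LD range) and ``cytotoxic`` (nuclei/field below the nuclei
    lower bound) plus audit columns recording the ranges used. Control rows
    (``is_control``) are passed through unflagged.
    """
    out = extract_metrics.copy()
    is_extract = ~out.get("is_control", pd.Series(False, index=out.index)).astype(bool)
    ld = out["mean_lds_per_cell"]
    nuc = out["nuclei_per_field"]
    out["ld_increase"] = is_extract & (ld > ld_range.upper)
    out["ld_decrease"] = is_extract & (ld < ld_range.lower)
    out["cytotoxic"] = is_extract & (nuc < nuclei_range.lower)
    out["ld_mean"] = ld_range.mean
    out["ld_sd"] = ld_range.sd
    out["nuclei_mean"] = nuclei_range.mean
    out["nuclei_sd"] = nuclei_range.sd
    out["k"] = ld_range.k
    assert not (out["ld_increase"] & out["ld_decrease"]).any()
    return out


def co_occurrence(calls: pd.DataFrame) -> Dict[str, int]:
    """Counts of flag co-occurrence (cytotoxic extracts that also shift LDs)."""
    cyto = calls["cytotoxic"]
    return {
        "n_ld_increase": int(calls["ld_increase"].sum()),
        "n_ld_decrease": int(calls["ld_decrease"].sum()),
        "n_cytotoxic": int(cyto.sum()),
        "n_cytotoxic_and_ld_increase": int((cyto & calls["ld_increase"]).sum()),
        "n_cytotoxic_and_ld_decrease": int((cyto & calls["ld_decrease"]).sum()),
    }


def hit_rate(n_hits: int, n_screened: int) -> int:
    """Hit rate as a whole-number percentage (rounded half away from zero)."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_hits <= n_screened):
        raise ValueError("n_hits must lie in [0, n_screened]")
    return int(math.floor(100.0 * n_hits / n_screened + 0.5))


def percent_inhibition(treated: float, positive_control: float, baseline: float) -> float:
    """Percent inhibition of LD formation.

    The positive control is the fully loaded (oleic-acid) condition, the
    baseline the delipidated condition: 100 * (1 - (treated - baseline) /
    (positive_control - baseline)). 0% at the loaded level, 100% at the
    delipidated level.
    """
    denom = positive_control - baseline
    if denom == 0:
        raise ZeroDivisionError("positive control equals baseline; inhibition undefined")
    return 100.0 * (1.0 - (treated - baseline) / denom)


def fold_change(condition_mean: float, baseline_mean: float) -> float:
    """Ratio of a condition mean to the baseline mean."""
    if baseline_mean == 0:
        raise ZeroDivisionError("baseline mean is zero; fold change undefined")
    return condition_mean / baseline_mean


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit y = bottom + (top-bottom)/(1+(x/midpoint)^slope)."""

    bottom: float
    top: float
    midpoint: float
    slope: float
    converged: bool


@dataclass
class DoseResponseResult:
    """Per-concentration responses plus trend and inhibition summaries."""

    concentrations: np.ndarray
    mean_response: np.ndarray
    sd_response: np.ndarray
    percent_inhibition: Optional[np.ndarray]
    trend_rho: float
    trend_pvalue: float
    trend_defined: bool
    sigmoid: Optional[SigmoidFit] = None


def _fit_sigmoid(conc: np.ndarray, resp: np.ndarray) -> Optional[SigmoidFit]:
    pos = conc > 0
    if pos.sum() < 3:
        return None

    def f(x, bottom, top, mid, slope):
        return bottom + (top - bottom) / (1.0 + (x / mid) ** slope)

    p0 = [float(resp.min()), float(resp.max()), float(np.median(conc[pos])), 1.0]
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
            f,
            conc[pos],
            resp[pos],
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return None
    bottom, top, mid, slope = (float(v) for v in popt)
    bracketed = conc[pos].min() <= mid <= conc[pos].max()
    return SigmoidFit(bottom=bottom, top=top, midpoint=mid, slope=slope, converged=bool(bracketed))


def dose_response(
    concentrations: Sequence[float],
    responses,
    positive_control: Optional[float] = None,
    baseline: Optional[float] = None,
    fit_sigmoid: bool = True,
) -> DoseResponseResult:
    """Summarise a concentration series of LDs/cell responses.

    ``responses`` is (n_conc,) or (n_conc, n_replicates). Concentrations must
    be strictly increasing with at least 3 levels. Percent inhibition is
    computed only when both controls are supplied. The monotone-trend
    statistic is the Spearman rank correlation of the mean response against
    concentration (undefined and flagged for constant responses). A
    four-parameter sigmoid midpoint is reported only when the fit converges
    and the midpoint lies within the dosed range.
    """
    conc = np.asarray(concentrations, dtype=float)
    if len(conc) < 3:
        raise ValueError("at least 3 concentrations are required")
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be strictly increasing")
    resp = np.asarray(responses, dtype=float)
    if resp.ndim == 1:
        resp = resp[:, None]
    if resp.shape[0] != len(conc):
        raise ValueError("responses must have one row per concentration")
    mean_resp = resp.mean(axis=1)
    sd_resp = resp.std(axis=1, ddof=0)

    inhibition = None
    if positive_control is not None and baseline is not None:
        inhibition = np.array(
            [percent_inhibition(v, positive_control, baseline) for v in mean_resp]
        )

    if np.allclose(mean_resp, mean_resp[0]):
        rho, pval, defined = 0.0, float("nan"), False
    else:
        rho, pval = stats.spearmanr(conc, mean_resp)
        defined = bool(np.isfinite(rho))

    sig = _fit_sigmoid(conc, mean_resp) if fit_sigmoid and defined else None
    if sig is not None and not sig.converged:
        sig = None
    return DoseResponseResult(
        concentrations=conc,
        mean_response=mean_resp,
        sd_response=sd_resp,
        percent_inhibition=inhibition,
        trend_rho=float(rho),
        trend_pvalue=float(pval) if defined else float("nan"),
        trend_defined=defined,
        sigmoid=sig,
    )


@dataclass
class KineticsFit:
    """Saturating-uptake fit I(t) = i_max * (1 - exp(-t/tau)).

    ``t_plateau`` is the time to 95% of i_max (= 3*tau). ``success`` is False
    (with NaN parameters) when the fit fails or hits a degenerate input;
    failure is explicit, never silent defaults.
    """

    i_max: float
    tau: float
    t_plateau: float
    residual_rms: float
    success: bool


def fit_uptake(times: Sequence[float], intensities: Sequence[float]) -> KineticsFit:
    """Least-squares fit of the single-exponential saturation model."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 4:
        raise ValueError("at least 4 time points are required")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("times must be non-negative")
    failure = KineticsFit(float("nan"), float("nan"), float("nan"), float("nan"), False)
    if not np.all(np.isfinite(y)) or np.allclose(y, 0) or y.max() <= 0:
        return failure

    def f(tt, i_max, tau):
        return i_max * (1.0 - np.exp(-tt / tau))

    i0 = float(y.max())
    above = t[y >= 0.63 * i0]
    tau0 = float(above[0]) if len(above) and above[0] > 0 else max(float(t[-1]) / 3.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            f, t, y, p0=[i0, tau0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000
        )
    except (RuntimeError, ValueError):
        return failure
    i_max, tau = float(popt[0]), float(popt[1])
    if not (i_max > 0 and tau > 0):
        return failure
    resid = y - f(t, i_max, tau)
    return KineticsFit(
        i_max=i_max,
        tau=tau,
        t_plateau=3.0 * tau,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        success=True,
    )


@dataclass
class QCRecord:
    """Control-based plate QC: Z'-factor and assay window."""

    z_prime: float
    window: float
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    defined: bool


def assay_window(positive_wells: Sequence[float], negative_wells: Sequence[float], ddof: int = 0) -> QCRecord:
    """Quantify the separation between control distributions.

    ``positive_wells`` are the inhibited control (triacsin-C, low signal),
    ``negative_wells`` the loaded control (high signal). Z' = 1 - 3*(sd_pos +
    sd_neg) / |mu_pos - mu_neg|; the assay window is mu_neg / mu_pos. Equal
    control means yield an undefined (NaN, flagged) record.
    """
    pos = np.asarray(positive_wells, dtype=float)
    neg = np.asarray(negative_wells, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("at least 2 wells per control class are required")
    mu_p, sd_p = float(pos.mean()), float(pos.std(ddof=ddof))
    mu_n, sd_n = float(neg.mean()), float(neg.std(ddof=ddof))
    if mu_p == mu_n:
        return QCRecord(float("nan"), float("nan"), mu_p, sd_p, mu_n, sd_n, False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    window = mu_n / mu_p if mu_p != 0 else float("nan")
    return QCRecord(z_prime=z, window=window, mu_pos=mu_p, sd_pos=sd_p, mu_neg=mu_n, sd_neg=sd_n, defined=True)
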