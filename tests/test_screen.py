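"""Plate analytics: averaging, normal ranges, hit calls, dose-response, kinetics, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldscreen.screen import (
    assay_window,
    average_duplicates,
    call_hits,
    co_occurrence,
    default_plate_layout,
    dose_response,
    fit_uptake,
    fold_change,
    hit_rate,
    percent_inhibition,
    plate_normal_range,
)


def layout_for(treatments):
    rows = []
    for i, t in enumerate(treatments):
        role = "extract" if t.startswith("EXT") else t
        rows.append(
            dict(
                well_id=f"W{i:02d}",
                extract_id=t if role == "extract" else "",
                role=role,
                concentration=50.0,
                conc_units="ug/mL",
                replicate=1,
            )
        )
    return pd.DataFrame(rows)


def metrics_for(values, treatments):
    return pd.DataFrame(
        {
            "well_id": [f"W{i:02d}" for i in range(len(values))],
            "mean_lds_per_cell": values,
            "nuclei_per_field": [10.0] * len(values),
        }
    )


# ---------------------------------------------------------------------------
# duplicate averaging


@pytest.mark.parametrize(
    "values,expected",
    [([12.0, 8.0], 10.0), ([7.0], 7.0), ([1.0, 2.0, 6.0], 3.0)],
)
def test_average_duplicates_arithmetic(values, expected):
    treatments = ["EXT01"] * len(values)
    out = average_duplicates(metrics_for(values, treatments), layout_for(treatments))
    assert out.loc[out["treatment"] == "EXT01", "mean_lds_per_cell"].iloc[0] == pytest.approx(expected)


def test_average_duplicates_keeps_missing_explicit():
    treatments = ["EXT01", "EXT01"]
    m = metrics_for([np.nan, np.nan], treatments)
    out = average_duplicates(m, layout_for(treatments))
    assert np.isnan(out.loc[out["treatment"] == "EXT01", "mean_lds_per_cell"].iloc[0])


# ---------------------------------------------------------------------------
# normal range


def test_normal_range_example_population_sd():
    nr = plate_normal_range([8.0, 10.0, 12.0], k=1.0)
    assert nr.mean == pytest.approx(10.0)
    assert nr.sd == pytest.approx(1.63299, abs=1e-4)
    assert nr.lower == pytest.approx(8.36701, abs=1e-4)
    assert nr.upper == pytest.approx(11.63299, abs=1e-4)


def test_normal_range_degenerate_plate():
    nr = plate_normal_range([10.0] * 42)
    assert nr.sd == 0.0
    assert (nr.lower, nr.upper) == (10.0, 10.0)


def test_normal_range_requires_three_values():
    with pytest.raises(ValueError):
        plate_normal_range([1.0, 2.0])


def test_normal_range_sample_sd_option():
    nr = plate_normal_range([8.0, 10.0, 12.0], ddof=1)
    assert nr.sd == pytest.approx(2.0)


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    st.floats(-50, 50),
)
def test_normal_range_translation_equivariance(values, c):
    a = plate_normal_range(values)
    b = plate_normal_range([v + c for v in values])
    assert b.mean == pytest.approx(a.mean + c, abs=1e-8)
    assert b.lower == pytest.approx(a.lower + c, abs=1e-8)
    assert b.upper == pytest.approx(a.upper + c, abs=1e-8)


# ---------------------------------------------------------------------------
# hit calling


def extract_table(ld_values, nuclei_values=None):
    n = len(ld_values)
    if nuclei_values is None:
        nuclei_values = [10.0] * n
    return pd.DataFrame(
        {
            "treatment": [f"EXT{i:02d}" for i in range(n)],
            "mean_lds_per_cell": ld_values,
            "nuclei_per_field": nuclei_values,
            "is_control": [False] * n,
        }
    )


def test_degenerate_plate_has_zero_flags():
    tbl = extract_table([10.0] * 42)
    nr_ld = plate_normal_range(tbl["mean_lds_per_cell"])
    nr_nu = plate_normal_range(tbl["nuclei_per_field"])
    calls = call_hits(tbl, nr_ld, nr_nu)
    assert not calls[["ld_increase", "ld_decrease", "cytotoxic"]].any().any()


def test_single_outlier_flagged_by_direct_mean_sd_oracle():
    values = [10.0] * 41 + [100.0]
    tbl = extract_table(values)
    nr_ld = plate_normal_range(tbl["mean_lds_per_cell"])
    # brute-force oracle
    mean = np.mean(values)
    sd = np.std(values)
    assert nr_ld.mean == pytest.approx(mean)
    assert nr_ld.sd == pytest.approx(sd)
    assert 100.0 > mean + sd
    calls = call_hits(tbl, nr_ld, plate_normal_range(tbl["nuclei_per_field"]))
    assert calls["ld_increase"].sum() == 1
    assert calls.loc[calls["ld_increase"], "mean_lds_per_cell"].iloc[0] == 100.0
    assert not calls["ld_decrease"].any()


def test_co_occurrence_counts_cytotoxic_overlap():
    ld = [10.0] * 39 + [30.0, 10.0, 10.0]
    nuclei = [10.0] * 39 + [2.0, 2.0, 2.0]  # last three cytotoxic, first of them also LD-up
    tbl = extract_table(ld, nuclei)
    calls = call_hits(tbl, plate_normal_range(ld), plate_normal_range(nuclei))
    table = co_occurrence(calls)
    assert table["n_cytotoxic"] == 3
    assert table["n_cytotoxic_and_ld_increase"] == 1


def test_hit_calling_invariant_to_well_order_and_controls():
    treatments = ["EXT01", "EXT01", "EXT02", "EXT02", "EXT03", "EXT03", "triacsin-C", "inactive-extract"]
    values = [10.0, 12.0, 30.0, 28.0, 11.0, 9.0, 2.0, 20.0]
    layout = layout_for(treatments)
    metrics = metrics_for(values, treatments)

    def run(perm):
        m = metrics.iloc[list(perm)].reset_index(drop=True)
        ext = average_duplicates(m, layout)
        ext_only = ext[~ext["is_control"]]
        nr_ld = plate_normal_range(ext_only["mean_lds_per_cell"])
        nr_nu = plate_normal_range(ext_only["nuclei_per_field"])
        calls = call_hits(ext, nr_ld, nr_nu)
        return calls.sort_values("treatment")[["treatment", "ld_increase", "ld_decrease"]]

    base = run(range(8))
    shuffled = run([7, 3, 0, 5, 2, 6, 1, 4])
    pd.testing.assert_frame_equal(base.reset_index(drop=True), shuffled.reset_index(drop=True))
    assert base.set_index("treatment").loc["EXT02", "ld_increase"]


# ---------------------------------------------------------------------------
# rates and ratios


@pytest.mark.parametrize("n_hits,n_screened,expected", [(87, 2184, 4), (27, 2184, 1), (0, 100, 0)])
def test_hit_rate_rounds_to_whole_percent(n_hits, n_screened, expected):
    assert hit_rate(n_hits, n_screened) == expected


def test_hit_rate_input_validation():
    with pytest.raises(ValueError):
        hit_rate(1, 0)
    with pytest.raises(ValueError):
        hit_rate(5, 4)


@pytest.mark.parametrize(
    "treated,pos,base,expected",
    [(33.0, 33.0, 3.0, 0.0), (3.0, 33.0, 3.0, 100.0), (15.0, 33.0, 3.0, 60.0)],
)
def test_percent_inhibition_examples(treated, pos, base, expected):
    assert percent_inhibition(treated, pos, base) == pytest.approx(expected)


def test_percent_inhibition_zero_window_errors():
    with pytest.raises(ZeroDivisionError):
        percent_inhibition(5.0, 10.0, 10.0)


@settings(deadline=None, derandomize=True)
@given(
    st.floats(-50, 50),
    st.floats(0.1, 10),
    st.floats(-20, 20),
)
def test_percent_inhibition_affine_invariant(treated, a, b):
    pos, base = 33.0, 3.0
    before = percent_inhibition(treated, pos, base)
    after = percent_inhibition(a * treated + b, a * pos + b, a * base + b)
    assert after == pytest.approx(before, abs=1e-6)


def test_fold_change_examples():
    assert fold_change(35.0, 3.5) == pytest.approx(10.0)
    assert fold_change(4.2, 4.2) == pytest.approx(1.0)
    with pytest.raises(ZeroDivisionError):
        fold_change(1.0, 0.0)


# ---------------------------------------------------------------------------
# dose response


def test_strictly_decreasing_responses_give_perfect_negative_trend():
    res = dose_response([1, 2, 4, 8, 16], [50, 40, 30, 20, 10])
    assert res.trend_defined
    assert res.trend_rho == pytest.approx(-1.0)


def test_constant_responses_are_flagged_undefined():
    res = dose_response([1, 2, 4], [10.0, 10.0, 10.0])
    assert not res.trend_defined
    assert res.trend_rho == 0.0
    assert res.sigmoid is None


def test_non_increasing_concentrations_rejected():
    with pytest.raises(ValueError):
        dose_response([1, 1, 2], [3, 2, 1])


def test_percent_inhibition_column_uses_controls():
    res = dose_response([1, 2, 4], [33.0, 18.0, 3.0], positive_control=33.0, baseline=3.0)
    assert res.percent_inhibition == pytest.approx([0.0, 50.0, 100.0])


def test_sigmoid_fit_recovers_midpoint_on_clean_data():
    conc = np.array([0.5, 1, 2, 4, 8, 16, 32])
    resp = 5 + (40 - 5) / (1 + (conc / 4.0) ** 1.5)
    res = dose_response(conc, resp)
    assert res.sigmoid is not None
    assert res.sigmoid.midpoint == pytest.approx(4.0, rel=1e-3)


# ---------------------------------------------------------------------------
# kinetics


def test_uptake_fit_exact_on_noiseless_data():
    t = np.arange(1.0, 61.0)
    y = 100.0 * (1 - np.exp(-t / 3.33))
    fit = fit_uptake(t, y)
    assert fit.success
    assert fit.i_max == pytest.approx(100.0, rel=1e-6)
    assert fit.tau == pytest.approx(3.33, rel=1e-6)
    assert fit.t_plateau == pytest.approx(3 * 3.33, rel=1e-6)


def test_uptake_fit_fails_explicitly_on_zero_signal():
    fit = fit_uptake([0, 1, 2, 3], [0.0, 0.0, 0.0, 0.0])
    assert not fit.success
    assert np.isnan(fit.tau)


def test_uptake_fit_input_validation():
    with pytest.raises(ValueError):
        fit_uptake([0, 1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_uptake([0, 2, 1, 3], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# QC


def test_z_prime_hand_arithmetic():
    qc = assay_window([5.0, 6.0, 4.0], [35.0, 36.0, 34.0], ddof=1)
    assert qc.z_prime == pytest.approx(1 - 6.0 / 30.0)
    assert qc.window == pytest.approx(35.0 / 5.0)


def test_z_prime_limit_and_degenerate_cases():
    qc = assay_window([5.0, 5.0], [35.0, 35.0])
    assert qc.z_prime == pytest.approx(1.0)
    und = assay_window([10.0, 12.0], [12.0, 10.0])
    assert not und.defined
    assert np.isnan(und.z_prime)


def test_default_layout_is_a_full_96_well_plate():
    layout = default_plate_layout()
    assert len(layout) == 96
    assert layout["well_id"].is_unique
    ext = layout[layout["role"] == "extract"]
    assert ext["extract_id"].nunique() == 42
    assert (ext.groupby("extract_id").size() == 2).all()
    assert (layout["role"] == "triacsin-C").sum() == 6
    assert (layout["role"] == "inactive-extract").sum() == 6
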