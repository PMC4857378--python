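"""Summary, accumulated and stabilization statistics across frames."""

import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from posturekit import (
    AccumulatedStatsRow,
    InsufficientDataError,
    MetricSeries,
    UndefinedReferenceError,
    accumulated_stats,
    aggregate_metrics,
    percent_error,
    repetitions_needed,
    round_half_up,
    summary_stats,
)

series_values = st.lists(
    st.floats(1.0, 100.0, allow_nan=False, allow_infinity=False), min_size=2, max_size=40
)


def test_round_half_up_differs_from_bankers():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.675, 2) == 2.68
    assert round_half_up(0.0254, 3) == 0.025
    assert round(0.125, 2) == 0.12  # what we are deliberately not doing


def test_known_rectangle_summary_statistics(table1):
    """30 repeated measurements of a 25 x 15 cm rectangle: the width
    series averages 24.99 with SD 0.22 and CV 0.88 %, the height series
    14.99 / 0.35 / 2.33 % under the printed-table rounding policy."""
    width = summary_stats(MetricSeries("width", table1.widths))
    assert round_half_up(width.mean) == 24.99
    assert round_half_up(width.sd) == 0.22
    assert round_half_up(width.cv) == 0.88
    assert (width.min, width.max) == (24.75, 25.8)

    height = summary_stats(MetricSeries("height", table1.heights))
    assert round_half_up(height.mean) == 14.99
    assert round_half_up(height.sd) == 0.35
    assert round_half_up(height.cv) == 2.33
    assert (height.min, height.max) == (14.56, 15.75)


def test_sample_not_population_sd(table1):
    """The published width SD (0.22) matches the n-1 denominator, not n."""
    v = np.asarray(table1.widths)
    assert round_half_up(float(v.std(ddof=1))) == 0.22
    assert round_half_up(float(v.std(ddof=0))) == 0.21


def test_accumulated_checkpoints_match_reference_table(table1):
    """Accumulated SD = sample SD of the running means; checkpoints at
    k=4, 5, 10 reproduce the published accumulated cells."""
    rows = accumulated_stats(MetricSeries("width", table1.widths))
    by_k = {r.k: r for r in rows}
    assert round_half_up(by_k[4].mean_accum) == 24.80
    assert round_half_up(by_k[4].sd_accum, 3) == 0.025
    assert round_half_up(by_k[5].mean_accum) == 24.86
    assert round_half_up(by_k[5].sd_accum, 3) == 0.050
    assert round_half_up(by_k[10].mean_accum) == 24.92
    assert round_half_up(by_k[10].sd_accum, 3) == 0.062

    hrows = {r.k: r for r in accumulated_stats(MetricSeries("height", table1.heights))}
    assert round_half_up(hrows[5].sd_accum, 3) == 0.017
    assert round_half_up(hrows[10].mean_accum) == 15.14


def test_constant_series_has_zero_spread():
    rows = accumulated_stats([7.0, 7.0, 7.0])
    assert all(r.sd_accum == 0 and r.cv_accum == 0 for r in rows)
    s = summary_stats([7.0, 7.0, 7.0])
    assert s.sd == 0 and s.cv == 0
    assert repetitions_needed(rows).k_stable == 2


@given(values=series_values)
def test_accumulated_stats_match_brute_force_oracle(values):
    """Running means by direct averaging and SDs by two-pass formula."""
    rows = accumulated_stats(MetricSeries("m", tuple(values)), rounding="exact")
    means = []
    for k in range(1, len(values) + 1):
        means.append(sum(values[:k]) / k)
        row = rows[k - 1]
        assert row.mean_accum == pytest.approx(means[-1], abs=1e-12, rel=1e-12)
        expected_sd = statistics.stdev(means) if k > 1 else 0.0
        assert row.sd_accum == pytest.approx(expected_sd, abs=1e-9, rel=1e-9)
    s = summary_stats(MetricSeries("m", tuple(values)), rounding="exact")
    assert s.mean == pytest.approx(rows[-1].mean_accum, abs=1e-12, rel=1e-12)
    assert s.sd == pytest.approx(statistics.stdev(values), abs=1e-9, rel=1e-9)
    assert s.cv == pytest.approx(100 * s.sd / s.mean, abs=1e-12)


@given(values=series_values)
def test_cv_nonnegative_and_zero_iff_sd_zero(values):
    s = summary_stats(values, rounding="exact")
    assert s.cv >= 0
    assert (s.cv == 0) == (s.sd == 0)


def test_rounding_policies_agree_closely_on_reference_data(table1):
    for values in (table1.widths, table1.heights):
        printed = accumulated_stats(values, rounding="printed-table")
        exact = accumulated_stats(values, rounding="exact")
        for p, e in zip(printed, exact):
            assert abs(p.cv_accum - e.cv_accum) <= 0.05
        sp = summary_stats(values, rounding="printed-table")
        se = summary_stats(values, rounding="exact")
        assert abs(sp.cv - se.cv) <= 0.05


def _rows_from_cv(cvs):
    return [AccumulatedStatsRow(k + 1, 10.0, cv / 10.0, cv) for k, cv in enumerate(cvs)]


def test_terminal_plateau_matches_exhaustive_scan():
    """A CV plateau injected at k=12 is found by the rule and by a
    brute-force scan over every candidate k."""
    cvs = [round(2.0 - 0.1 * k, 2) for k in range(11)] + [0.83] * 19
    rows = _rows_from_cv(cvs)
    result = repetitions_needed(rows)
    rounded = [round_half_up(c) for c in cvs]
    oracle = min(
        k for k in range(2, len(cvs) + 1)
        if all(r == rounded[-1] for r in rounded[k - 1:])
    )
    assert oracle == 12
    assert result.k_stable == 12 and result.stabilized


def test_terminal_plateau_idempotent_under_extension():
    cvs = [1.5, 1.2, 0.9, 0.83, 0.83, 0.83]
    base = repetitions_needed(_rows_from_cv(cvs))
    extended = repetitions_needed(_rows_from_cv(cvs + [0.83] * 5))
    assert base.k_stable == extended.k_stable == 4


def test_delta_threshold_rule_and_not_stabilized_flag():
    diverging = _rows_from_cv([float(k) for k in range(1, 12)])
    res = repetitions_needed(diverging, rule="delta-threshold", epsilon=0.05, window=3)
    assert not res.stabilized and res.k_stable is None
    settling = _rows_from_cv([3.0, 2.0, 1.0, 1.01, 1.02, 1.01, 1.0, 1.01])
    res = repetitions_needed(settling, rule="delta-threshold", epsilon=0.05, window=3)
    assert res.stabilized and res.k_stable == 3


def test_repetitions_needed_input_validation():
    with pytest.raises(InsufficientDataError):
        repetitions_needed(_rows_from_cv([1.0]))
    with pytest.raises(ValueError):
        repetitions_needed(_rows_from_cv([1.0, 1.0]), rule="no-such-rule")


@pytest.mark.parametrize(
    "measured, truth, expected",
    [(15, 15, 0.0), (24.75, 25, 1.0), (14.99, 15, 0.06667)],
)
def test_percent_error_literal_definition(measured, truth, expected):
    assert percent_error(measured, truth) == pytest.approx(expected, abs=1e-4)


def test_percent_error_zero_reference_rejected():
    with pytest.raises(UndefinedReferenceError):
        percent_error(1.0, 0.0)


def test_aggregate_metrics_counts_skips(table1):
    frames = table1.as_frames()
    del frames[3]["width"]
    out = aggregate_metrics(frames)
    assert out["width"].summary.n == 29
    assert out["width"].n_skipped == 1
    assert out["height"].summary.n == 30 and out["height"].n_skipped == 0


def test_aggregate_metrics_flags_sparse_metric(table1):
    frames = table1.as_frames()
    frames[0]["extra"] = 1.0  # present in a single frame
    out = aggregate_metrics(frames)
    assert out["extra"] is None
    with pytest.raises(InsufficientDataError):
        aggregate_metrics(frames[:1])


def test_identical_frames_have_zero_sd():
    out = aggregate_metrics([{"a": 2.0, "b": 3.0}] * 5)
    assert all(agg.summary.sd == 0 for agg in out.values())
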