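"""GEBV reliability formula, its inverse, and the preselection adjustment."""

import pytest
from hypothesis import given, settings, strategies as st

from refpop.ebv import (
    parent_average_reliability,
    progeny_test_reliability,
)
from refpop.genomic import (
    GenomeParams,
    ReferenceGroup,
    deselect_reliability,
    effective_segments,
    preselection_adjust,
    required_reference_size,
    unselected_reliability,
)
from refpop.truncation import variance_reduction

GENOME = GenomeParams(ne=100.0, length_morgans=30.0)


@pytest.mark.parametrize(
    "ne, length, expected",
    [(100, 30, 6000), (1, 0.5, 1), (750, 30, 45000)],
)
def test_effective_segments(ne, length, expected):
    assert effective_segments(GenomeParams(ne, length)) == expected


def test_unselected_reliability_reference_points():
    r2_bulls = progeny_test_reliability(50, 0.1)
    assert unselected_reliability(10000, 6000, r2_bulls) == pytest.approx(
        0.4836, abs=5e-5
    )
    assert unselected_reliability(20000, 6000, 0.3) == pytest.approx(0.5, abs=1e-12)
    assert unselected_reliability(0, 6000, 0.5) == 0.0


def test_unselected_reliability_monotone():
    vals_n = [unselected_reliability(n, 6000, 0.3) for n in (10, 1000, 10**5, 10**8)]
    assert all(a < b for a, b in zip(vals_n, vals_n[1:])) and vals_n[-1] < 1.0
    vals_r = [unselected_reliability(10000, 6000, r) for r in (0.05, 0.3, 0.9)]
    assert all(a < b for a, b in zip(vals_r, vals_r[1:]))


def test_required_reference_size_inverts_table_cell():
    assert required_reference_size(0.5, 6000, 0.3) == pytest.approx(20000)
    assert required_reference_size(0.0, 6000, 0.3) == 0.0
    with pytest.raises(ValueError):
        required_reference_size(1.0, 6000, 0.3)


@settings(max_examples=200, derandomize=True)
@given(
    n_ref=st.floats(1.0, 1e6),
    r2_info=st.floats(0.01, 1.0),
)
def test_size_reliability_round_trip(n_ref, r2_info):
    u = unselected_reliability(n_ref, 6000.0, r2_info)
    back = required_reference_size(u, 6000.0, r2_info)
    assert back == pytest.approx(n_ref, rel=1e-12)


def test_preselection_adjust_reference_scenarios():
    # bulls, h2=0.1, nP=10,000, 5% preselection on 50-daughter PA
    r2_pt = progeny_test_reliability(50, 0.1)
    u = unselected_reliability(10000, 6000, r2_pt)
    r2_pa = parent_average_reliability(r2_pt, 0.1)
    res = preselection_adjust(u, variance_reduction(0.05).k, r2_pa)
    assert res.ratio == pytest.approx(0.9209, abs=5e-5)
    assert res.r2_selected == pytest.approx(0.445309, abs=5e-6)

    # bulls, h2=0.3, nP=10,000: bias slope
    r2_pt = progeny_test_reliability(50, 0.3)
    u = unselected_reliability(10000, 6000, r2_pt)
    assert u == pytest.approx(0.5721, abs=5e-5)
    r2_pa = parent_average_reliability(r2_pt, 0.3)
    res = preselection_adjust(u, variance_reduction(0.05).k, r2_pa)
    assert res.bias_slope == pytest.approx(0.882, abs=5e-4)


def test_no_selection_is_identity():
    res = preselection_adjust(0.42, 0.0, 0.9)
    assert res.r2_selected == 0.42 and res.bias_slope == 1.0


def test_deselect_inverts_reference_scenario():
    k = variance_reduction(0.05).k
    back = deselect_reliability(0.445309, k, 0.165449)
    assert back == pytest.approx(0.4836, abs=5e-5)
    assert deselect_reliability(0.3, 0.0, 0.9) == 0.3


@settings(max_examples=200, derandomize=True)
@given(
    r2_u=st.floats(0.0, 0.999),
    p=st.floats(0.01, 1.0),
    r2_presel=st.floats(0.0, 1.0),
)
def test_adjust_deselect_round_trip_and_ordering(r2_u, p, r2_presel):
    k = variance_reduction(p).k
    res = preselection_adjust(r2_u, k, r2_presel)
    assert res.r2_selected <= r2_u + 1e-15
    assert 0.0 < res.bias_slope <= 1.0
    assert res.bias_slope * r2_u == pytest.approx(res.r2_selected, abs=1e-15)
    assert deselect_reliability(res.r2_selected, k, r2_presel) == pytest.approx(
        r2_u, abs=1e-12
    )


def test_bias_alleviated_by_larger_reference_population():
    k = variance_reduction(0.05).k
    slopes = [
        preselection_adjust(
            unselected_reliability(n, 6000, 0.562), k, 0.165
        ).bias_slope
        for n in (5000, 10000, 20000, 40000)
    ]
    assert all(a < b for a, b in zip(slopes, slopes[1:]))
    assert slopes[-1] < 1.0


def test_reference_group_pipeline_matches_manual_composition():
    regime = variance_reduction(0.05)
    r2_pt = progeny_test_reliability(50, 0.1)
    group = ReferenceGroup(
        label="bulls", n_ref=10000, r2_info=r2_pt,
        r2_presel=parent_average_reliability(r2_pt, 0.1), regime=regime,
    )
    res = group.reliability(GENOME)
    assert res.ratio == pytest.approx(0.9209, abs=5e-5)


def test_degenerate_selection_raises():
    with pytest.raises(ValueError):
        preselection_adjust(0.5, 1.2, 1.0)
    with pytest.raises(ValueError):
        GenomeParams(0, 30)
    with pytest.raises(ValueError):
        unselected_reliability(-1, 6000, 0.3)
    with pytest.raises(ValueError):
        unselected_reliability(100, 6000, 1.2)
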