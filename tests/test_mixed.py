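"""Bull-per-cow equivalence and mixed reference populations."""

import pytest
from hypothesis import given, settings, strategies as st

from refpop.ebv import (
    cow_ebv_reliability,
    parent_average_reliability,
    progeny_test_reliability,
)
from refpop.genomic import (
    GenomeParams,
    deselect_reliability,
    required_reference_size,
    unselected_reliability,
    preselection_adjust,
)
from refpop.mixed import (
    EquivalenceInputs,
    bull_cow_equivalence,
    combined_reliability,
    cow_value_mixed,
    general_equivalence,
)
from refpop.truncation import variance_reduction

GENOME = GenomeParams(ne=100.0, length_morgans=30.0)


def _equivalence_inputs(h2, p_bulls, p_cows):
    r2_m = progeny_test_reliability(50, h2)
    return EquivalenceInputs(
        r2_info_m=r2_m,
        r2_info_f=h2,
        r2_presel_m=parent_average_reliability(r2_m, h2),
        r2_presel_f=cow_ebv_reliability(h2),
        k_m=variance_reduction(p_bulls).k,
        k_f=variance_reduction(p_cows).k,
    )


@pytest.mark.parametrize(
    "h2, expected", [(0.1, 0.208), (0.5, 0.811)]
)
def test_bulls_per_cow_with_unselected_cows(h2, expected):
    inp = _equivalence_inputs(h2, 0.05, 1.0)
    assert round(bull_cow_equivalence(inp), 3) == expected


def test_without_preselection_only_information_ratio_matters():
    inp = _equivalence_inputs(0.1, 1.0, 1.0)
    assert bull_cow_equivalence(inp) == pytest.approx(
        0.1 / progeny_test_reliability(50, 0.1)
    )
    assert bull_cow_equivalence(inp) == pytest.approx(0.178, abs=5e-4)


@settings(max_examples=200, derandomize=True)
@given(
    h2=st.floats(0.05, 0.9),
    p_bulls=st.floats(0.01, 1.0),
    p_cows=st.floats(0.01, 1.0),
    star=st.floats(0.01, 0.95),
)
def test_general_ratio_collapses_under_equal_adjusted_reliabilities(
    h2, p_bulls, p_cows, star
):
    inp = _equivalence_inputs(h2, p_bulls, p_cows)
    assert general_equivalence(inp, star, star) == pytest.approx(
        bull_cow_equivalence(inp), rel=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(
    h2=st.floats(0.05, 0.9),
    p_bulls=st.floats(0.01, 0.99),
    a=st.floats(0.05, 0.9),
    c=st.floats(0.05, 0.9),
)
def test_general_ratio_agrees_with_reference_size_oracle(h2, p_bulls, a, c):
    """The full ratio must equal the nP ratio built from the de-selected
    reliabilities through the reference-size inversion."""
    inp = _equivalence_inputs(h2, p_bulls, 0.7)
    u_m = deselect_reliability(a, inp.k_m, inp.r2_presel_m)
    u_f = deselect_reliability(c, inp.k_f, inp.r2_presel_f)
    n_m = required_reference_size(u_m, 6000.0, inp.r2_info_m)
    n_f = required_reference_size(u_f, 6000.0, inp.r2_info_f)
    assert general_equivalence(inp, a, c) == pytest.approx(n_m / n_f, rel=1e-10)


def test_combined_reliability_reference_cells():
    assert round(combined_reliability(0.496817, 0.142857).r2_combined, 3) == 0.536
    assert round(combined_reliability(0.534184, 0.625).r2_combined, 3) == 0.738


def test_combined_reliability_degenerate_and_weights():
    res = combined_reliability(0.4, 0.0)
    assert res.r2_combined == pytest.approx(0.4) and res.b2 == pytest.approx(0.6 / 1.0)
    # index weights solve P b = g
    a, c = 0.3, 0.2
    res = combined_reliability(a, c)
    assert a * res.b1 + a * c * res.b2 == pytest.approx(a)
    assert a * c * res.b1 + c * res.b2 == pytest.approx(c)
    with pytest.raises(ValueError):
        combined_reliability(1.0, 1.0)


@settings(max_examples=200, derandomize=True)
@given(a=st.floats(0.0, 0.99), c=st.floats(0.0, 0.99))
def test_combined_reliability_invariants(a, c):
    r1 = combined_reliability(a, c).r2_combined
    r2 = combined_reliability(c, a).r2_combined
    assert r1 == pytest.approx(r2, abs=1e-14)        # symmetric
    assert r1 >= max(a, c) - 1e-14                   # never worse than one group
    assert r1 <= min(a + c, 1.0) + 1e-14             # overlapping information
    if max(a, c) < 1.0:
        assert r1 < 1.0


def test_combined_reliability_saturates():
    assert combined_reliability(0.3, 0.999999).r2_combined == pytest.approx(
        1.0, abs=1e-5
    )


def _bull_side(h2, p_bulls, daughters=100, n_bulls=10000):
    r2_m = progeny_test_reliability(daughters, h2)
    return dict(
        n_bulls=n_bulls,
        r2_info_m=r2_m,
        r2_presel_m=parent_average_reliability(r2_m, h2),
        regime_m=variance_reduction(p_bulls),
    )


def test_cow_value_zero_when_cows_add_nothing():
    res = cow_value_mixed(GENOME, r2_f_star=0.0, n_cows=10000, **_bull_side(0.1, 0.05))
    assert res.delta_r2 == 0.0 and res.n_bull_equiv == 0.0


def test_cow_value_without_male_preselection_keeps_delta():
    side = _bull_side(0.1, 1.0)
    res = cow_value_mixed(GENOME, r2_f_star=0.142857, n_cows=10000, **side)
    assert res.delta_r2 == pytest.approx(res.r2_combined - res.r2_m_star)


def test_cow_value_regression_scenario():
    """h2=0.1, 10,000 bulls at 5% on 100-daughter PA + 10,000 unselected cows.

    Frozen output of the literal back-conversion pipeline; this value does
    NOT agree with the collapsed equal-reliability ratio (0.169), and no
    such agreement is asserted anywhere.
    """
    c = unselected_reliability(10000, 6000, 0.1)
    res = cow_value_mixed(GENOME, r2_f_star=c, n_cows=10000, **_bull_side(0.1, 0.05))
    assert res.r2_m_star == pytest.approx(0.496811, abs=5e-6)
    assert res.r2_combined == pytest.approx(0.535746, abs=5e-6)
    assert res.delta_r2 == pytest.approx(0.046892, abs=5e-6)
    assert res.n_bull_equiv == pytest.approx(0.041032, abs=5e-6)


def test_cow_value_requires_cows():
    with pytest.raises(ValueError):
        cow_value_mixed(GENOME, r2_f_star=0.1, n_cows=0, **_bull_side(0.1, 0.05))


def test_equivalence_input_validation():
    with pytest.raises(ValueError):
        EquivalenceInputs(r2_info_m=0.5, r2_info_f=0.1, k_m=2.0, r2_presel_m=0.9)
    with pytest.raises(ValueError):
        bull_cow_equivalence(EquivalenceInputs(r2_info_m=0.0, r2_info_f=0.1))
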