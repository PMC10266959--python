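"""DuPont statement, unit-rate calibration, and the ICUR helper."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionapath.finance import (
    CALIBRATION_LINE_KEYS,
    CalibrationError,
    FinanceError,
    UnitRates,
    calibrate_unit_rates,
    icur,
    per_case_amounts,
    statement,
)
from ionapath.pathway import CaseMix, ProcedureKind, ScenarioParams, expected_case_mix

K = ProcedureKind

RATES = UnitRates(
    billing_meniscectomy_da=1250.0,
    billing_repair=1260.0,
    cost_meniscectomy_da=1300.0,
    cost_repair=1600.0,
    cost_iona_disposable=770.0,
)


def test_zero_mix_gives_zero_statement_with_flagged_margin():
    st_ = statement(CaseMix({}), RATES)
    assert st_.revenue_total == 0.0
    assert st_.expenses_total == 0.0
    assert st_.profit == 0.0
    assert st_.profit_margin is None


def test_single_meniscectomy_profit_is_rate_difference():
    st_ = statement(CaseMix({K.OR_MENISCECTOMY: 1.0}), RATES)
    assert st_.profit == pytest.approx(1250.0 - 1300.0)


def test_revision_consumes_disposable_and_or_repair():
    st_ = statement(CaseMix({K.IONA_REVISION: 2.0}), RATES)
    assert st_.expenses["iona_revision"] == pytest.approx(2 * (770.0 + 1600.0))
    # billed once, at the meniscectomy bundled-payment rate
    assert st_.revenue["iona_revision"] == pytest.approx(2 * 1250.0)


mix_strategy = st.fixed_dictionaries(
    {kind: st.floats(min_value=0.0, max_value=300.0) for kind in K}
).map(CaseMix)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(mix_strategy, mix_strategy)
def test_statement_is_additive_line_by_line(mix_a, mix_b):
    combined = statement(mix_a + mix_b, RATES)
    a, b = statement(mix_a, RATES), statement(mix_b, RATES)
    for key in combined.revenue:
        assert combined.revenue[key] == pytest.approx(a.revenue[key] + b.revenue[key])
        assert combined.expenses[key] == pytest.approx(a.expenses[key] + b.expenses[key])
    assert combined.profit == pytest.approx(a.profit + b.profit)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.floats(min_value=1.0, max_value=500.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_revenue_invariant_under_equal_billing_rates(base_probs, N, s, r):
    """With one billing rate for every procedure, each patient is billed
    exactly once, so total revenue cannot depend on the pathway."""
    equal = UnitRates(1250.0, 1250.0, 1300.0, 1600.0, 770.0)
    current = statement(expected_case_mix(N, base_probs, ScenarioParams.current()), equal)
    proposed = statement(
        expected_case_mix(N, base_probs, ScenarioParams.proposed(s, r)), equal
    )
    assert proposed.revenue_total == pytest.approx(current.revenue_total, rel=1e-12)


def test_per_diverted_patient_saving_at_zero_revision(base_probs):
    """At r = 0 every diverted patient trades one OR meniscectomy/DA cost
    for one disposable set."""
    current = expected_case_mix(198.0, base_probs, ScenarioParams.current())
    proposed = expected_case_mix(198.0, base_probs, ScenarioParams.proposed(0.5, 0.0))
    diverted = 198.0 * 0.528 * 0.5
    cur_exp = statement(current, RATES).expenses_total
    prop_exp = statement(proposed, RATES).expenses_total
    # each diverted patient trades their would-be OR cost for a disposable
    # set: 79.7% would have been meniscectomy/DA cases, 20.3% repairs
    expected = diverted * 0.797 * (RATES.cost_meniscectomy_da - RATES.cost_iona_disposable)
    expected += diverted * 0.203 * (RATES.cost_repair - RATES.cost_iona_disposable)
    assert cur_exp - prop_exp == pytest.approx(expected, rel=1e-9)
    # with a single OR cost rate this collapses to the simple per-patient form
    flat = UnitRates(1250.0, 1260.0, 1300.0, 1300.0, 770.0)
    diff = statement(current, flat).expenses_total - statement(proposed, flat).expenses_total
    assert diff == pytest.approx(diverted * (1300.0 - 770.0), rel=1e-9)


def test_zero_noise_synthetic_lines_recover_rates_exactly(base_mixes):
    """Consistency of the linear map: lines generated from known rates are
    inverted with zero residual."""
    current, proposed = base_mixes
    cur_st = statement(current, RATES)
    prop_st = statement(proposed, RATES)
    lines = {
        "current_or_meniscectomy_da_billing": cur_st.revenue["or_meniscectomy_da"],
        "current_or_repair_billing": cur_st.revenue["or_repair"],
        "current_or_meniscectomy_da_cost": cur_st.expenses["or_meniscectomy_da"],
        "current_or_repair_cost": cur_st.expenses["or_repair"],
        "proposed_iona_meniscectomy_da_billing": prop_st.revenue["iona_meniscectomy_da"],
        "proposed_iona_revision_billing": prop_st.revenue["iona_revision"],
        "proposed_iona_meniscectomy_da_cost": prop_st.expenses["iona_meniscectomy_da"],
        "proposed_iona_revision_cost": prop_st.expenses["iona_revision"],
    }
    result = calibrate_unit_rates(lines, current, proposed)
    for field in RATES.__dataclass_fields__:
        assert getattr(result.rates, field) == pytest.approx(getattr(RATES, field), rel=1e-9)
    assert result.max_abs_residual < 1e-9


def test_calibration_against_published_lines(base_calibration):
    _, rates, calibration, _, _ = base_calibration
    # headline unit rates recovered from the published aggregate lines
    assert 1250 <= rates.billing_meniscectomy_da <= 1260
    assert rates.cost_repair == pytest.approx(1600, abs=10)
    assert rates.cost_meniscectomy_da == pytest.approx(1298.5, abs=5)
    assert 600 <= rates.cost_iona_disposable <= 800
    # published lines are internally inconsistent at the few-percent level
    assert calibration.max_abs_residual < 0.05


def test_calibration_requires_all_lines(base_mixes):
    current, proposed = base_mixes
    with pytest.raises(CalibrationError, match="missing"):
        calibrate_unit_rates({"current_or_repair_billing": 1.0}, current, proposed)


def test_calibration_detects_unidentified_rates(base_mixes):
    current, _ = base_mixes
    # a current-state "proposed" mix has no IONA counts: disposable rate unidentified
    lines = dict.fromkeys(CALIBRATION_LINE_KEYS, 1000.0)
    with pytest.raises(CalibrationError, match="singular"):
        calibrate_unit_rates(lines, current, current)


def test_per_case_amounts_align_with_statement():
    amounts = per_case_amounts(RATES)
    for kind in K:
        st_ = statement(CaseMix({kind: 1.0}), RATES)
        assert st_.revenue_total == pytest.approx(amounts[kind][0])
        assert st_.expenses_total == pytest.approx(amounts[kind][1])


def test_negative_rates_rejected():
    with pytest.raises(FinanceError):
        UnitRates(-1.0, 1.0, 1.0, 1.0, 1.0)


@pytest.mark.parametrize(
    "savings, qaly, expected",
    [
        (14502.55, 17.0, pytest.approx(853.09, abs=0.01)),
        (14502.55, 8.09, pytest.approx(1792.65, abs=0.01)),
        (0.0, 5.0, 0.0),
    ],
)
def test_icur(savings, qaly, expected):
    assert icur(savings, qaly) == expected


def test_icur_rejects_nonpositive_qaly():
    with pytest.raises(FinanceError):
        icur(1000.0, 0.0)
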