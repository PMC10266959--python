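"""Decision-tree case-mix allocation and its conservation properties."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionapath.pathway import (
    OR_BOUND,
    CaseMix,
    PathwayError,
    ProcedureKind,
    ScenarioParams,
    branch_distribution,
    expected_case_mix,
    or_bound_count,
)

K = ProcedureKind


def enumeration_oracle(N, probs, params):
    """Independent per-patient oracle: walk every tree path explicitly and
    accumulate each patient's exact probability mass per terminal branch.

    Arm splits are renormalised the same way the tree defines them, but the
    walk is written as an explicit path enumeration rather than a vector
    formula, so it exercises the same contract by a different route.
    """
    s = params.selection_fraction if params.state == "proposed" else 0.0
    r = params.revision_rate
    top = probs.p_repairable + probs.p_irreparable
    paths = []  # (branch, probability of one patient taking it)
    for arm_name, p_arm, split in (
        ("repairable", probs.p_repairable / top, probs.repairable),
        ("irreparable", probs.p_irreparable / top, probs.irreparable),
    ):
        z = split.p_repair + split.p_resect + split.p_diagnostic
        branches = {
            K.OR_REPAIR: split.p_repair / z,
            K.OR_MENISCECTOMY: split.p_resect / z,
            K.OR_DIAGNOSTIC: split.p_diagnostic / z,
        }
        if arm_name == "repairable":
            for kind, p in branches.items():
                paths.append((kind, p_arm * p))
        else:
            for kind, p in branches.items():  # declines IONA (or current state)
                paths.append((kind, p_arm * (1 - s) * p))
            paths.append((K.IONA_REVISION, p_arm * s * r))
            office = branches[K.OR_MENISCECTOMY] + branches[K.OR_DIAGNOSTIC]
            paths.append(
                (K.IONA_MENISCECTOMY, p_arm * s * (1 - r) * branches[K.OR_MENISCECTOMY] / office)
            )
            paths.append(
                (K.IONA_DIAGNOSTIC, p_arm * s * (1 - r) * branches[K.OR_DIAGNOSTIC] / office)
            )
    counts = {kind: 0.0 for kind in K}
    for _ in range(int(N)):  # one patient at a time, as a literal enumeration
        for kind, p in paths:
            counts[kind] += p
    return counts


def test_current_state_case_mix_matches_frozen_oracle(base_probs):
    mix = expected_case_mix(198.0, base_probs, ScenarioParams.current())
    # values frozen from the enumeration oracle at N = 198
    assert mix[K.OR_REPAIR] == pytest.approx(80.473536, abs=1e-6)
    assert mix[K.OR_MENISCECTOMY] == pytest.approx(93.766464, abs=1e-6)
    assert mix[K.OR_DIAGNOSTIC] == pytest.approx(23.76, abs=1e-6)
    for kind in (K.IONA_MENISCECTOMY, K.IONA_DIAGNOSTIC, K.IONA_REVISION):
        assert mix[kind] == 0.0


def test_proposed_state_case_mix_matches_frozen_oracle(base_probs):
    mix = expected_case_mix(198.0, base_probs, ScenarioParams.proposed())
    assert mix[K.IONA_REVISION] == pytest.approx(10.611216, abs=1e-6)
    office = mix[K.IONA_MENISCECTOMY] + mix[K.IONA_DIAGNOSTIC]
    assert office == pytest.approx(41.660784, abs=1e-6)
    # non-revision IONA mass splits 0.677 : 0.120
    assert mix[K.IONA_MENISCECTOMY] / office == pytest.approx(0.677 / 0.797, rel=1e-9)
    assert or_bound_count(mix) == pytest.approx(198.0 - 41.660784, abs=1e-6)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    st.integers(min_value=0, max_value=500),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_expected_mix_equals_per_patient_enumeration(base_probs, N, s, r):
    params = ScenarioParams.proposed(selection_fraction=s, revision_rate=r)
    mix = expected_case_mix(float(N), base_probs, params)
    oracle = enumeration_oracle(N, base_probs, params)
    for kind in K:
        assert mix[kind] == pytest.approx(oracle[kind], abs=1e-9 * max(1, N))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.floats(min_value=0.0, max_value=1e4),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_patient_conservation(base_probs, N, s, r):
    params = ScenarioParams.proposed(selection_fraction=s, revision_rate=r)
    mix = expected_case_mix(N, base_probs, params)
    assert mix.total == pytest.approx(N, rel=1e-12, abs=1e-9)


def test_zero_uptake_equals_current_state(base_probs):
    current = expected_case_mix(198.0, base_probs, ScenarioParams.current())
    zero_uptake = expected_case_mix(
        198.0, base_probs, ScenarioParams.proposed(selection_fraction=0.0)
    )
    assert current.counts == zero_uptake.counts


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_or_bound_monotone_in_selection_and_revision(base_probs, s1, s2, r1, r2):
    s_lo, s_hi = sorted((s1, s2))
    r_lo, r_hi = sorted((r1, r2))
    at = lambda s, r: or_bound_count(
        expected_case_mix(198.0, base_probs, ScenarioParams.proposed(s, r))
    )
    # non-increasing in selection, non-decreasing in revision
    assert at(s_hi, r_lo) <= at(s_lo, r_lo) + 1e-9
    assert at(s_lo, r_hi) >= at(s_lo, r_lo) - 1e-9


def test_or_bound_counts_revisions_as_or_cases(base_probs):
    mix = expected_case_mix(198.0, base_probs, ScenarioParams.proposed())
    assert K.IONA_REVISION in OR_BOUND
    manual = sum(mix[k] for k in (K.OR_MENISCECTOMY, K.OR_REPAIR, K.OR_DIAGNOSTIC, K.IONA_REVISION))
    assert or_bound_count(mix) == manual
    assert or_bound_count(CaseMix({})) == 0.0


def test_multinomial_mode_conserves_and_reproduces(base_probs):
    params = ScenarioParams.proposed()
    mix1 = expected_case_mix(
        198, base_probs, params, multinomial=True, rng=np.random.default_rng(3)
    )
    mix2 = expected_case_mix(
        198, base_probs, params, multinomial=True, rng=np.random.default_rng(3)
    )
    assert mix1.counts == mix2.counts
    assert mix1.total == 198
    assert all(float(v).is_integer() for v in mix1.counts.values())
    with pytest.raises(PathwayError, match="rng"):
        expected_case_mix(198, base_probs, params, multinomial=True)


def test_invalid_inputs_rejected(base_probs):
    with pytest.raises(PathwayError, match="non-negative"):
        expected_case_mix(-1.0, base_probs, ScenarioParams.current())
    with pytest.raises(PathwayError, match="current state"):
        ScenarioParams(state="current", selection_fraction=0.5)
    with pytest.raises(PathwayError):
        ScenarioParams(state="proposed", selection_fraction=1.2)


def test_branch_distribution_is_probability_mass(base_probs):
    for params in (ScenarioParams.current(), ScenarioParams.proposed(0.3, 0.4)):
        dist = branch_distribution(base_probs, params)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in dist.values())
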