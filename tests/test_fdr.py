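"""Step-up procedures, null-proportion estimators, grouped methods."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import fdrcorrection

from groupfdr import fdr
from groupfdr.fdr import (
    PValueSet,
    adaptive_unigroup,
    bh_stepup,
    gbh,
    lsl_pi0,
    sabha,
    storey_q,
    tst_pi0,
)


def brute_force_stepup(p: np.ndarray, level: float) -> int:
    """Independent oracle: maximise k over {0..n} of the step-up condition."""
    p_sorted = np.sort(p)
    n = p.size
    best = 0
    for k in range(n + 1):
        if k == 0 or p_sorted[k - 1] <= k * level / n:
            best = k
    return best


# ---------------------------------------------------------------------------
# BH step-up


@pytest.mark.parametrize(
    "p, alpha, expected_k",
    [
        ([0.001, 0.02, 0.03, 0.2], 0.05, 3),
        ([1.0, 1.0, 1.0], 0.05, 0),
        ([0.04, 0.04], 0.05, 2),  # boundary tie: both rejected
    ],
)
def test_bh_stepup_hand_examples(p, alpha, expected_k):
    res = bh_stepup(p, alpha)
    assert res.k_star == expected_k
    assert len(res.rejected) == expected_k


def test_bh_matches_statsmodels():
    """Cross-check against an independent BH implementation."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 40)) ** 2
        ours = bh_stepup(p, 0.05)
        theirs, _ = fdrcorrection(p, alpha=0.05, method="indep")
        assert ours.rejected == {f"h{i}" for i in np.nonzero(theirs)[0]}


def test_stepup_oracle_equivalence():
    """k* equals brute-force enumeration for small n on many random draws."""
    rng = np.random.default_rng(7)
    for trial in range(500):
        n = int(rng.integers(1, 13))
        p = np.round(rng.uniform(size=n) ** rng.choice([1, 2, 4]), 3)
        alpha = float(rng.choice([0.01, 0.05, 0.1, 0.3]))
        assert bh_stepup(p, alpha).k_star == brute_force_stepup(p, alpha)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_bh_level_monotonicity(p, alpha_idx):
    """Rejection sets grow (weakly) with the control level."""
    lo = 0.01 + 0.4 * alpha_idx / 10_000
    hi = lo + 0.2
    assert bh_stepup(p, lo).rejected <= bh_stepup(p, hi).rejected


def test_bh_empty_input_rejected():
    with pytest.raises(fdr.EmptyInputError):
        bh_stepup([], 0.05)


# ---------------------------------------------------------------------------
# null-proportion estimators


def test_tst_pi0_hand_examples():
    assert tst_pi0([0.001, 0.2, 0.7, 0.9], 0.05) == pytest.approx(0.75)
    assert tst_pi0([1.0, 1.0, 1.0], 0.05) == 1.0
    assert tst_pi0([1e-6, 1e-6], 0.05) == 0.0


def test_lsl_pi0_hand_examples():
    # slope sequence first increases at i=6: l5=2.0101, l6=2.5 -> n0=min(3,6)
    assert lsl_pi0([0.001, 0.002, 0.003, 0.004, 0.005, 0.6]) == pytest.approx(0.5)
    assert lsl_pi0([1.0, 1.0]) == 1.0
    # increase at i=4 (l4=10 > l3=2.857): n0 = min(11, 4) clipped to n_g
    assert lsl_pi0([0.1, 0.2, 0.3, 0.9]) == 1.0


def test_storey_q_hand_examples():
    assert storey_q([0.01, 0.02, 0.03, 0.04], tau=0.5, epsilon=0.1) == pytest.approx(0.1)
    assert storey_q([0.01, 0.2, 0.6, 0.8], tau=0.5, epsilon=0.1) == pytest.approx(1.0)
    assert storey_q([0.6, 0.7, 0.8, 0.9], tau=0.5, epsilon=0.1) == 1.0  # ceiling clip


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
@settings(max_examples=100, deadline=None)
def test_estimators_land_in_unit_interval(p):
    assert 0.0 <= tst_pi0(p, 0.05) <= 1.0
    assert 0.0 <= lsl_pi0(p) <= 1.0
    assert 0.1 <= storey_q(p) <= 1.0


def test_estimator_parameter_validation():
    with pytest.raises(ValueError):
        storey_q([0.5], tau=1.5)
    with pytest.raises(ValueError):
        storey_q([0.5], epsilon=0.0)
    with pytest.raises(fdr.EmptyInputError):
        lsl_pi0([])


# ---------------------------------------------------------------------------
# grouped procedures


def _pset(p, groups):
    return PValueSet.from_arrays(p, [f"h{i}" for i in range(len(p))], groups)


def test_gbh_two_group_hand_trace():
    """Signal-pure group A is rejected wholesale; all-null group B never is."""
    pset = _pset([0.001, 0.002, 0.003, 0.04, 0.2, 0.5, 0.8, 0.9], ["A"] * 4 + ["B"] * 4)
    res = gbh(pset, 0.05, estimator="tst")
    assert res.pi0_by_group == {"A": 0.0, "B": 1.0}
    assert res.pi0_overall == pytest.approx(0.5)
    assert res.rejected == {"h0", "h1", "h2", "h3"}
    w = res.weighted_p
    assert np.all(w[:4] == 0.0) and np.all(np.isinf(w[4:]))


def test_gbh_all_ones_rejects_nothing():
    pset = _pset([1.0] * 6, ["A"] * 3 + ["B"] * 3)
    for est in ("tst", "lsl"):
        res = gbh(pset, 0.05, estimator=est)
        assert res.pi0_overall == 1.0 and res.rejected == set()


def test_gbh_single_group_equals_two_stage_bh():
    pset = _pset([0.001, 0.02, 0.03, 0.2], ["A"] * 4)
    res = gbh(pset, 0.05, estimator="tst")
    assert res.pi0_overall == pytest.approx(0.25)
    assert res.rejected == {"h0", "h1", "h2"}


def test_sabha_two_group_hand_trace():
    pset = _pset([0.001, 0.01, 0.02, 0.6, 0.3, 0.55, 0.7, 0.9], ["A"] * 4 + ["B"] * 4)
    res = sabha(pset, 0.05, tau=0.5, epsilon=0.1)
    assert res.pi0_by_group == {"A": 0.5, "B": 1.0}
    assert res.k_star == 3
    assert res.rejected == {"h0", "h1", "h2"}


def test_sabha_unit_weights_reduce_to_bh():
    """If every group estimate clips to 1, SABHA is plain BH."""
    rng = np.random.default_rng(3)
    p = 0.55 + 0.45 * rng.uniform(size=12)  # all above tau: q-hat = 1 everywhere
    pset = _pset(p, ["A"] * 6 + ["B"] * 6)
    res = sabha(pset, 0.3, tau=0.5, epsilon=0.1)
    assert all(q == 1.0 for q in res.pi0_by_group.values())
    assert res.rejected == bh_stepup(p, 0.3).rejected


def test_sabha_all_ones_rejects_nothing():
    assert sabha(_pset([1.0] * 4, ["A"] * 4), 0.05).rejected == set()


# ---------------------------------------------------------------------------
# single-group reductions (independent oracles)


def _oracle_two_stage_bh(p, alpha):
    """BKY two-stage adaptive BH, coded directly from its definition."""
    alpha_prime = alpha / (1 + alpha)
    r1 = brute_force_stepup(p, alpha_prime)
    if r1 == 0:
        return set()
    n = p.size
    pi0 = (n - r1) / n
    if pi0 == 0:
        return {f"h{i}" for i in range(n)}
    k = brute_force_stepup(p, alpha_prime / pi0)
    thr = np.sort(p)[k - 1] if k else -1.0
    return {f"h{i}" for i, pv in enumerate(p) if pv <= thr}


def _oracle_adaptive_bh(p, alpha, pi0, empty_if_pure_null=False):
    """Plain adaptive BH at level alpha/pi0 for a given null-proportion estimate.

    With ``empty_if_pure_null`` a unit estimate rejects nothing, matching the
    infinite-weight convention of the grouped weighting formulation.
    """
    if pi0 >= 1 and empty_if_pure_null:
        return set()
    if pi0 == 0:
        return {f"h{i}" for i in range(p.size)}
    k = brute_force_stepup(p, alpha / pi0)
    thr = np.sort(p)[k - 1] if k else -1.0
    return {f"h{i}" for i, pv in enumerate(p) if pv <= thr}


def test_single_group_reductions_match_oracles():
    """gbh/sabha with one group equal TST-BH / LSL-BH / Storey-BH exactly."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(2, 40))
        p = rng.uniform(size=n) ** rng.choice([1, 3])
        alpha = float(rng.choice([0.05, 0.1, 0.2]))
        assert adaptive_unigroup(p, alpha, "tst").rejected == _oracle_two_stage_bh(p, alpha)
        assert adaptive_unigroup(p, alpha, "lsl").rejected == _oracle_adaptive_bh(
            p, alpha, lsl_pi0(p), empty_if_pure_null=True
        )
        assert adaptive_unigroup(p, alpha, "storey").rejected == _oracle_adaptive_bh(
            p, alpha, storey_q(p, 0.5, 0.1)
        )


def test_unigroup_equals_grouped_with_one_group():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(2, 30))
        p = rng.uniform(size=n) ** 2
        pset = _pset(p, ["all"] * n)
        assert gbh(pset, 0.05, "tst").rejected == adaptive_unigroup(p, 0.05, "tst").rejected
        assert gbh(pset, 0.05, "lsl").rejected == adaptive_unigroup(p, 0.05, "lsl").rejected
        assert sabha(pset, 0.05).rejected == adaptive_unigroup(p, 0.05, "storey").rejected


# ---------------------------------------------------------------------------
# invariants


def test_within_group_monotonicity():
    """In any group, rejecting a hypothesis implies rejecting smaller p-values."""
    rng = np.random.default_rng(19)
    for _ in range(100):
        n = 24
        p = rng.uniform(size=n) ** rng.choice([1, 4])
        groups = [f"g{i % 4}" for i in range(n)]
        pset = _pset(p, groups)
        for res in (gbh(pset, 0.1, "tst"), gbh(pset, 0.1, "lsl"), sabha(pset, 0.1)):
            for g in set(groups):
                idx = [i for i in range(n) if groups[i] == g]
                rejected_p = [p[i] for i in idx if f"h{i}" in res.rejected]
                kept_p = [p[i] for i in idx if f"h{i}" not in res.rejected]
                if rejected_p and kept_p:
                    assert max(rejected_p) <= min(kept_p)


def test_grouped_rejections_need_not_contain_bh_set():
    """Grouped methods can *lose* a BH detection (frozen seeded instance)."""
    p = [0.4057, 0.0728, 0.0017, 0.0003, 0.6614, 0.8331, 0.368, 0.5322,
         0.2955, 0.8744, 0.6656, 0.0]
    groups = ["g0"] * 4 + ["g1"] * 4 + ["g2"] * 4
    pset = _pset(p, groups)
    bh_set = bh_stepup(np.array(p), 0.05).rejected
    lsl_set = gbh(pset, 0.05, estimator="lsl").rejected
    assert bh_set - lsl_set  # containment fails


def test_missing_group_labels_raise():
    with pytest.raises(ValueError):
        gbh(PValueSet.from_arrays([0.1, 0.2]), 0.05)
    with pytest.raises(ValueError):
        PValueSet(p=np.array([0.1]), hypothesis_ids=["a"], group_of={"b": "g"})
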