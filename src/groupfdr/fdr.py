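"""Step-up FDR procedures: BH, adaptive BH variants, grouped BH, group SABHA.

All procedures reject individual hypotheses via a step-up rule on (possibly
weighted) p-values.  The grouped procedures estimate the proportion of true
nulls pi0_g within each group and recalibrate p-values so that hypotheses in
groups rich in signal are prioritised:

* **TST-GBH** estimates pi0_g by the two-stage step-up rule (a first-pass BH
  run within the group at level alpha' = alpha/(1+alpha)); the final pooled
  step-up also runs at alpha'.
* **LSL-GBH** estimates pi0_g by the least-slope rule and runs the pooled
  step-up at alpha.
* **group SABHA** uses a tau-censored (Storey-type) estimate per group,
  clipped below at epsilon, and rejects via a step-up on q_g(i) * p_i.

With both GBH variants the p-value of hypothesis i is reweighted as
``p_i * pi0_g / (1 - pi0_g)`` (infinite when pi0_g = 1, zero when pi0_g = 0)
and the pooled BH level is inflated by 1/(1 - pi0_bar), where pi0_bar is the
size-weighted average of the group estimates; pi0_bar = 1 rejects nothing.
With a single group the three methods reduce exactly to TST-BH, LSL-BH and
Storey's adaptive BH.

p-values of exactly 0 or 1 are legal everywhere; the least-slope rule treats
1 - p = 0 via an infinite slope, and a zero group estimate gives weighted
p-values of zero, which are rejected whenever anything is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

Method = Literal["bh", "storey_bh", "tst_bh", "lsl_bh", "tst_gbh", "lsl_gbh", "sabha"]
Estimator = Literal["tst", "lsl"]


class EmptyInputError(ValueError):
    """No p-values supplied."""


@dataclass
class PValueSet:
    """Raw p-values with optional group labels.

    ``group_of`` must cover every hypothesis when present.
    """

    p: np.ndarray
    hypothesis_ids: list[str]
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size == 0:
            raise EmptyInputError("empty p-value set")
        if self.p.size != len(self.hypothesis_ids):
            raise ValueError("p and hypothesis_ids length mismatch")
        if len(set(self.hypothesis_ids)) != len(self.hypothesis_ids):
            raise ValueError("duplicate hypothesis ids")
        if not np.all(np.isfinite(self.p)) or self.p.min() < 0 or self.p.max() > 1:
            raise ValueError("p-values must be finite and lie in [0, 1]")
        if self.group_of is not None:
            missing = [h for h in self.hypothesis_ids if h not in self.group_of]
            if missing:
                raise ValueError(f"hypotheses without group labels: {missing}")

    @classmethod
    def from_arrays(
        cls,
        p: Sequence[float],
        ids: Sequence[str] | None = None,
        groups: Sequence[str] | None = None,
    ) -> "PValueSet":
        p = np.asarray(p, dtype=float)
        if ids is None:
            ids = [f"h{i}" for i in range(p.size)]
        group_of = dict(zip(ids, groups)) if groups is not None else None
        return cls(p=p, hypothesis_ids=list(ids), group_of=group_of)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Map group id -> integer indices of its hypotheses (input order)."""
        if self.group_of is None:
            raise ValueError("p-value set has no group labels")
        out: dict[str, list[int]] = {}
        for i, h in enumerate(self.hypothesis_ids):
            out.setdefault(self.group_of[h], []).append(i)
        return {g: np.asarray(idx, dtype=int) for g, idx in out.items()}


@dataclass
class FDRResult:
    method: Method
    alpha: float
    rejected: set[str]
    pi0_by_group: dict[str, float] = field(default_factory=dict)
    pi0_overall: float = float("nan")
    weighted_p: np.ndarray | None = None
    k_star: int = 0
    threshold: float = 0.0


def _stepup_k(p: np.ndarray, level: float) -> int:
    """k* = max{k : p_(k) <= k * level / n}, 0 if no k qualifies."""
    n = p.size
    p_sorted = np.sort(p)
    ok = p_sorted <= level * np.arange(1, n + 1) / n
    return int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0


def bh_stepup(
    p: Sequence[float] | np.ndarray,
    alpha: float,
    ids: Sequence[str] | None = None,
) -> FDRResult:
    """Benjamini-Hochberg step-up at level alpha.

    Rejects the k* smallest p-values where k* = max{k : p_(k) <= k alpha/n};
    ties at the realized threshold are all rejected.
    """
    pset = p if isinstance(p, PValueSet) else PValueSet.from_arrays(p, ids)
    arr = pset.p
    k_star = _stepup_k(arr, alpha)
    n = arr.size
    if k_star == 0:
        rejected: set[str] = set()
        threshold = 0.0
    else:
        threshold = float(np.sort(arr)[k_star - 1])
        rejected = {h for h, pv in zip(pset.hypothesis_ids, arr) if pv <= threshold}
        k_star = len(rejected)  # boundary ties all rejected
    return FDRResult(
        method="bh",
        alpha=alpha,
        rejected=rejected,
        weighted_p=arr.copy(),
        k_star=k_star,
        threshold=threshold if k_star else 0.0,
    )


# ---------------------------------------------------------------------------
# null-proportion estimators


def tst_pi0(p_group: Sequence[float] | np.ndarray, alpha: float) -> float:
    """Two-stage step-up estimate of the null proportion within one group.

    Runs BH at the reduced level alpha' = alpha / (1 + alpha); with r
    rejections out of n_g hypotheses the estimate is (n_g - r) / n_g.
    """
    arr = np.asarray(p_group, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("empty group")
    alpha_prime = alpha / (1.0 + alpha)
    r = _stepup_k(arr, alpha_prime)
    if r:  # count boundary ties like the rejection rule does
        thr = float(np.sort(arr)[r - 1])
        r = int(np.sum(arr <= thr))
    return (arr.size - r) / arr.size


def lsl_pi0(p_group: Sequence[float] | np.ndarray) -> float:
    """Least-slope estimate of the null proportion within one group.

    With sorted p-values the slope sequence is l_i = (n_g + 1 - i)/(1 - p_(i))
    (infinite where p_(i) = 1).  At the first index i >= 2 where the slope
    increases (comparisons between two infinities count as no increase) the
    null count is floor(l_i) + 1, capped at n_g; if the slope never
    increases the estimate is 1.
    """
    arr = np.sort(np.asarray(p_group, dtype=float))
    n = arr.size
    if n == 0:
        raise EmptyInputError("empty group")
    with np.errstate(divide="ignore"):
        slopes = np.where(arr < 1.0, (n + 1.0 - np.arange(1, n + 1)) / (1.0 - arr), np.inf)
    n0 = n
    for i in range(1, n):
        a, b = slopes[i - 1], slopes[i]
        if b > a and not (math.isinf(a) and math.isinf(b)):
            n0 = n if math.isinf(b) else min(int(math.floor(b)) + 1, n)
            break
    return n0 / n


def storey_q(
    p_group: Sequence[float] | np.ndarray,
    tau: float = 0.5,
    epsilon: float = 0.1,
) -> float:
    """Tau-censored null-proportion estimate, clipped to [epsilon, 1].

    q = #{p > tau} / (n_g (1 - tau)), then clipped; epsilon keeps the SABHA
    weights away from zero so a lucky group cannot claim unlimited priority.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must be in (0, 1]")
    arr = np.asarray(p_group, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("empty group")
    raw = np.sum(arr > tau) / (arr.size * (1.0 - tau))
    return float(min(1.0, max(epsilon, raw)))


# ---------------------------------------------------------------------------
# grouped procedures


def gbh(
    pset: PValueSet,
    alpha: float,
    estimator: Estimator = "tst",
) -> FDRResult:
    """Group-adaptive BH with TST or LSL group null-proportion estimates.

    Weighted p-values p_i * pi0_g/(1 - pi0_g) are pooled into one BH step-up
    at level alpha_base / (1 - pi0_bar), where alpha_base is alpha/(1+alpha)
    for TST and alpha for LSL.  pi0_bar = 1 means no evidence of signal in
    any group: nothing is rejected.
    """
    if pset.group_of is None:
        raise ValueError("gbh requires group labels")
    if estimator not in ("tst", "lsl"):
        raise ValueError(f"unknown estimator {estimator!r}")
    idx_by_group = pset.group_indices()
    n = pset.p.size
    pi0: dict[str, float] = {}
    for g, idx in idx_by_group.items():
        pi0[g] = tst_pi0(pset.p[idx], alpha) if estimator == "tst" else lsl_pi0(pset.p[idx])

    weighted = np.empty(n)
    for g, idx in idx_by_group.items():
        pg = pi0[g]
        if pg >= 1.0:
            weighted[idx] = np.inf
        elif pg <= 0.0:
            weighted[idx] = 0.0
        else:
            weighted[idx] = pset.p[idx] * pg / (1.0 - pg)

    pi0_overall = sum(len(idx) * pi0[g] for g, idx in idx_by_group.items()) / n
    method: Method = "tst_gbh" if estimator == "tst" else "lsl_gbh"
    if pi0_overall >= 1.0:
        return FDRResult(method, alpha, set(), pi0, pi0_overall, weighted, 0, 0.0)

    alpha_base = alpha / (1.0 + alpha) if estimator == "tst" else alpha
    level = alpha_base / (1.0 - pi0_overall)
    # any step-up threshold is <= level, so level + 1 stands in for +inf
    finite = np.where(np.isinf(weighted), level + 1.0, weighted)
    k_star = _stepup_k(finite, level)
    if k_star == 0:
        return FDRResult(method, alpha, set(), pi0, pi0_overall, weighted, 0, 0.0)
    threshold = float(np.sort(finite)[k_star - 1])
    rejected = {
        h for h, wp in zip(pset.hypothesis_ids, weighted) if wp <= threshold
    }
    return FDRResult(method, alpha, rejected, pi0, pi0_overall, weighted, len(rejected), threshold)


def sabha(
    pset: PValueSet,
    alpha: float,
    tau: float = 0.5,
    epsilon: float = 0.1,
    tau_cap: bool = False,
) -> FDRResult:
    """Group-aware SABHA: step-up on q_g(i) * p_i with censored estimates.

    q_g is the tau-censored null-proportion estimate clipped to [epsilon, 1].
    k_hat = max{k : #{i : q_g(i) p_i <= k alpha / n} >= k}; rejects every
    hypothesis with q_g(i) p_i <= k_hat alpha / n.  ``tau_cap`` additionally
    requires p_i <= tau for rejection (off by default: with alpha = 0.05 and
    tau = 0.5 the cap is never binding in practice).
    """
    if pset.group_of is None:
        raise ValueError("sabha requires group labels")
    idx_by_group = pset.group_indices()
    n = pset.p.size
    qhat: dict[str, float] = {}
    weighted = np.empty(n)
    for g, idx in idx_by_group.items():
        qhat[g] = storey_q(pset.p[idx], tau=tau, epsilon=epsilon)
        weighted[idx] = qhat[g] * pset.p[idx]

    eligible = np.ones(n, dtype=bool) if not tau_cap else (pset.p <= tau)
    k_hat = 0
    for k in range(n, 0, -1):
        if np.sum((weighted <= k * alpha / n) & eligible) >= k:
            k_hat = k
            break
    if k_hat == 0:
        return FDRResult("sabha", alpha, set(), qhat, float("nan"), weighted, 0, 0.0)
    threshold = k_hat * alpha / n
    rejected = {
        h
        for h, wp, ok in zip(pset.hypothesis_ids, weighted, eligible)
        if ok and wp <= threshold
    }
    return FDRResult("sabha", alpha, rejected, qhat, float("nan"), weighted, len(rejected), threshold)


def adaptive_unigroup(
    p: Sequence[float] | np.ndarray,
    alpha: float,
    variant: Literal["storey", "tst", "lsl"] = "tst",
    tau: float = 0.5,
    epsilon: float = 0.1,
    ids: Sequence[str] | None = None,
) -> FDRResult:
    """Single-group degenerate forms: Storey-BH, TST-BH, LSL-BH.

    Implemented literally as the corresponding grouped procedure with one
    group holding every hypothesis.
    """
    arr = np.asarray(p, dtype=float)
    if ids is None:
        ids = [f"h{i}" for i in range(arr.size)]
    pset = PValueSet.from_arrays(arr, ids, groups=["all"] * arr.size)
    if variant == "storey":
        res = sabha(pset, alpha, tau=tau, epsilon=epsilon)
        res.method = "storey_bh"
    elif variant == "tst":
        res = gbh(pset, alpha, estimator="tst")
        res.method = "tst_bh"
    elif variant == "lsl":
        res = gbh(pset, alpha, estimator="lsl")
        res.method = "lsl_bh"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return res


def run_method(
    pset: PValueSet,
    method: Method,
    alpha: float,
    tau: float = 0.5,
    epsilon: float = 0.1,
) -> FDRResult:
    """Dispatch a named procedure on a (possibly grouped) p-value set."""
    if method == "bh":
        return bh_stepup(pset.p, alpha, ids=pset.hypothesis_ids)
    if method == "tst_gbh":
        return gbh(pset, alpha, estimator="tst")
    if method == "lsl_gbh":
        return gbh(pset, alpha, estimator="lsl")
    if method == "sabha":
        return sabha(pset, alpha, tau=tau, epsilon=epsilon)
    if method in ("storey_bh", "tst_bh", "lsl_bh"):
        variant = {"storey_bh": "storey", "tst_bh": "tst", "lsl_bh": "lsl"}[method]
        return adaptive_unigroup(pset.p, alpha, variant=variant, tau=tau, epsilon=epsilon,
                                 ids=pset.hypothesis_ids)
    raise ValueError(f"unknown method {method!r}")
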