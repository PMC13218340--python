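"""Random-group-assignment control study.

The grouped procedures should owe their extra detections to biologically
informative groups.  To check that, hypotheses are repeatedly reassigned to
groups *uniformly at random while preserving the multiset of group sizes*,
each grouped method is rerun on the unchanged p-values (the tumor/normal
pairing is never touched — p-values are computed once, only labels move),
and per-hypothesis detection frequencies plus per-replicate detection-count
summaries are collected.  Standard BH is excluded: it ignores groups.

Each replicate draws from an independent RNG substream keyed by
(seed, replicate index), so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from groupfdr.fdr import FDRResult, PValueSet, run_method
from groupfdr.grouping import GroupingScheme

CONTROL_METHODS = ("tst_gbh", "lsl_gbh", "sabha")


@dataclass
class ControlStudyResult:
    method: str
    n_reps: int
    freq: dict[str, float]  # per-hypothesis detection fraction
    count_summary: tuple[float, float, tuple[float, float]]  # mean, median, (q25, q75)
    bh_overlap_summary: tuple[float, float, tuple[float, float]]
    nonbh_overlap_summary: tuple[float, float, tuple[float, float]]
    seed: int


def random_reassign(scheme: GroupingScheme, rng: np.random.Generator) -> GroupingScheme:
    """Uniformly permute the hypothesis -> group assignment, sizes fixed."""
    members = [m for mem in scheme.groups.values() for m in mem]
    perm = list(np.asarray(members, dtype=object)[rng.permutation(len(members))])
    groups: dict[str, list[str]] = {}
    pos = 0
    for gid, mem in scheme.groups.items():
        groups[gid] = perm[pos : pos + len(mem)]
        pos += len(mem)
    assignment = {m: gid for gid, mem in groups.items() for m in mem}
    return GroupingScheme(assignment=assignment, groups=groups, level=scheme.level, k=scheme.k)


def _summary(counts: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    q25, q75 = np.percentile(counts, [25, 75])  # inclusive midpoint convention
    return float(np.mean(counts)), float(np.median(counts)), (float(q25), float(q75))


def control_study(
    pset: PValueSet,
    scheme: GroupingScheme,
    methods: Sequence[str] = CONTROL_METHODS,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    bh_set: set[str] | None = None,
    comparison_set: set[str] | None = None,
    tau: float = 0.5,
    epsilon: float = 0.1,
) -> list[ControlStudyResult]:
    """Rerun grouped methods under ``n_reps`` random group reassignments."""
    bad = set(methods) - set(CONTROL_METHODS)
    if bad:
        raise ValueError(f"control study only covers grouped methods, not {sorted(bad)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    bh_set = bh_set or set()
    comparison_set = comparison_set or set()
    ids = pset.hypothesis_ids
    counts = {m: np.zeros(n_reps) for m in methods}
    bh_overlap = {m: np.zeros(n_reps) for m in methods}
    nonbh_overlap = {m: np.zeros(n_reps) for m in methods}
    hits = {m: {h: 0 for h in ids} for m in methods}

    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        shuffled = random_reassign(scheme, rng)
        rep_pset = replace(pset, group_of=dict(shuffled.assignment))
        for method in methods:
            res: FDRResult = run_method(rep_pset, method, alpha, tau=tau, epsilon=epsilon)
            counts[method][r] = len(res.rejected)
            bh_overlap[method][r] = len(res.rejected & bh_set)
            nonbh_overlap[method][r] = len(res.rejected & comparison_set)
            for h in res.rejected:
                hits[method][h] += 1

    return [
        ControlStudyResult(
            method=m,
            n_reps=n_reps,
            freq={h: hits[m][h] / n_reps for h in ids},
            count_summary=_summary(counts[m]),
            bh_overlap_summary=_summary(bh_overlap[m]),
            nonbh_overlap_summary=_summary(nonbh_overlap[m]),
            seed=seed,
        )
        for m in methods
    ]


def summarize_control(results: Sequence[ControlStudyResult]) -> pd.DataFrame:
    """Tidy method x (mean, median, IQR) summary of the control study."""
    if not results:
        raise ValueError("no control-study results to summarize")
    rows = []
    for res in results:
        for kind, (mean, median, (q25, q75)) in (
            ("detections", res.count_summary),
            ("bh_overlap", res.bh_overlap_summary),
            ("nonbh_overlap", res.nonbh_overlap_summary),
        ):
            rows.append(
                {
                    "method": res.method,
                    "quantity": kind,
                    "mean": mean,
                    "median": median,
                    "iqr_low": q25,
                    "iqr_high": q75,
                }
            )
    return pd.DataFrame(rows)
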