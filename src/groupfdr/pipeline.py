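"""End-to-end orchestration: tests -> scheme family -> all FDR methods.

``run_pipeline`` composes the individual modules exactly as they would be
called by hand — complete-case ddCt, directional paired t-tests, the full
hierarchy of grouping schemes, and BH / TST-GBH / LSL-GBH / SABHA per scheme
— and assembles a per-miRNA result table with one detection flag per
(method, scheme) plus a sweep summary of how detection sets change from one
scheme to the next.  Scheme choice (e.g. by the elbow of the detections-vs-
scheme curve) is left to the user: the sweep reports counts and first
differences but never picks a scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from groupfdr.detest import compute_ddct, median_impute, test_all
from groupfdr.fdr import FDRResult, PValueSet, run_method
from groupfdr.grouping import GroupingScheme, scheme_family, scheme_label
from groupfdr.io_model import (
    AnnotationRecord,
    ExpressionTable,
    ResultRow,
    RunConfig,
)

logger = logging.getLogger(__name__)

PIPELINE_METHODS = ("bh", "tst_gbh", "lsl_gbh", "sabha")


@dataclass
class SweepResult:
    """Detection counts/sets per (method, scheme) and scheme-to-scheme diffs."""

    scheme_labels: list[str]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    detections: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    entered: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    exited: dict[tuple[str, str], set[str]] = field(default_factory=dict)


def scheme_sweep(
    detections: dict[str, dict[str, set[str]]],
    scheme_order: Sequence[str],
) -> SweepResult:
    """Counts plus enter/exit diffs between consecutive schemes per method.

    ``detections[method][scheme_label]`` is that run's rejection set.
    """
    if len(scheme_order) < 2:
        raise ValueError("need at least two schemes to sweep")
    sweep = SweepResult(scheme_labels=list(scheme_order))
    for method, per_scheme in detections.items():
        prev: set[str] | None = None
        for label in scheme_order:
            dets = per_scheme[label]
            sweep.detections[(method, label)] = set(dets)
            sweep.counts[(method, label)] = len(dets)
            if prev is not None:
                sweep.entered[(method, label)] = dets - prev
                sweep.exited[(method, label)] = prev - dets
            prev = dets
    return sweep


def run_pipeline(
    config: RunConfig,
    expression: ExpressionTable,
    annotation: Sequence[AnnotationRecord],
    impute: bool = False,
) -> tuple[list[ResultRow], SweepResult, dict[str, dict[str, FDRResult]]]:
    """The full analysis; returns result rows, sweep summary, raw FDR results.

    ``impute=True`` switches to the median-imputation sensitivity variant;
    the default is the complete-case path.
    """
    ddct = compute_ddct(expression)
    if impute:
        ddct = median_impute(ddct)
    tests = test_all(ddct, delta=config.delta)
    logger.info("tested %d miRNAs (%d flagged untestable)",
                len(tests), sum(t.flag is not None for t in tests))

    ann_by_id = {rec.mirna_id: rec for rec in annotation}
    mirna_ids = [t.mirna_id for t in tests]
    p = np.asarray([t.p_raw for t in tests])

    schemes = scheme_family(annotation, config.k_values, mirna_ids=mirna_ids)
    labels = [scheme_label(s) for s in schemes]

    fdr_results: dict[str, dict[str, FDRResult]] = {m: {} for m in PIPELINE_METHODS}
    for scheme, label in zip(schemes, labels):
        pset = PValueSet.from_arrays(
            p, mirna_ids, groups=[scheme.assignment[m] for m in mirna_ids]
        )
        for method in PIPELINE_METHODS:
            res = run_method(pset, method, config.alpha,
                             tau=config.tau, epsilon=config.epsilon)
            fdr_results[method][label] = res
            logger.info("scheme=%s method=%s groups=%d rejected=%d",
                        label, method, scheme.n_groups, len(res.rejected))

    rows = []
    for t in tests:
        rec = ann_by_id[t.mirna_id]
        flags = {
            f"{method}:{label}": t.mirna_id in fdr_results[method][label].rejected
            for method in PIPELINE_METHODS
            for label in labels
        }
        rows.append(
            ResultRow(
                mirna_id=t.mirna_id,
                chrom=rec.chrom,
                strand=rec.strand,
                arm=rec.arm,
                mean_ddct=t.mean_ddct,
                p_raw=t.p_raw,
                n_missing_pairs=t.n_missing_pairs,
                detected_by=flags,
            )
        )

    detections = {
        method: {label: set(fdr_results[method][label].rejected) for label in labels}
        for method in PIPELINE_METHODS
    }
    sweep = scheme_sweep(detections, labels)
    return rows, sweep, fdr_results
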