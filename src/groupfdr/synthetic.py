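"""Seeded synthetic miRNAome generator.

Emulates the statistical structure of a paired-tissue qPCR miRNA screen:
18 patients x ~522 miRNAs scattered over 22 chromosomes with uneven density
(so position-based grouping yields a mixture of small and large groups),
sparse grouped differential-expression signals, an exchangeable
patient/group/residual correlation structure, and missing-not-at-random
dropout driven by the qPCR detection limit (any raw Ct above the cutoff
invalidates the whole tumor/normal pair; miRNAs missing in more than half
the patients are removed, mirroring common pre-processing).

The variance components ``sigma_a2 / sigma_b2 / sigma_e2`` act on the
*tumor-vs-normal* (ddCt) scale and default to the proportions
0.04 : 0.11 : 0.85 of a total ddCt variance of 4 (sd 2 Ct), giving
intra-group correlation 0.15 and inter-group correlation 0.04.  The
per-tissue expression layer uses the same proportions scaled by
``dct_var_ratio`` so that dCt values vary across patients with sd ~5 Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from groupfdr.io_model import (
    AnnotationRecord,
    ExpressionTable,
    write_annotation,
    write_expression,
)
from groupfdr.grouping import build_scheme

REFERENCE_CT = 20.0  # geometric-mean Ct of the endogenous controls


@dataclass
class SimulationParams:
    """Knobs of the synthetic miRNAome; defaults emulate the study design."""

    n_patients: int = 18
    n_mirnas: int = 522
    n_chromosomes: int = 22
    frac_signal_groups: float = 0.1
    frac_alt_within_signal_group: float = 0.5
    effect_range: tuple[float, float] = (1.5, 7.0)
    # ddCt-scale exchangeable variance components (patient, patient-by-group, residual)
    sigma_a2: float = 0.16
    sigma_b2: float = 0.44
    sigma_e2: float = 3.40
    # per-tissue dCt layer = ddCt components scaled by this ratio (sd ~5 Ct)
    dct_var_ratio: float = 6.25
    # raw-Ct baseline per miRNA and the qPCR detection limit
    ct_baseline_mean: float = 31.5
    ct_baseline_sd: float = 3.5
    ct_cutoff: float = 40.0
    missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_b2, self.sigma_e2) < 0:
            raise ValueError("variance components must be >= 0")
        for frac in (self.frac_signal_groups, self.frac_alt_within_signal_group):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.effect_range
        if not (0.0 < lo <= hi):
            raise ValueError("effect_range must be within (0, inf) with lo <= hi")
        if self.n_mirnas < 2:
            raise ValueError("need at least two miRNAs")


@dataclass
class SyntheticTruth:
    """Ground truth: which miRNAs carry signal and how strong it is."""

    is_null: dict[str, bool]
    true_effect: dict[str, float]  # ddCt shift in Ct units, 0 for nulls
    group_of_truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, null in self.is_null.items():
            if null != (self.true_effect[m] == 0.0):
                raise ValueError(f"{m}: is_null inconsistent with true_effect")


def generate_annotation(
    params: SimulationParams, rng: np.random.Generator
) -> list[AnnotationRecord]:
    """Scatter miRNAs over chromosomes with harmonically decaying density.

    The uneven density plus mildly skewed strand/arm frequencies makes the
    chromosome/strand/arm partition produce both small groups and groups
    large enough (>25 members) to exercise every max-size split.
    """
    if params.n_mirnas < 2:
        raise ValueError("need at least two miRNAs")
    n_chrom = params.n_chromosomes
    weights = 1.0 / np.arange(1, n_chrom + 1)
    weights /= weights.sum()
    chroms = rng.choice(np.arange(1, n_chrom + 1), size=params.n_mirnas, p=weights)
    strands = rng.choice(np.array(["+", "-"]), size=params.n_mirnas, p=[0.55, 0.45])
    arms = rng.choice(np.array(["p", "q"]), size=params.n_mirnas, p=[0.4, 0.6])
    chrom_lengths = {c: int(2.4e8 / math.sqrt(c)) for c in range(1, n_chrom + 1)}
    records = []
    used: dict[int, set[int]] = {c: set() for c in range(1, n_chrom + 1)}
    for i in range(params.n_mirnas):
        c = int(chroms[i])
        while True:
            start = int(rng.integers(1, chrom_lengths[c] + 1))
            if start not in used[c]:
                used[c].add(start)
                break
        records.append(
            AnnotationRecord(
                mirna_id=f"mir-{i + 1:04d}",
                chrom=str(c),
                strand=str(strands[i]),
                arm=str(arms[i]),
                start=start,
            )
        )
    return records


def _exchangeable_noise(
    rng: np.random.Generator,
    n_patients: int,
    group_idx: np.ndarray,
    sigma_a2: float,
    sigma_b2: float,
    sigma_e2: float,
) -> np.ndarray:
    """Draw a (patients x miRNAs) matrix a_j + b_{j,g(i)} + e_{j,i}."""
    n_mirnas = group_idx.size
    n_groups = int(group_idx.max()) + 1
    a = rng.normal(0.0, math.sqrt(sigma_a2), size=(n_patients, 1))
    b = rng.normal(0.0, math.sqrt(sigma_b2), size=(n_patients, n_groups))
    e = rng.normal(0.0, math.sqrt(sigma_e2), size=(n_patients, n_mirnas))
    return a + b[:, group_idx] + e


def generate_expression(
    annotation: Sequence[AnnotationRecord],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[ExpressionTable, SyntheticTruth]:
    """Draw paired dCt values with grouped signals and detection-limit dropout.

    Normal-tissue raw Ct is ``baseline_i`` plus exchangeable noise keyed to
    the chromosome/strand/arm group of the miRNA; tumor raw Ct adds the true
    ddCt effect mu_i plus an independent exchangeable layer.  Any raw Ct
    above ``ct_cutoff`` knocks out the whole pair; miRNAs with more than 50%
    missing pairs are dropped.
    """
    mirnas = [rec.mirna_id for rec in annotation]
    scheme = build_scheme(annotation, "chrom_strand_arm")
    group_ids = sorted(scheme.groups)
    group_pos = {g: i for i, g in enumerate(group_ids)}
    group_idx = np.asarray([group_pos[scheme.assignment[m]] for m in mirnas])

    # sparse grouped signals
    n_signal_groups = int(round(params.frac_signal_groups * len(group_ids)))
    signal_groups = set(
        rng.choice(np.asarray(group_ids, dtype=object), size=n_signal_groups, replace=False)
    ) if n_signal_groups else set()
    effects = np.zeros(len(mirnas))
    lo, hi = params.effect_range
    for g in group_ids:
        if g not in signal_groups:
            continue
        members = scheme.groups[g]
        n_alt = max(1, int(round(params.frac_alt_within_signal_group * len(members))))
        picked = rng.choice(np.asarray(members, dtype=object), size=n_alt, replace=False)
        for m in picked:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            effects[mirnas.index(m)] = sign * rng.uniform(lo, hi)

    n_pat = params.n_patients
    baseline = rng.normal(params.ct_baseline_mean, params.ct_baseline_sd, size=len(mirnas))
    ratio = params.dct_var_ratio
    normal_ct = baseline[None, :] + _exchangeable_noise(
        rng, n_pat, group_idx,
        params.sigma_a2 * ratio, params.sigma_b2 * ratio, params.sigma_e2 * ratio,
    )
    tumor_ct = normal_ct + effects[None, :] + _exchangeable_noise(
        rng, n_pat, group_idx, params.sigma_a2, params.sigma_b2, params.sigma_e2
    )

    if params.missingness:
        missing_pair = (normal_ct > params.ct_cutoff) | (tumor_ct > params.ct_cutoff)
    else:
        missing_pair = np.zeros_like(normal_ct, dtype=bool)
    normal_dct = np.where(missing_pair, np.nan, normal_ct - REFERENCE_CT)
    tumor_dct = np.where(missing_pair, np.nan, tumor_ct - REFERENCE_CT)

    patients = [f"P{j + 1:02d}" for j in range(n_pat)]
    tumor_df = pd.DataFrame(tumor_dct.T, index=mirnas, columns=patients)
    normal_df = pd.DataFrame(normal_dct.T, index=mirnas, columns=patients)

    # pre-processing drop rule: remove miRNAs missing in more than half the patients
    frac_missing = tumor_df.isna().mean(axis=1)
    keep = frac_missing[frac_missing <= 0.5].index
    tumor_df = tumor_df.loc[keep]
    normal_df = normal_df.loc[keep]

    table = ExpressionTable(tumor=tumor_df, normal=normal_df)
    kept = set(keep)
    truth = SyntheticTruth(
        is_null={m: effects[i] == 0.0 for i, m in enumerate(mirnas) if m in kept},
        true_effect={m: float(effects[i]) for i, m in enumerate(mirnas) if m in kept},
        group_of_truth={m: scheme.assignment[m] for m in mirnas if m in kept},
    )
    return table, truth


def generate_dataset(
    params: SimulationParams, out_dir: str | Path | None = None
) -> tuple[ExpressionTable, list[AnnotationRecord], SyntheticTruth]:
    """Annotation + expression + truth under a single seed; optional fixtures.

    When ``out_dir`` is given, writes ``expression.csv``, ``annotation.tsv``
    and ``truth.tsv`` there.
    """
    rng = np.random.default_rng(params.seed)
    annotation = generate_annotation(params, rng)
    table, truth = generate_expression(annotation, params, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression(table, out / "expression.csv")
        write_annotation(annotation, out / "annotation.tsv")
        truth_df = pd.DataFrame(
            {
                "mirna_id": list(truth.is_null),
                "is_null": [int(truth.is_null[m]) for m in truth.is_null],
                "true_effect": [truth.true_effect[m] for m in truth.is_null],
                "group": [truth.group_of_truth[m] for m in truth.is_null],
            }
        )
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return table, annotation, truth
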