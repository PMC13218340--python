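"""Intra- vs inter-group correlation of ddCt values.

Under an exchangeable random-effects model the ddCt value of miRNA *i* in
patient *j* decomposes as

    z[j, i] = mu_i + a_j + b[j, g(i)] + e[j, i]

with independent patient (a), patient-by-group (b) and residual (e)
components, so any two miRNAs in the same group share correlation
(sa2 + sb2) / (sa2 + sb2 + se2) and any two miRNAs in different groups share
sa2 / (sa2 + sb2 + se2), constant across groups.  The moment estimator used
here averages pairwise Pearson correlations over all within-group pairs
(intra) and all between-group pairs (inter); per-miRNA means mu_i are
absorbed by the centering inside each correlation.  Missing ddCt values are
handled pairwise-complete, and pairs sharing fewer than three patients are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from groupfdr.detest import DeltaDeltaTable, InsufficientDataError
from groupfdr.grouping import GroupingScheme

MIN_SHARED_PATIENTS = 3


@dataclass
class CorrelationEstimate:
    rho_intra: float
    rho_inter: float
    n_intra_pairs: int
    n_inter_pairs: int


def estimate_correlations(
    ddct: DeltaDeltaTable, scheme: GroupingScheme
) -> CorrelationEstimate:
    """Average pairwise correlation within and between groups.

    Correlations use pairwise-complete observations; the estimates are the
    moment estimators of the exchangeable-model intra- and inter-group
    correlations described in the module docstring.
    """
    values = ddct.values
    mirnas = [m for m in values.index if m in scheme.assignment]
    if len(mirnas) < 2:
        raise InsufficientDataError("need at least two grouped miRNAs")
    sub = values.loc[mirnas].T  # patients x miRNAs
    if sub.shape[0] < MIN_SHARED_PATIENTS:
        raise InsufficientDataError("need at least three patients")

    corr = sub.corr(min_periods=MIN_SHARED_PATIENTS).to_numpy()
    labels = np.asarray([scheme.assignment[m] for m in mirnas])
    same = labels[:, None] == labels[None, :]
    upper = np.triu(np.ones_like(same, dtype=bool), k=1)
    valid = upper & np.isfinite(corr)

    intra_mask = valid & same
    inter_mask = valid & ~same
    n_intra = int(intra_mask.sum())
    n_inter = int(inter_mask.sum())
    if n_intra == 0 or n_inter == 0:
        raise InsufficientDataError("no usable within-group or between-group pairs")
    return CorrelationEstimate(
        rho_intra=float(corr[intra_mask].mean()),
        rho_inter=float(corr[inter_mask].mean()),
        n_intra_pairs=n_intra,
        n_inter_pairs=n_inter,
    )
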