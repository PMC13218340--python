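"""Directional one-sided paired t-tests on ddCt values.

ddCt = tumor dCt - normal dCt, so a *positive* ddCt means the miRNA is
expressed later (lower) in the tumor, i.e. downregulated; one Ct unit equals
a two-fold change.  For each miRNA the test direction is fixed by the sign of
the median ddCt across patients, and the null hypothesis states that the
deregulation in that direction does not exceed ``2**delta``-fold (delta Ct
units, default 1.0 = two-fold):

* direction "down" (median ddCt > 0): H1: mu > delta,
  t = (dbar - delta) / (s / sqrt(m)), p = upper tail of Student-t(m - 1);
* direction "up" (median ddCt < 0): H1: mu < -delta,
  t = (dbar + delta) / (s / sqrt(m)), p = lower tail.

Only complete tumor/normal pairs enter the statistics (complete-case
analysis).  Median imputation of missing ddCt values is provided solely for
sensitivity comparisons: imputing at the per-miRNA median deflates the
sample variance and inflates detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from groupfdr.io_model import ExpressionTable

logger = logging.getLogger(__name__)

Direction = Literal["up", "down", "none"]


class InsufficientDataError(ValueError):
    """Too few complete observations to carry out the requested operation."""


class DegenerateVarianceError(ValueError):
    """The complete-case sample standard deviation is zero."""


@dataclass
class DeltaDeltaTable:
    """Per-(patient, miRNA) ddCt values; NaN where the source pair was missing."""

    values: pd.DataFrame  # rows miRNAs, columns patients

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TestResult:
    mirna_id: str
    direction: Direction
    m: int  # complete pairs used
    mean_ddct: float
    t_stat: float
    p_raw: float
    n_missing_pairs: int
    flag: str | None = None  # reason the miRNA was untestable, if any


def compute_ddct(expr: ExpressionTable) -> DeltaDeltaTable:
    """ddCt = tumor dCt - normal dCt per (patient, miRNA); NaN propagates."""
    return DeltaDeltaTable(values=expr.tumor - expr.normal)


def direction_from_median(ddct_vector: Sequence[float] | np.ndarray | pd.Series) -> Direction:
    """Test direction from the sign of the median ddCt over complete cases.

    Positive ddCt means downregulation in tumor.  A zero median falls back to
    the sign of the mean; a zero mean as well yields ``"none"``.
    """
    arr = np.asarray(ddct_vector, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("all ddCt values missing")
    med = float(np.median(arr))
    if med > 0:
        return "down"
    if med < 0:
        return "up"
    mean = float(np.mean(arr))
    if mean > 0:
        return "down"
    if mean < 0:
        return "up"
    return "none"


def paired_one_sided_t(
    ddct_vector: Sequence[float] | np.ndarray | pd.Series,
    delta: float = 1.0,
    mirna_id: str = "",
) -> TestResult:
    """One-sided paired t-test on complete-case ddCt values.

    The alternative direction is set by :func:`direction_from_median`; the
    null boundary sits ``delta`` Ct units from zero in that direction.
    """
    full = np.asarray(ddct_vector, dtype=float)
    arr = full[~np.isnan(full)]
    n_missing = int(full.size - arr.size)
    if arr.size == 0:
        raise InsufficientDataError("all ddCt values missing")
    direction = direction_from_median(arr)
    mean = float(np.mean(arr))
    m = int(arr.size)
    if direction == "none":
        logger.warning("%s: zero median and mean ddCt; p set to 1", mirna_id or "<miRNA>")
        return TestResult(mirna_id, "none", m, mean, float("nan"), 1.0, n_missing, flag="no_direction")
    if m < 2:
        raise InsufficientDataError(f"{mirna_id}: need >= 2 complete pairs, have {m}")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError(f"{mirna_id}: zero sample standard deviation")
    se = sd / np.sqrt(m)
    if direction == "down":
        t = (mean - delta) / se
        p = float(stats.t.sf(t, df=m - 1))
    else:
        t = (mean + delta) / se
        p = float(stats.t.cdf(t, df=m - 1))
    return TestResult(mirna_id, direction, m, mean, float(t), p, n_missing)


def test_all(ddct: DeltaDeltaTable, delta: float = 1.0) -> list[TestResult]:
    """Run the directional paired t-test for every miRNA.

    Untestable miRNAs (too few complete pairs, constant values, no direction)
    are not dropped: they are returned flagged with p = 1 so downstream
    multiple-testing procedures see the full hypothesis family.
    """
    results = []
    n_patients = len(ddct.patient_ids)
    for mirna_id, row in ddct.values.iterrows():
        try:
            res = paired_one_sided_t(row.to_numpy(), delta=delta, mirna_id=str(mirna_id))
        except (InsufficientDataError, DegenerateVarianceError) as exc:
            logger.warning("%s untestable: %s", mirna_id, exc)
            arr = row.to_numpy(dtype=float)
            arr = arr[~np.isnan(arr)]
            res = TestResult(
                mirna_id=str(mirna_id),
                direction="none",
                m=int(arr.size),
                mean_ddct=float(np.mean(arr)) if arr.size else float("nan"),
                t_stat=float("nan"),
                p_raw=1.0,
                n_missing_pairs=n_patients - int(arr.size),
                flag=type(exc).__name__,
            )
        results.append(res)
    return results


def median_impute(ddct: DeltaDeltaTable) -> DeltaDeltaTable:
    """Replace each missing ddCt by the per-miRNA median over observed patients.

    Used only for the sensitivity comparison against the complete-case path;
    see the module docstring for why it inflates detections.
    """
    values = ddct.values
    if values.notna().sum(axis=1).eq(0).any():
        offenders = values.index[values.notna().sum(axis=1).eq(0)].tolist()
        raise InsufficientDataError(f"all values missing for miRNA(s): {offenders}")
    medians = values.median(axis=1, skipna=True)
    imputed = values.apply(lambda col: col.fillna(medians), axis=0)
    return DeltaDeltaTable(values=imputed)


def negate(ddct: DeltaDeltaTable) -> DeltaDeltaTable:
    """Sign-flipped copy; swaps up/down directions, preserves p-values."""
    return replace(ddct, values=-ddct.values)
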