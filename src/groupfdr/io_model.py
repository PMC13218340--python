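"""Data containers and plain-text readers/writers.

Expression input is a table of dCt values (expression relative to endogenous
controls, in Ct units) for matched tumor/normal tissue pairs.  Missing values
are always *pairwise*: a qPCR reaction that fails to cross the detection
threshold in either tissue invalidates the whole tumor/normal pair, so the
readers repair one-sided gaps to pairwise gaps rather than rejecting them.

Formats are deliberately minimal: CSV/TSV for expression (wide or long
dialect), TSV for annotations and results, and a flat ``key = value`` text
file for run configuration.  Missing entries are encoded as an empty field or
the literal ``NA`` on read and written back as ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("tumor", "normal")

_CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Malformed input file (bad header, bad field values)."""


class DuplicateError(ValueError):
    """Duplicate (patient, miRNA, tissue) observation in an input file."""


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


@dataclass
class ExpressionTable:
    """Paired dCt values, one matrix per tissue (rows miRNAs, cols patients).

    ``tumor`` and ``normal`` are float DataFrames indexed by ``mirna_ids``
    with ``patient_ids`` columns; NaN marks a missing pair and appears in
    both matrices at the same positions (pairwise missingness).
    """

    tumor: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tumor.index.equals(self.normal.index) or not self.tumor.columns.equals(
            self.normal.columns
        ):
            raise ValidationError("tumor and normal matrices must share index and columns")
        if self.tumor.index.has_duplicates or self.tumor.columns.has_duplicates:
            raise DuplicateError("miRNA and patient identifiers must be unique")
        self.enforce_pairwise()
        for name, m in (("tumor", self.tumor), ("normal", self.normal)):
            vals = m.to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite Ct value in {name} matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.tumor.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.tumor.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing pairs (True = pair missing)."""
        return self.tumor.isna()

    def enforce_pairwise(self) -> None:
        """Repair one-sided missingness: blank the surviving half of a pair."""
        tumor_na = self.tumor.isna()
        normal_na = self.normal.isna()
        mismatch = tumor_na ^ normal_na
        n_bad = int(mismatch.to_numpy().sum())
        if n_bad:
            logger.warning(
                "repaired %d one-sided missing value(s) to pairwise missingness", n_bad
            )
            either = tumor_na | normal_na
            self.tumor = self.tumor.mask(either)
            self.normal = self.normal.mask(either)


@dataclass(frozen=True)
class AnnotationRecord:
    """Genomic placement of one miRNA: chromosome, strand, arm, 1-based start."""

    mirna_id: str
    chrom: str
    strand: Literal["+", "-"]
    arm: Literal["p", "q"]
    start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.mirna_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.arm not in ("p", "q"):
            raise ValidationError(f"{self.mirna_id}: arm must be 'p' or 'q', got {self.arm!r}")
        if not isinstance(self.start, int) or isinstance(self.start, bool):
            raise ValidationError(f"{self.mirna_id}: start must be an integer")
        if self.start < 1:
            raise ValidationError(f"{self.mirna_id}: start must be >= 1 (1-based coordinates)")


@dataclass
class RunConfig:
    """Pipeline configuration.

    alpha
        Nominal FDR level.
    epsilon, tau
        SABHA tuning: lower clip for the per-group null-proportion estimate
        and the censoring threshold of the tau-censored estimator.
    delta
        Fold-change offset of the one-sided t-test null, in Ct units
        (1 Ct unit = 2-fold).
    k_values
        Maximum group sizes for the refined grouping schemes, descending.
    n_reps
        Replications of the random-group-assignment control study.
    """

    alpha: float = 0.05
    epsilon: float = 0.1
    tau: float = 0.5
    delta: float = 1.0
    k_values: tuple[int, ...] = tuple(range(25, 4, -2))
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValidationError("epsilon must be in (0, 1]")
        if not 0 < self.tau < 1:
            raise ValidationError("tau must be in (0, 1)")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        self.k_values = tuple(int(k) for k in self.k_values)
        if any(k < 2 for k in self.k_values):
            raise ValidationError("all k values must be >= 2")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` configuration file."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"config line has no '=': {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in ("alpha", "epsilon", "tau", "delta"):
                kwargs[key] = float(value)
            elif key in ("n_reps", "seed"):
                kwargs[key] = int(value)
            elif key == "k_values":
                kwargs[key] = tuple(int(v) for v in value.replace(",", " ").split())
            else:
                raise FormatError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class ResultRow:
    """One output row: test outcome plus per-(method, scheme) detection flags."""

    mirna_id: str
    chrom: str
    strand: str
    arm: str
    mean_ddct: float
    p_raw: float
    n_missing_pairs: int
    detected_by: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_raw) or 0.0 <= self.p_raw <= 1.0):
            raise ValidationError(f"{self.mirna_id}: p_raw must lie in [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def _parse_missing(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.replace({"NA": np.nan, "": np.nan}).astype(float)


def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_expression(path: str | Path, dialect: Literal["wide", "long"] = "wide") -> ExpressionTable:
    """Load a paired dCt table.

    Wide dialect: one row per miRNA, columns ``<patient>_<tissue>`` for both
    tissues.  Long dialect: columns (mirna_id, patient_id, tissue, delta_ct).
    One-sided missing pairs are repaired to fully-missing pairs with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if df.columns[0] != "mirna_id":
            raise FormatError("wide expression file must start with a 'mirna_id' column")
        if df["mirna_id"].duplicated().any():
            dupes = df.loc[df["mirna_id"].duplicated(), "mirna_id"].tolist()
            raise DuplicateError(f"duplicated miRNA rows: {dupes}")
        df = df.set_index("mirna_id")
        patients: list[str] = []
        for col in df.columns:
            if "_" not in col:
                raise FormatError(f"wide column {col!r} is not of the form <patient>_<tissue>")
            patient, tissue = col.rsplit("_", 1)
            if tissue not in TISSUES:
                raise FormatError(f"unknown tissue suffix in column {col!r}")
            if patient not in patients:
                patients.append(patient)
        matrices = {}
        for tissue in TISSUES:
            cols = [f"{p}_{tissue}" for p in patients]
            missing_cols = [c for c in cols if c not in df.columns]
            if missing_cols:
                raise FormatError(f"missing columns: {missing_cols}")
            mat = _parse_missing(df[cols])
            mat.columns = patients
            matrices[tissue] = mat
        return ExpressionTable(tumor=matrices["tumor"], normal=matrices["normal"])
    if dialect == "long":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        required = ["mirna_id", "patient_id", "tissue", "delta_ct"]
        if list(df.columns[:4]) != required:
            raise FormatError(f"long expression file must have columns {required}")
        bad_tissue = set(df["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise FormatError(f"unknown tissue labels: {sorted(bad_tissue)}")
        if df.duplicated(subset=["mirna_id", "patient_id", "tissue"]).any():
            raise DuplicateError("duplicated (miRNA, patient, tissue) rows")
        df["delta_ct"] = _parse_missing(df[["delta_ct"]])["delta_ct"]
        mirnas = list(dict.fromkeys(df["mirna_id"]))
        patients = list(dict.fromkeys(df["patient_id"]))
        matrices = {}
        for tissue in TISSUES:
            sub = df[df["tissue"] == tissue]
            mat = sub.pivot(index="mirna_id", columns="patient_id", values="delta_ct")
            matrices[tissue] = mat.reindex(index=mirnas, columns=patients)
        return ExpressionTable(tumor=matrices["tumor"], normal=matrices["normal"])
    raise ValueError(f"unknown dialect {dialect!r}")


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Load a miRNA annotation TSV (mirna_id, chrom, strand, arm, start)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["mirna_id", "chrom", "strand", "arm", "start"]
    if list(df.columns[:5]) != required:
        raise FormatError(f"annotation file must have columns {required}")
    if df["mirna_id"].duplicated().any():
        raise DuplicateError("duplicated mirna_id in annotation")
    records = []
    for row in df.itertuples(index=False):
        try:
            start = int(row.start)
        except ValueError as exc:
            raise ValidationError(f"{row.mirna_id}: non-integer start {row.start!r}") from exc
        records.append(
            AnnotationRecord(
                mirna_id=row.mirna_id,
                chrom=row.chrom,
                strand=row.strand,
                arm=row.arm,
                start=start,
            )
        )
    return records


def write_annotation(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.mirna_id, r.chrom, r.strand, r.arm, r.start) for r in records],
        columns=["mirna_id", "chrom", "strand", "arm", "start"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    """Write a wide-dialect expression file (missing values as ``NA``)."""
    out = {}
    for patient in table.patient_ids:
        out[f"{patient}_tumor"] = table.tumor[patient]
        out[f"{patient}_normal"] = table.normal[patient]
    df = pd.DataFrame(out, index=pd.Index(table.mirna_ids, name="mirna_id"))
    df.to_csv(path, na_rep="NA")


def write_results(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write a result TSV sorted by ascending raw p-value."""
    if not rows:
        raise ValueError("no result rows to write")
    flag_keys: list[str] = []
    for row in rows:
        for key in row.detected_by:
            if key not in flag_keys:
                flag_keys.append(key)
    records = []
    for row in rows:
        rec = {
            "mirna_id": row.mirna_id,
            "chrom": row.chrom,
            "strand": row.strand,
            "arm": row.arm,
            "mean_ddct": row.mean_ddct,
            "p_raw": row.p_raw,
            "n_missing_pairs": row.n_missing_pairs,
        }
        for key in flag_keys:
            rec[key] = int(bool(row.detected_by.get(key, False)))
        records.append(rec)
    df = pd.DataFrame(records)
    df = df.sort_values(["p_raw", "mirna_id"], kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> list[ResultRow]:
    """Parse a result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["mirna_id", "chrom", "strand", "arm", "mean_ddct", "p_raw", "n_missing_pairs"]
    flag_keys = [c for c in df.columns if c not in fixed]
    rows = []
    for d in df.to_dict(orient="records"):
        rows.append(
            ResultRow(
                mirna_id=d["mirna_id"],
                chrom=str(d["chrom"]),
                strand=d["strand"],
                arm=d["arm"],
                mean_ddct=float(d["mean_ddct"]),
                p_raw=float(d["p_raw"]),
                n_missing_pairs=int(d["n_missing_pairs"]),
                detected_by={k: bool(d[k]) for k in flag_keys},
            )
        )
    return rows


def chromosome_order(chrom: str) -> tuple[int, str]:
    """Deterministic sort key for chromosome labels: 1..22, X, Y, then others."""
    if chrom in _CHROMOSOMES:
        return (_CHROMOSOMES.index(chrom), "")
    return (len(_CHROMOSOMES), chrom)
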