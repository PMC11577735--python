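"""Cohort containers and I/O.

A cohort pairs a log2-scale gene (or probe) expression matrix with a
per-sample clinical annotation table carrying right-censored overall
survival and the standard HGSC prognostic covariates (age, FIGO stage,
surgical debulking status).  Loading is strict by default: non-numeric
expression cells and duplicate sample IDs are errors, samples lacking
survival annotation are dropped (and logged) during alignment, and
follow-up can be administratively censored at a fixed horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGE_LEVELS = ("low", "high", "NA")
DEBULKING_LEVELS = ("optimal", "suboptimal", "NA")

#: FIGO roman/arabic stage codes mapped onto the two-level coding.
FIGO_MAP = {
    "I": "low", "II": "low", "1": "low", "2": "low",
    "III": "high", "IV": "high", "3": "high", "4": "high",
}

CLINICAL_REQUIRED = ("os_time", "os_event")
CLINICAL_OPTIONAL = ("age", "stage", "debulking")


class CohortError(ValueError):
    """Raised for malformed expression or clinical inputs."""


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of log2 expression values.

    ``data`` is indexed by feature ID (gene symbol or array probe ID) with
    sample IDs as columns.  Duplicate feature IDs are permitted (multi-probe
    genes, collapsed later); duplicate sample IDs are not.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "probe"):
            raise CohortError(f"feature_kind must be 'gene' or 'probe', got {self.feature_kind!r}")
        if self.data.shape[0] == 0:
            raise CohortError("expression matrix has no features")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample IDs in expression matrix: {dups}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise CohortError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.feature_kind)


@dataclass
class ClinicalTable:
    """Per-sample survival and covariate annotations.

    Index is the sample ID; columns os_time (years), os_event (0/1) and the
    optional covariates age (years), stage ({low, high, NA}) and debulking
    ({optimal, suboptimal, NA}).  Missing covariate values are NA; missing
    survival is allowed here and resolved (dropped) by :func:`align_cohort`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in CLINICAL_REQUIRED:
            if col not in self.data.columns:
                raise CohortError(f"clinical table missing required column {col!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample IDs in clinical table: {dups}")
        ev = self.data["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise CohortError("os_event must be 0 or 1")
        t = self.data["os_time"].dropna()
        if (t < 0).any():
            raise CohortError("os_time must be >= 0")
        for col, levels in (("stage", STAGE_LEVELS), ("debulking", DEBULKING_LEVELS)):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                bad = set(vals.unique()) - set(levels)
                if bad:
                    raise CohortError(f"invalid {col} values {sorted(bad)}; expected {levels}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class Cohort:
    """An expression matrix aligned with its clinical table (same samples, same order)."""

    expr: ExpressionMatrix
    clinical: ClinicalTable
    name: str = "cohort"
    dropped_samples: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expr.sample_ids != self.clinical.sample_ids:
            raise CohortError("expression and clinical sample IDs differ in content or order; use align_cohort")

    @property
    def n_samples(self) -> int:
        return len(self.expr.sample_ids)

    @property
    def sample_ids(self) -> list[str]:
        return self.expr.sample_ids


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_expression_matrix(
    path,
    feature_kind: str = "gene",
    log2_offset: float | None = None,
    missing: str = "strict",
) -> ExpressionMatrix:
    """Load a delimited features x samples expression matrix.

    The first column holds feature IDs, the header row sample IDs.  Values
    must be numeric; with ``missing="strict"`` (default) any empty or
    non-numeric cell is a parse error naming the offending feature and
    sample, while ``missing="impute"`` fills missing cells with the
    feature's row mean.  ``log2_offset`` applies log2(x + offset) for
    raw-scale inputs; by default values are assumed already log2.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    # pandas silently renames duplicate header fields, so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = [sid for sid in set(header) if header.count(sid) > 1]
    if dups:
        raise CohortError(f"duplicate sample IDs in {path.name}: {sorted(dups)}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    values = raw.apply(pd.to_numeric, errors="coerce")
    bad_mask = values.isna().to_numpy()
    if bad_mask.any():
        if missing == "strict":
            r, c = np.argwhere(bad_mask)[0]
            feat, samp = values.index[r], values.columns[c]
            cell = raw.iat[r, c]
            raise CohortError(
                f"non-numeric expression cell at feature {feat!r}, sample {samp!r}: {cell!r}"
            )
        elif missing == "impute":
            row_means = values.mean(axis=1)
            if row_means.isna().any():
                empty = values.index[row_means.isna()].tolist()
                raise CohortError(f"features with no numeric values cannot be imputed: {empty}")
            values = values.T.fillna(row_means).T
            logger.warning("imputed %d missing expression cells with row means", int(bad_mask.sum()))
        else:
            raise CohortError(f"unknown missing policy {missing!r}")
    if log2_offset is not None:
        values = np.log2(values + log2_offset)
    return ExpressionMatrix(values.astype(float), feature_kind=feature_kind)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    expr.data.to_csv(path, sep=_sniff_sep(path), index_label="feature_id")


def load_clinical_table(path, map_figo: bool = False) -> ClinicalTable:
    """Load a clinical annotation table keyed by sample_id.

    Requires columns sample_id, os_time, os_event; age, stage and debulking
    are optional.  ``map_figo=True`` converts roman/arabic FIGO stages
    (I/II -> low, III/IV -> high) before validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise CohortError("clinical table missing 'sample_id' column")
    df = df.set_index("sample_id")
    for col in ("os_time", "os_event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("stage", "debulking"):
        if col in df.columns:
            df[col] = df[col].astype("string").str.strip()
            df[col] = df[col].replace({"": pd.NA, "NA": pd.NA, "nan": pd.NA})
            if col == "stage" and map_figo:
                df[col] = df[col].replace(FIGO_MAP)
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    path = Path(path)
    clinical.data.to_csv(path, sep=_sniff_sep(path), index_label="sample_id", na_rep="NA")


def collapse_probes(
    expr: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    passthrough: bool = True,
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene-level rows by averaging.

    Each gene's row is the arithmetic mean of its probes' log2 values, per
    sample.  Probes absent from the mapping are passed through under their
    own ID when ``passthrough`` is true, otherwise dropped.
    """
    if not probe_to_gene and not passthrough:
        raise CohortError("empty probe-to-gene mapping with passthrough disabled")
    idx = expr.data.index
    genes = idx.map(lambda p: probe_to_gene.get(p, p if passthrough else None))
    keep = genes.notna()
    data = expr.data.loc[keep]
    collapsed = data.groupby(genes[keep], sort=False).mean()
    collapsed.index.name = expr.data.index.name
    return ExpressionMatrix(collapsed, feature_kind="gene")


def align_cohort(expr: ExpressionMatrix, clinical: ClinicalTable, name: str = "cohort") -> Cohort:
    """Restrict expression and clinical data to their shared samples.

    Sample order follows the expression matrix.  Samples missing os_time or
    os_event, or with os_time == 0, are dropped and reported via the
    returned cohort's ``dropped_samples`` mapping and the module logger.
    """
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise CohortError("expression and clinical tables share no sample IDs")
    cdata = clinical.data.loc[shared]
    dropped: dict[str, str] = {}
    for sid, row in cdata.iterrows():
        if pd.isna(row["os_time"]) or pd.isna(row["os_event"]):
            dropped[sid] = "missing survival annotation"
        elif row["os_time"] == 0:
            dropped[sid] = "zero follow-up time"
    keep = [s for s in shared if s not in dropped]
    if not keep:
        raise CohortError("no samples with usable survival annotation after alignment")
    if dropped:
        logger.warning("cohort %s: dropped %d samples during alignment: %s", name, len(dropped), dropped)
    return Cohort(
        expr=expr.subset_samples(keep),
        clinical=ClinicalTable(cdata.loc[keep].copy()),
        name=name,
        dropped_samples=dropped,
    )


def cap_followup(clinical: ClinicalTable, horizon_years: float = 8.0) -> ClinicalTable:
    """Administratively censor follow-up beyond a fixed horizon.

    Samples with os_time strictly greater than the horizon have their time
    set to the horizon and their event indicator set to 0.  Events at
    exactly the horizon are retained (the boundary is inclusive).
    """
    if horizon_years <= 0:
        raise CohortError(f"horizon_years must be positive, got {horizon_years}")
    df = clinical.data.copy()
    over = df["os_time"] > horizon_years
    df.loc[over, "os_time"] = horizon_years
    df.loc[over, "os_event"] = 0
    return ClinicalTable(df)


def cap_cohort(cohort: Cohort, horizon_years: float = 8.0) -> Cohort:
    """Convenience: :func:`cap_followup` applied in place on a cohort."""
    return replace(cohort, clinical=cap_followup(cohort.clinical, horizon_years))
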