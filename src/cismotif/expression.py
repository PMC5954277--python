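"""Expression matrix and condition-design I/O, plus quantile normalization.

The expression matrix is a genes x samples table of log2 intensities (the
scale produced by RMA-style summarization).  The condition design maps each
experimental condition to its treatment samples, control samples, and the
dataset (sample universe) it belongs to; downstream co-expression is computed
over all samples of a condition's dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when an input matrix or design violates its contract."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.  All values
        must be finite floats; gene and sample ids must be unique.
    normalized
        Whether quantile normalization has been applied.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)


@dataclass
class Condition:
    condition_id: str
    treatment_sample_ids: list[str]
    control_sample_ids: list[str]
    dataset_id: str


@dataclass
class ConditionDesign:
    """Sample-to-condition assignment.

    Each condition names >= 2 treatment and >= 2 control samples, disjoint
    from one another, all drawn from the condition's dataset.  Datasets
    partition the samples used for cross-condition z-scores and for
    co-expression.
    """

    conditions: list[Condition]
    datasets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.conditions:
            if c.condition_id in seen:
                raise ValidationError(f"duplicate condition id {c.condition_id!r}")
            seen.add(c.condition_id)
            if len(c.treatment_sample_ids) < 2:
                raise ValidationError(
                    f"condition {c.condition_id!r}: needs >=2 treatment samples"
                )
            if len(c.control_sample_ids) < 2:
                raise ValidationError(
                    f"condition {c.condition_id!r}: needs >=2 control samples"
                )
            overlap = set(c.treatment_sample_ids) & set(c.control_sample_ids)
            if overlap:
                raise ValidationError(
                    f"condition {c.condition_id!r}: samples in both roles: {sorted(overlap)}"
                )
            ds = self.datasets.get(c.dataset_id)
            if ds is None:
                raise ValidationError(
                    f"condition {c.condition_id!r}: unknown dataset {c.dataset_id!r}"
                )
            missing = (set(c.treatment_sample_ids) | set(c.control_sample_ids)) - set(ds)
            if missing:
                raise ValidationError(
                    f"condition {c.condition_id!r}: samples not in dataset "
                    f"{c.dataset_id!r}: {sorted(missing)}"
                )

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def conditions_of_dataset(self, dataset_id: str) -> list[Condition]:
        return [c for c in self.conditions if c.dataset_id == dataset_id]

    def validate_against(self, m: ExpressionMatrix) -> None:
        known = set(m.sample_ids)
        for ds_id, samples in self.datasets.items():
            missing = set(samples) - known
            if missing:
                raise ValidationError(
                    f"dataset {ds_id!r}: samples absent from matrix: {sorted(missing)}"
                )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (column 1 = gene id, header = sample ids).

    Rows with a gene id listed twice are rejected: an identifier that maps to
    more than one measurement is ambiguous and is discarded wholesale rather
    than silently collapsed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise ValidationError(
                    f"non-numeric value at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_design(path: str | Path) -> ConditionDesign:
    """Read a condition design from YAML or JSON."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    conditions = [
        Condition(
            condition_id=str(c["condition_id"]),
            treatment_sample_ids=[str(s) for s in c["treatment_sample_ids"]],
            control_sample_ids=[str(s) for s in c["control_sample_ids"]],
            dataset_id=str(c["dataset_id"]),
        )
        for c in doc["conditions"]
    ]
    datasets = {str(k): [str(s) for s in v] for k, v in doc["datasets"].items()}
    return ConditionDesign(conditions=conditions, datasets=datasets)


def write_design(design: ConditionDesign, path: str | Path) -> None:
    doc = {
        "conditions": [
            {
                "condition_id": c.condition_id,
                "treatment_sample_ids": c.treatment_sample_ids,
                "control_sample_ids": c.control_sample_ids,
                "dataset_id": c.dataset_id,
            }
            for c in design.conditions
        ],
        "datasets": design.datasets,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a common reference distribution.

    The reference is the vector of row means of the column-sorted matrix.
    Each value is replaced by the reference value at its within-column rank;
    tied values receive the mean of the reference values at their tied rank
    positions, so the map is well defined and rank order is preserved.
    """
    if m.data.shape[0] == 0 or m.data.shape[1] == 0:
        raise ValidationError("cannot quantile-normalize an empty matrix")
    values = m.data.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average reference values across ties within the column
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(df, normalized=True)
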