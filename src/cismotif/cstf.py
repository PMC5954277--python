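"""Condition-specific transcription factor (CsTF) selection.

A TF is differentially expressed (DETF) in a condition when a two-sided
Welch t-test between treatment and control replicates gives p < alpha and
the log2 fold change (difference of group means on the log2 scale) exceeds
the fold-change threshold.  A DETF is promoted to CsTF when the z-score of
its fold change in that condition, taken over its fold changes across all
conditions of the same dataset, exceeds the z threshold: the TF is not just
induced, it is induced specifically there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression import ConditionDesign, ExpressionMatrix, ValidationError


@dataclass
class DifferentialResult:
    gene_id: str
    p_value: float
    log2_fc: float


@dataclass
class DETFRecord:
    tf_id: str
    condition_id: str
    p_value: float
    log2_fc: float


@dataclass
class ConditionZScore:
    tf_id: str
    condition_id: str
    x: float
    mu: float
    sigma: float
    z: float | None  # None when sigma == 0 (undefined)


@dataclass
class CsTFRecord:
    tf_id: str
    condition_id: str
    p_value: float
    log2_fc: float
    z: float


def test_differential(
    m: ExpressionMatrix,
    design: ConditionDesign,
    gene_ids: list[str],
    condition_id: str,
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Welch t-test (two-sided) and log2 fold change per gene for one condition.

    Degenerate case: when both groups have zero variance the t statistic is
    undefined; p is set to 0 if the means differ and 1 if they are equal,
    with a warning.
    """
    cond = design.condition(condition_id)
    if len(cond.treatment_sample_ids) < 2:
        raise ValidationError(
            f"condition {condition_id!r}: <2 treatment replicates"
        )
    if len(cond.control_sample_ids) < 2:
        raise ValidationError(f"condition {condition_id!r}: <2 control replicates")
    t_vals = m.data.loc[gene_ids, cond.treatment_sample_ids].to_numpy(dtype=float)
    c_vals = m.data.loc[gene_ids, cond.control_sample_ids].to_numpy(dtype=float)
    log2_fc = t_vals.mean(axis=1) - c_vals.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = (t_vals.var(axis=1) == 0) & (c_vals.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance in both groups; "
            "p set to 0 (means differ) or 1 (means equal)",
            stacklevel=2,
        )
        p[degenerate] = np.where(log2_fc[degenerate] != 0.0, 0.0, 1.0)
    return [
        DifferentialResult(g, float(pv), float(fc))
        for g, pv, fc in zip(gene_ids, p, log2_fc)
    ]


def select_detfs(
    results: list[DifferentialResult],
    condition_id: str,
    alpha: float = 0.01,
    min_log2fc: float = 1.0,
    two_sided_fc: bool = False,
) -> list[DETFRecord]:
    """Keep genes with p < alpha and log2_fc strictly above min_log2fc.

    By default only induced TFs qualify (log2_fc > threshold); set
    two_sided_fc to admit |log2_fc| > threshold.
    """
    kept = []
    for r in results:
        fc = abs(r.log2_fc) if two_sided_fc else r.log2_fc
        if r.p_value < alpha and fc > min_log2fc:
            kept.append(DETFRecord(r.gene_id, condition_id, r.p_value, r.log2_fc))
    return kept


def condition_zscore(
    fold_changes: dict[str, float], target_condition: str, tf_id: str = ""
) -> ConditionZScore:
    """z = (x - mu) / sigma over a TF's fold changes across one dataset.

    mu and sigma are the mean and sample (n-1) standard deviation of the fold
    changes over all conditions of the dataset.  sigma = 0 leaves z undefined
    (None): the TF shows no cross-condition contrast and is not promotable.
    """
    if len(fold_changes) < 2:
        raise ValidationError("z-score needs >=2 conditions in the dataset")
    if target_condition not in fold_changes:
        raise KeyError(target_condition)
    values = np.array(list(fold_changes.values()), dtype=float)
    x = float(fold_changes[target_condition])
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    z = (x - mu) / sigma if sigma > 0 else None
    return ConditionZScore(tf_id, target_condition, x, mu, sigma, z)


def select_cstfs(
    detfs: list[DETFRecord],
    zscores: dict[tuple[str, str], ConditionZScore],
    z_threshold: float = 2.0,
) -> list[CsTFRecord]:
    """Promote DETFs whose condition z-score strictly exceeds the threshold.

    zscores is keyed by (tf_id, condition_id); every DETF must have one.
    A TF may be a CsTF in several conditions.
    """
    out = []
    for d in detfs:
        key = (d.tf_id, d.condition_id)
        if key not in zscores:
            raise ValidationError(f"no z-score computed for DETF {key}")
        z = zscores[key].z
        if z is not None and z > z_threshold:
            out.append(CsTFRecord(d.tf_id, d.condition_id, d.p_value, d.log2_fc, z))
    return out


def call_cstfs(
    m: ExpressionMatrix,
    design: ConditionDesign,
    tf_ids: list[str],
    alpha: float = 0.01,
    min_log2fc: float = 1.0,
    z_threshold: float = 2.0,
    equal_var: bool = False,
    two_sided_fc: bool = False,
) -> tuple[list[DETFRecord], dict[tuple[str, str], ConditionZScore], list[CsTFRecord]]:
    """Full CsTF calling over every condition of every dataset.

    Returns (all DETFs, z-scores for every TF x condition, CsTFs).
    """
    tf_ids = [t for t in tf_ids if t in set(m.gene_ids)]
    # fold changes for every TF in every condition, grouped by dataset
    fc: dict[str, dict[str, dict[str, float]]] = {}  # dataset -> tf -> cond -> fc
    per_condition: dict[str, list[DifferentialResult]] = {}
    for cond in design.conditions:
        res = test_differential(m, design, tf_ids, cond.condition_id, equal_var)
        per_condition[cond.condition_id] = res
        ds = fc.setdefault(cond.dataset_id, {})
        for r in res:
            ds.setdefault(r.gene_id, {})[cond.condition_id] = r.log2_fc
    detfs: list[DETFRecord] = []
    for cond in design.conditions:
        detfs.extend(
            select_detfs(
                per_condition[cond.condition_id],
                cond.condition_id,
                alpha,
                min_log2fc,
                two_sided_fc,
            )
        )
    zscores: dict[tuple[str, str], ConditionZScore] = {}
    for dataset_id, by_tf in fc.items():
        for tf, cond_fc in by_tf.items():
            if len(cond_fc) < 2:
                continue
            for cond_id in cond_fc:
                zscores[(tf, cond_id)] = condition_zscore(cond_fc, cond_id, tf)
    cstfs = select_cstfs(detfs, zscores, z_threshold)
    return detfs, zscores, cstfs
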