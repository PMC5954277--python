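"""Co-expressed gene groups of CsTFs.

Differentially expressed genes (DEGs) of the CsTF's condition are screened
by Pearson correlation against the CsTF's expression profile, computed over
ALL samples of the condition's dataset (not only the treatment/control
arrays of that condition), and genes with PCC >= 0.8 form the group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cstf import CsTFRecord, test_differential
from .expression import ConditionDesign, ExpressionMatrix

#: Groups smaller than this are flagged as discarded before enrichment.
DEFAULT_MIN_GROUP_SIZE = 10


@dataclass
class CoexpressionGroup:
    cstf_id: str
    condition_id: str
    member_gene_ids: list[str]
    pcc: dict[str, float] = field(default_factory=dict)
    discarded: bool = False

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def select_degs(
    m: ExpressionMatrix,
    design: ConditionDesign,
    condition_id: str,
    alpha: float = 0.01,
    min_abs_log2fc: float = math.log2(1.5),
    equal_var: bool = False,
) -> list[str]:
    """DEGs of one condition: p < alpha and |log2 fc| >= min_abs_log2fc.

    Note the asymmetric boundaries: the p threshold is strict, the
    fold-change threshold is inclusive.
    """
    res = test_differential(m, design, m.gene_ids, condition_id, equal_var)
    return [
        r.gene_id
        for r in res
        if r.p_value < alpha and abs(r.log2_fc) >= min_abs_log2fc
    ]


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN for a constant vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if u.size < 3:
        raise ValueError("need >=3 observations")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan")
    du = u - u.mean()
    dv = v - v.mean()
    return float(du @ dv / math.sqrt((du @ du) * (dv @ dv)))


def build_group(
    cstf: CsTFRecord,
    deg_ids: list[str],
    m: ExpressionMatrix,
    design: ConditionDesign,
    min_pcc: float = 0.8,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    include_self: bool = False,
) -> CoexpressionGroup:
    """Correlate the CsTF against each DEG over the dataset's samples.

    Members are DEGs with PCC >= min_pcc (inclusive).  DEGs with constant
    expression have undefined correlation and are excluded.  The CsTF itself
    is excluded from membership unless include_self is set.  A group below
    min_group_size is kept but flagged discarded (too few promoters to
    calibrate enrichment).
    """
    cond = design.condition(cstf.condition_id)
    samples = design.datasets[cond.dataset_id]
    tf_row = m.data.loc[cstf.tf_id, samples].to_numpy(dtype=float)

    candidates = [g for g in deg_ids if include_self or g != cstf.tf_id]
    if not candidates:
        warnings.warn(
            f"CsTF {cstf.tf_id} ({cstf.condition_id}): empty DEG list", stacklevel=2
        )
    sub = m.data.loc[candidates, samples].to_numpy(dtype=float)
    members: list[str] = []
    pcc: dict[str, float] = {}
    if len(candidates) and np.ptp(tf_row) > 0:
        tf_c = tf_row - tf_row.mean()
        tf_norm = math.sqrt(tf_c @ tf_c)
        centered = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered * centered).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (centered @ tf_c) / (norms * tf_norm)
        for g, ri, ni in zip(candidates, r, norms):
            if ni == 0:  # constant DEG: undefined correlation
                continue
            if ri >= min_pcc:
                members.append(g)
                pcc[g] = float(ri)
    group = CoexpressionGroup(
        cstf_id=cstf.tf_id,
        condition_id=cstf.condition_id,
        member_gene_ids=members,
        pcc=pcc,
        discarded=len(members) < min_group_size,
    )
    if group.discarded:
        warnings.warn(
            f"CsTF {cstf.tf_id} ({cstf.condition_id}): group size {group.size} "
            f"< {min_group_size}; discarded before further analysis",
            stacklevel=2,
        )
    return group
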