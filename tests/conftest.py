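import numpy as np
import pandas as pd
import pytest

from cismotif.expression import Condition, ConditionDesign, ExpressionMatrix
from cismotif.promoters import PromoterRecord, PromoterSet


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = ["s1", "s2", "s3", "s4"]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, (6, 4)), index=genes, columns=samples)
    )


@pytest.fixture
def two_condition_design() -> ConditionDesign:
    return ConditionDesign(
        conditions=[
            Condition("condA", ["a_t1", "a_t2"], ["a_c1", "a_c2"], "DS1"),
            Condition("condB", ["b_t1", "b_t2"], ["b_c1", "b_c2"], "DS1"),
        ],
        datasets={"DS1": ["a_t1", "a_t2", "a_c1", "a_c2", "b_t1", "b_t2", "b_c1", "b_c2"]},
    )


def make_promoter_set(seqs_by_gene: dict[str, list[str]]) -> PromoterSet:
    """Build an in-memory promoter set from {gene: [sequence, ...]}."""
    records = []
    pos = 1
    for gene, seqs in seqs_by_gene.items():
        for j, seq in enumerate(seqs, start=1):
            records.append(
                PromoterRecord(
                    promoter_id=f"{gene}.p{j}",
                    gene_id=gene,
                    chromosome="chr1",
                    start=pos,
                    end=pos + len(seq) - 1,
                    strand="+",
                    sequence=seq.upper(),
                )
            )
            pos += len(seq) + 10
    return PromoterSet(records)
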