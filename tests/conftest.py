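import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from retlnc import synthetic
from retlnc.models import ExpressionMatrix, GeneLocus, GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def toy_genome():
    """One deterministic toy genome shared by read-only tests."""
    return synthetic.build_toy_genome(seed=11, n_coding=40, n_single_exon=2)


@pytest.fixture(scope="session")
def toy_expression(toy_genome):
    staged, panel = synthetic.make_expression(toy_genome.truth, seed=12)
    return staged, panel


def make_transcript(
    tid="t1",
    gene="g1",
    exons=((100, 300), (500, 800)),
    strand="+",
    chrom="chrT",
    source="short_read",
    biotype="unknown",
):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return TranscriptModel(tid, gene, ivs, source, biotype)


def make_locus(locus_id="L1", **kwargs):
    return GeneLocus(locus_id, (make_transcript(**kwargs),))


def make_matrix(values, columns=None, conditions=None, unit="FPKM", index=None):
    """Small ExpressionMatrix helper: values is genes x samples array-like."""
    arr = np.asarray(values, dtype=float)
    if columns is None:
        columns = [f"s{i}" for i in range(arr.shape[1])]
    if conditions is None:
        conditions = columns
    if index is None:
        index = [f"g{i}" for i in range(arr.shape[0])]
    reps = {}
    meta = []
    for col, cond in zip(columns, conditions):
        reps[cond] = reps.get(cond, 0) + 1
        meta.append({"condition": cond, "replicate": reps[cond]})
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=index, columns=columns),
        samples=pd.DataFrame(meta, index=columns),
        unit=unit,
    )
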