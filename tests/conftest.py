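"""Shared fixtures: a hand-audited 25-locus variant table, small trees,
and compact geometries used across the suite."""

import numpy as np
import pandas as pd
import pytest

from oncophylogeo.filtering import (CopyNumberSegments, SampleGeometry,
                                    VariantCallTable)
from oncophylogeo.trees import Tree

SAMPLES = ["T1", "T2", "T3", "N1", "N2"]
HEALTHY = np.array([False, False, False, True, True])


def _locus(pos, depth, alt, qual):
    return dict(pos=pos, depth=depth, alt=alt, qual=qual)


def build_toy_table():
    """25 loci over 3 tumor + 2 healthy samples; each filter rule removes a
    known subset (9 loci survive the somatic call filter, 7 the prefilter).
    """
    rows = []
    # 7 clean somatic loci, VAF ~0.3 in at least one tumor sample
    for i in range(7):
        rows.append(_locus(1000 + i, [60, 55, 50, 40, 45],
                           [18, 0, 10, 0, 0], [60] * 5))
    # 2 clean somatic loci with max tumor VAF 0.08 (pass call filter's 0.05,
    # fail the deconvolution prefilter's 0.10)
    for i in range(2):
        rows.append(_locus(2000 + i, [50, 50, 50, 40, 45],
                           [4, 0, 0, 0, 0], [60] * 5))
    # 3 fail coverage (one sample below 20x, including a healthy one)
    rows.append(_locus(3000, [19, 60, 60, 40, 45], [18, 20, 0, 0, 0], [60] * 5))
    rows.append(_locus(3001, [60, 60, 60, 19, 45], [18, 0, 0, 0, 0], [60] * 5))
    rows.append(_locus(3002, [60, 18, 60, 40, 45], [18, 0, 0, 0, 0], [60] * 5))
    # 3 germline (alt evidence in a healthy sample)
    for i in range(3):
        rows.append(_locus(4000 + i, [60, 60, 60, 40, 45],
                           [20, 22, 18, 19, 0], [60] * 5))
    # 3 below the VAF floor everywhere (max tumor VAF 0.04)
    for i in range(3):
        rows.append(_locus(5000 + i, [50, 50, 50, 40, 45],
                           [2, 1, 0, 0, 0], [60] * 5))
    # 3 fail quality (every VAF-passing tumor call below Phred 20)
    for i in range(3):
        rows.append(_locus(6000 + i, [60, 60, 60, 40, 45],
                           [18, 15, 0, 0, 0], [15, 12, 60, 60, 60]))
    # 2 in a non-diploid segment of tumor sample T1 (positions 7000-7499)
    for i in range(2):
        rows.append(_locus(7000 + i, [60, 60, 60, 40, 45],
                           [20, 15, 0, 0, 0], [60] * 5))
    # 2 failing both coverage and germline
    for i in range(2):
        rows.append(_locus(8000 + i, [15, 60, 60, 40, 45],
                           [10, 20, 0, 12, 0], [60] * 5))
    assert len(rows) == 25
    loci = pd.DataFrame({
        "chrom": "1", "pos": [r["pos"] for r in rows],
        "ref": "A", "alt": "T",
    })
    depth = np.array([r["depth"] for r in rows])
    alt = np.array([r["alt"] for r in rows])
    qual = np.array([r["qual"] for r in rows], dtype=float)
    table = VariantCallTable(loci, SAMPLES, depth, alt, qual, HEALTHY)
    cn = CopyNumberSegments(pd.DataFrame([
        {"sample": "T1", "chrom": "1", "start": 6999, "end": 7500,
         "total_cn": 3, "minor_cn": 1},
    ]))
    return table, cn


@pytest.fixture
def toy_table():
    return build_toy_table()


@pytest.fixture
def tree3():
    # ((a,b):1.5,c):0  -> heights: ab at 1.0, root at 2.5
    return Tree([3, 3, 4, 4, -1], [0, 0, 0, 1.0, 2.5], ["a", "b", "c"])


@pytest.fixture
def tree4():
    # ((a,b),(c,d)) with heights 1, 1.2, root 2
    return Tree([4, 4, 5, 5, 6, 6, -1],
                [0, 0, 0, 0, 1.0, 1.2, 2.0], ["a", "b", "c", "d"])


@pytest.fixture
def geometry3():
    return SampleGeometry(["a", "b", "c"], [[0, 0], [1, 0], [0, 2]],
                          ["r1", "r1", "r2"])
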