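import numpy as np
import pandas as pd
import pytest

from mirqtl import simulate
from mirqtl.containers import CausalEffect, ExpressionMatrix, MirnaAnnotation, SimTruth


@pytest.fixture(scope="session")
def small_panel():
    """2000 samples x 100 SNPs, 10-SNP LD blocks at r=0.8."""
    return simulate.simulate_genotypes(
        2000, 100, block_size=10, within_block_r=0.8, maf_range=(0.1, 0.5), seed=11
    )


@pytest.fixture(scope="session")
def locus_panel():
    """Single equicorrelated 30-SNP locus used by coloc/SMR scenario tests."""
    return simulate.simulate_genotypes(
        2000, 30, block_size=30, within_block_r=0.6, maf_range=(0.1, 0.5), seed=5
    )


@pytest.fixture()
def toy_annotation():
    rows = [
        ("miR-a-5p", "mir-a-1", "1", 1_000_000, 1_000_080, "+", "5p", ""),
        ("miR-a-5p", "mir-a-2", "1", 1_100_000, 1_100_080, "+", "5p", ""),
        ("miR-b-3p", "mir-b", "2", 5_000_000, 5_000_090, "-", "3p", ""),
    ]
    return MirnaAnnotation(
        table=pd.DataFrame(
            rows,
            columns=[
                "mature_id", "precursor_id", "chrom", "start", "end",
                "strand", "arm", "cluster",
            ],
        )
    )


def make_truth(panel, feature_snp_vf, mediation=()):
    """Helper: SimTruth from [(feature, snp, var_frac)] triples."""
    return SimTruth(
        causal_map=[CausalEffect(f, s, 1.0, vf) for f, s, vf in feature_snp_vf],
        mediation_map=list(mediation),
    )


def expr_from_values(values, tag="log2", features=None):
    n, m = values.shape
    return ExpressionMatrix(
        sample_id=[f"s{i}" for i in range(n)],
        feature_id=features or [f"f{j}" for j in range(m)],
        values=values,
        tag=tag,
    )
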