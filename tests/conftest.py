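import numpy as np
import pandas as pd
import pytest

import orscreen as ors


def screen_bundle(bundle, **kwargs):
    """Counts -> FPKM -> log2 -> full screen, as a user would run it."""
    cm, _ = ors.align_genes(bundle.counts, bundle.annotation)
    expr = ors.log2_transform(ors.compute_fpkm(cm, bundle.annotation))
    fam = list(bundle.annotation.index[bundle.annotation["family"] == "OR"])
    return expr, ors.run_screen(expr, bundle.cna, fam, **kwargs)


@pytest.fixture(scope="session")
def three_subpop():
    bundle, truth = ors.generate_cohort(ors.three_subpop_config(), seed=0)
    return bundle, truth


@pytest.fixture(scope="session")
def screened(three_subpop):
    bundle, truth = three_subpop
    expr, result = screen_bundle(bundle)
    return bundle, truth, expr, result


@pytest.fixture(scope="session")
def subpops(screened):
    bundle, truth, expr, result = screened
    zsub = result.zscores.values.loc[sorted(result.overexpressed_genes)]
    return ors.cluster_cases(zsub, cases=result.positive_cases, k=3)


@pytest.fixture()
def small_counts(tmp_path):
    """A tiny well-formed count TSV plus its role map."""
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\tS1\tS2\n"
        "G1\t10\t0\n"
        "G2\t5\t7\n"
        "G3\t0\t2\n"
    )
    return path, {"S1": "tumor", "S2": "reference"}


def make_expr(values: pd.DataFrame, roles: pd.Series) -> ors.ExpressionMatrix:
    """Wrap a hand-built log2-scale matrix as an ExpressionMatrix."""
    return ors.ExpressionMatrix(values, roles, stage="log2fpkm", pseudocount=1.0)
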