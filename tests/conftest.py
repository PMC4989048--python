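"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from phenosubnet import paired_de as de
from phenosubnet.synthio import (
    SimConfig,
    simulate_hetnet,
    simulate_paired_counts,
    simulate_regulon_evidence,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_counts():
    """Paired counts for 8 patients x 300 genes with planted signal."""
    cfg = SimConfig(n_genes=300, seed=42)
    counts, meta, truth = simulate_paired_counts(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def hetnet_with_module():
    net, truth = simulate_hetnet(120, 10, 6, seed=8)
    return net, truth


@pytest.fixture(scope="session")
def planted_bundle():
    """Default-size evidence bundle with 4 planted regulons."""
    return simulate_regulon_evidence(seed=7)


@pytest.fixture(scope="session")
def study():
    """Coordinated synthetic study (counts + network + evidence)."""
    return simulate_study(seed=5)


@pytest.fixture(scope="session")
def study_de(study):
    """DE results of the coordinated study, computed once."""
    counts = de.filter_low_expression(study.counts, study.meta, 1.0)
    sf = de.size_factors_median_of_ratios(counts)
    first = de.nb_wald_paired_test(counts, study.meta, sf=sf)
    controls = de.select_control_genes(first, counts.shape[0] // 2)
    uf = de.estimate_unwanted_factors(counts, sf, controls, k=1)
    result = de.nb_wald_paired_test(counts, study.meta, sf=sf, uf=uf)
    up, down = de.call_degs(result)
    return result, up, down


def toy_de_table(rows):
    """Build a DEResult table from (gene, log2fc, padj) triples."""
    genes = [r[0] for r in rows]
    return de.DEResult(table=pd.DataFrame(
        {
            "baseMean": 100.0,
            "log2FoldChange": [r[1] for r in rows],
            "stat": 0.0,
            "pvalue": [r[2] for r in rows],
            "padj": [r[2] for r in rows],
        },
        index=genes,
    ))
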