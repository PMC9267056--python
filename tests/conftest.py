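"""Shared fixtures: one default synthetic dataset reused across the suite."""

import pytest

import methlink as ml
from methlink.config import SimConfig


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def ds(default_cfg):
    """Default synthetic dataset (the generator's study conditions)."""
    return ml.simulate_all(default_cfg)


@pytest.fixture(scope="session")
def dmc_records(ds):
    return ml.call_dmcs(ml.fit_cpg_models(ds.study))


@pytest.fixture(scope="session")
def weighted_links(ds):
    links = ml.link_cpgs(ds.study.cpgs, ds.annotation.genes, ds.annotation.eqtl, 50_000)
    return ml.assign_weights(links, ds.study.cpgs, ds.annotation.regulatory)


@pytest.fixture(scope="session")
def gene_scores(dmc_records, weighted_links, ds):
    scored = ml.score_links(dmc_records, weighted_links)
    return ml.aggregate_gene_scores(scored, all_genes=list(ds.annotation.genes.gene_id))


@pytest.fixture(scope="session")
def da_results(ds):
    return ml.test_differential_accessibility(ds.sc.accessibility, ds.sc.cells)


@pytest.fixture(scope="session")
def motif_hits(ds):
    from methlink.chromatin import scan_motifs, hit_matrix

    scan = scan_motifs(ds.sc.peaks, ds.sc.motifs, genome={ds.sc.chrom: ds.sc.genome})
    return hit_matrix(scan)
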