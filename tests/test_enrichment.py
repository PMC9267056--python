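"""GSEA and over-representation: exhaustive oracles, null behaviour, flags."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from methlink.enrichment import (
    gsea_preranked,
    overrepresentation,
    pathway_overlap,
    regulon_gsea,
)


def brute_force_es(values: dict[str, float], members: set[str], exponent: float) -> float:
    """Independent ES: full running-sum over the ranked list.

    Magnitude ties between the positive and negative extreme deviations
    resolve to the positive side (the convention the statistic documents).
    """
    genes = sorted(values, key=lambda g: (-values[g], g))
    w = {g: abs(values[g]) ** exponent if exponent else 1.0 for g in genes}
    nr = sum(w[g] for g in genes if g in members)
    n_miss = len(genes) - len(members)
    running = [0.0]
    for g in genes:
        if g in members:
            running.append(running[-1] + ((w[g] / nr) if nr > 0 else 1.0 / len(members)))
        else:
            running.append(running[-1] - 1.0 / n_miss)
    es_pos, es_neg = max(running), min(running)
    return es_neg if abs(es_neg) > abs(es_pos) else es_pos


@pytest.fixture(scope="module")
def ten_gene_ranking():
    rng = np.random.default_rng(42)
    vals = np.round(rng.normal(0, 2, 10), 3)
    return pd.Series(vals, index=[f"g{i}" for i in range(10)])


@pytest.mark.parametrize("exponent", [0.0, 1.0])
def test_es_matches_brute_force(ten_gene_ranking, exponent):
    values = ten_gene_ranking.to_dict()
    for members in [{"g0", "g3", "g7"}, {"g1", "g2", "g9"}, {"g4", "g5", "g6"}]:
        res = gsea_preranked(
            ten_gene_ranking, {"s": sorted(members)}, n_perm=120, seed=0,
            weight_exponent=exponent, min_size=1,
        )
        assert res.es.iloc[0] == pytest.approx(
            brute_force_es(values, members, exponent), rel=1e-10
        )


def test_permutation_p_matches_exhaustive_enumeration(ten_gene_ranking):
    """10-gene universe, 3-gene set: p equals the all-C(10,3) enumeration."""
    members = {"g0", "g3", "g7"}
    values = ten_gene_ranking.to_dict()
    es_obs = brute_force_es(values, members, 1.0)
    null = [
        brute_force_es(values, set(c), 1.0)
        for c in combinations(values.keys(), 3)
    ]
    same = [e for e in null if (e >= 0) == (es_obs >= 0)]
    p_exact = (1 + sum(abs(e) >= abs(es_obs) for e in same)) / (1 + len(same))

    n_perm = 200  # C(10,3)=120 <= n_perm triggers exhaustive enumeration
    res = gsea_preranked(ten_gene_ranking, {"s": sorted(members)}, n_perm=n_perm, seed=1, min_size=1)
    assert abs(res.p.iloc[0] - p_exact) <= 1.0 / (n_perm + 1)


def test_top_k_set_maximally_enriched():
    ranking = pd.Series(np.linspace(5, -5, 40), index=[f"g{i}" for i in range(40)])
    top = [f"g{i}" for i in range(5)]
    res = gsea_preranked(ranking, {"top": top}, n_perm=500, seed=2)
    assert res.es.iloc[0] > 0.9
    assert res.p.iloc[0] <= 5.0 / 500  # near the permutation floor


def test_permutation_p_floor():
    ranking = pd.Series(np.linspace(5, -5, 40), index=[f"g{i}" for i in range(40)])
    res = gsea_preranked(ranking, {"top": [f"g{i}" for i in range(5)]}, n_perm=500, seed=3)
    assert (res.p >= 1.0 / 501).all()


def test_random_set_null_p_roughly_uniform():
    rng = np.random.default_rng(4)
    pvals = []
    for trial in range(20):
        ranking = pd.Series(
            rng.normal(0, 1, 60), index=[f"g{i}" for i in range(60)]
        )
        members = list(rng.choice(ranking.index, 8, replace=False))
        res = gsea_preranked(ranking, {"s": members}, n_perm=200, seed=trial)
        pvals.append(res.p.iloc[0])
    assert 0.2 < np.mean(pvals) < 0.8


def test_exponent_zero_invariant_to_monotone_transform():
    rng = np.random.default_rng(5)
    ranking = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
    members = [f"g{i}" for i in range(0, 50, 7)]
    a = gsea_preranked(ranking, {"s": members}, n_perm=200, seed=6, weight_exponent=0.0)
    transformed = pd.Series(np.exp(ranking), index=ranking.index)  # monotone
    b = gsea_preranked(transformed, {"s": members}, n_perm=200, seed=6, weight_exponent=0.0)
    assert a.es.iloc[0] == pytest.approx(b.es.iloc[0], rel=1e-12)


def test_small_sets_skipped():
    ranking = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
    res = gsea_preranked(ranking, {"tiny": ["g0", "g1"]}, n_perm=100, seed=0, min_size=5)
    assert len(res) == 0


def test_duplicate_genes_rejected():
    ranking = pd.Series([1.0, 2.0], index=["g0", "g0"])
    with pytest.raises(ValueError, match="duplicate"):
        gsea_preranked(ranking, {"s": ["g0"]}, n_perm=100)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def test_ora_matches_exhaustive_enumeration():
    """Hypergeometric p equals counting over all C(20,4) draws."""
    universe = [f"g{i}" for i in range(20)]
    members = set(universe[:5])        # K = 5
    hits = ["g0", "g1", "g2", "g10"]   # k = 3 of n = 4
    res = overrepresentation(hits, universe, {"s": sorted(members)})

    total, at_least = 0, 0
    for draw in combinations(universe, 4):
        total += 1
        if len(set(draw) & members) >= 3:
            at_least += 1
    assert res.p.iloc[0] == pytest.approx(at_least / total, rel=1e-10)
    assert total == comb(20, 4)


def test_ora_empty_hits_all_p1():
    universe = [f"g{i}" for i in range(10)]
    res = overrepresentation([], universe, {"s": universe[:5]})
    assert (res.p == 1.0).all()


def test_ora_hits_outside_universe_rejected():
    with pytest.raises(ValueError):
        overrepresentation(["x"], ["g0"], {"s": ["g0"]})


def test_ora_recovers_planted_set(ds):
    """Synthetic DEGs are over-represented in the planted target set."""
    deg = ds.sc.deg
    hits = list(deg.loc[deg.is_deg, "gene_id"])
    universe = list(deg.gene_id)
    sets = {
        "planted": sorted(ds.truth.true_target_genes),
        "random": universe[:40],
    }
    res = overrepresentation(hits, universe, sets).set_index("set")
    assert res.loc["planted", "p"] < 1e-6
    assert res.loc["planted", "p"] < res.loc["random", "p"]


# ---------------------------------------------------------------------------
# pathway overlap
# ---------------------------------------------------------------------------

def _fake_results(names, sig):
    return pd.DataFrame({"set": names, "q": [0.001 if s else 0.5 for s in sig]})


def test_pathway_overlap_closed_form():
    """46 tested sets, 12 vs 19 significant, 10 shared: closed-form p."""
    from scipy.stats import hypergeom

    names = [f"P{i}" for i in range(46)]
    m_sig = [i < 12 for i in range(46)]                 # P0..P11
    e_sig = [2 <= i < 21 for i in range(46)]            # P2..P20 -> overlap 10
    res = pathway_overlap(_fake_results(names, m_sig), _fake_results(names, e_sig))
    assert res["n_overlap"] == 10
    assert res["p"] == pytest.approx(float(hypergeom.sf(9, 46, 12, 19)), rel=1e-12)
    assert res["p"] < 0.05


def test_pathway_overlap_identical_tables_maximal():
    names = [f"P{i}" for i in range(20)]
    sig = [i < 6 for i in range(20)]
    res = pathway_overlap(_fake_results(names, sig), _fake_results(names, sig))
    assert res["n_overlap"] == 6
    assert res["p"] == pytest.approx(1.0 / comb(20, 6), rel=1e-9)


def test_pathway_overlap_disjoint_collections_fail():
    with pytest.raises(ValueError):
        pathway_overlap(_fake_results(["A"], [True]), _fake_results(["B"], [True]))


def test_pathway_overlap_independent_rate():
    """Independent significance at rate r gives overlap ~ r^2 * universe."""
    rng = np.random.default_rng(7)
    names = [f"P{i}" for i in range(400)]
    r = 0.3
    overlaps = []
    for _ in range(30):
        m = rng.random(400) < r
        e = rng.random(400) < r
        res = pathway_overlap(_fake_results(names, m), _fake_results(names, e))
        overlaps.append(res["n_overlap"])
    assert np.mean(overlaps) == pytest.approx(r * r * 400, rel=0.15)


# ---------------------------------------------------------------------------
# regulon GSEA
# ---------------------------------------------------------------------------

def test_regulon_gsea_flags_planted(ds, gene_scores):
    """Planted regulons (hypermethylated + downregulated targets) flagged."""
    meth_rank = gene_scores.set_index("gene_id").score
    expr_rank = ds.sc.deg.set_index("gene_id").log2fc
    table = regulon_gsea(ds.sc.regulons, meth_rank, expr_rank, n_perm=1000, seed=9)
    planted = [tf for tf in list(ds.sc.regulons)[:2]]
    flagged = set(table.loc[table.hyper_down, "regulon"])
    assert set(planted) <= flagged
    others = set(table.regulon) - set(planted)
    assert not (flagged & others)


def test_negating_ranking_negates_nes():
    rng = np.random.default_rng(8)
    ranking = pd.Series(rng.normal(0, 1, 60), index=[f"g{i}" for i in range(60)])
    members = [f"g{i}" for i in range(8)]
    a = gsea_preranked(ranking, {"s": members}, n_perm=300, seed=10, weight_exponent=0.0)
    b = gsea_preranked(-ranking, {"s": members}, n_perm=300, seed=10, weight_exponent=0.0)
    assert np.sign(a.es.iloc[0]) == -np.sign(b.es.iloc[0])


def test_set_equal_to_universe_gives_zero_es():
    ranking = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
    res = gsea_preranked(ranking, {"all": list(ranking.index)}, n_perm=100, seed=0, min_size=1, max_size=100)
    assert res.es.iloc[0] == 0.0
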