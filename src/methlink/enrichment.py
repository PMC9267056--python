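"""Preranked GSEA and hypergeometric over-representation tests.

The GSEA implementation is the weighted Kolmogorov-Smirnov statistic with
weight exponent 1 (exponent 0 gives the classic unweighted KS and is
invariant to monotone transformations of the ranking). The null is a
gene-label permutation: random same-size gene sets drawn from the ranked
universe with a seeded generator. Normalisation and p-values follow the
sign-matched convention: NES = ES divided by the mean |null ES| of the same
sign, and the permutation p-value is (1 + more extreme same-sign nulls) /
(1 + same-sign nulls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _es_at_positions(pos: np.ndarray, w: np.ndarray, n_total: int, w_sum: float) -> tuple[float, int]:
    """Enrichment score from sorted hit positions in the ranked list.

    ``pos`` are 0-based positions of the set members in the ranked order,
    ``w`` their ranking weights (|r|^exponent), ``w_sum`` their total. The
    running statistic only turns at hit positions, so the extremum is at a
    hit (just after the increment) or just before one; both families of
    candidates are evaluated. Returns (ES, extremum position).
    """
    k = len(pos)
    if k == 0 or k == n_total:
        return 0.0, 0
    miss = 1.0 / (n_total - k)
    if w_sum <= 0:  # all-zero weights: hits contribute uniformly
        cum_hit = np.arange(1, k + 1) / k
    else:
        cum_hit = np.cumsum(w) / w_sum
    # the running statistic rises only at hits, so its maxima sit just after
    # a hit and its minima just before one
    after = cum_hit - miss * (pos + 1 - np.arange(1, k + 1))
    before = np.concatenate([[0.0], cum_hit[:-1]]) - miss * (pos - np.arange(k))
    i_max, i_min = int(np.argmax(after)), int(np.argmin(before))
    es_pos, es_neg = float(after[i_max]), float(before[i_min])
    if abs(es_neg) > abs(es_pos):  # magnitude ties resolve to the positive side
        return es_neg, int(pos[i_min])
    return es_pos, int(pos[i_max])


class _RankedList:
    """Precomputed ranked universe shared across sets and permutations."""

    def __init__(self, ranking: pd.Series, weight_exponent: float):
        if ranking.index.duplicated().any():
            raise ValueError("ranking contains duplicate genes")
        order = np.lexsort((ranking.index.to_numpy(), -ranking.to_numpy()))
        self.genes = ranking.index.to_numpy()[order]
        self.values = ranking.to_numpy()[order]
        self.weights = np.abs(self.values) ** weight_exponent if weight_exponent else np.ones(len(order))
        self.position = {g: i for i, g in enumerate(self.genes)}
        self.n = len(self.genes)

    def es(self, members) -> tuple[float, int]:
        pos = np.sort(np.array([self.position[g] for g in members], dtype=int))
        w = self.weights[pos]
        return _es_at_positions(pos, w, self.n, float(w.sum()))


def gsea_preranked(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA of ``sets`` against a gene -> value ranking.

    Sets are intersected with the ranked universe first; those outside
    [min_size, max_size] after intersection are skipped. Null ES
    distributions are shared between sets of equal effective size (the
    gene-label permutation null depends only on set size). When the number
    of distinct same-size gene sets C(N, size) does not exceed ``n_perm``
    the null is enumerated exhaustively instead of sampled, making the
    permutation p-value exact.
    """
    from math import comb
    from itertools import combinations

    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _RankedList(ranking, weight_exponent)
    rng = np.random.default_rng(seed)

    effective: dict[str, list[str]] = {}
    for name, members in sets.items():
        inter = [g for g in dict.fromkeys(members) if g in ranked.position]
        if min_size <= len(inter) <= max_size:
            effective[name] = inter

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({len(m) for m in effective.values()}):
        if comb(ranked.n, size) <= n_perm:
            null = np.empty(comb(ranked.n, size))
            for b, combo in enumerate(combinations(range(ranked.n), size)):
                pos = np.asarray(combo)
                w = ranked.weights[pos]
                null[b], _ = _es_at_positions(pos, w, ranked.n, float(w.sum()))
        else:
            null = np.empty(n_perm)
            for b in range(n_perm):
                pos = np.sort(rng.choice(ranked.n, size=size, replace=False))
                w = ranked.weights[pos]
                null[b], _ = _es_at_positions(pos, w, ranked.n, float(w.sum()))
        null_by_size[size] = null

    rows = []
    for name, members in effective.items():
        es, extremum = ranked.es(members)
        null = null_by_size[len(members)]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same) == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
        pos = np.sort([ranked.position[g] for g in members])
        if es >= 0:
            leading = [ranked.genes[i] for i in pos if i <= extremum]
        else:
            leading = [ranked.genes[i] for i in pos if i >= extremum]
        rows.append((name, len(members), es, nes, p, leading))

    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "leading_edge"])
    if len(out):
        out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out


def overrepresentation(
    hits, universe, sets: dict[str, list[str]], min_size: int = 1, max_size: int = 10_000
) -> pd.DataFrame:
    """Per-set hypergeometric upper-tail over-representation of ``hits``."""
    hits, universe = set(hits), set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in sets.items():
        member_set = set(members) & universe
        K = len(member_set)
        if not min_size <= K <= max_size:
            continue
        k = len(member_set & hits)
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n and K else np.nan
        rows.append((name, K, k, fold, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "n_hits", "fold_enrichment", "p"])
    if len(out):
        out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out


def pathway_overlap(
    methylation_results: pd.DataFrame,
    expression_results: pd.DataFrame,
    alpha: float = 0.05,
    sig_col: str = "q",
) -> dict:
    """Overlap of significant sets between two enrichment tables.

    Both tables must have been tested on the same collection (``set``
    column); the hypergeometric universe is the shared tested sets.
    """
    sets_m = set(methylation_results["set"])
    sets_e = set(expression_results["set"])
    common = sets_m & sets_e
    if not common:
        raise ValueError("enrichment tables share no tested sets")
    m_sig = set(methylation_results.loc[methylation_results[sig_col] < alpha, "set"]) & common
    e_sig = set(expression_results.loc[expression_results[sig_col] < alpha, "set"]) & common
    k = len(m_sig & e_sig)
    N = len(common)
    p = float(stats.hypergeom.sf(k - 1, N, len(m_sig), len(e_sig)))
    return {
        "n_universe": N,
        "n_sig_methylation": len(m_sig),
        "n_sig_expression": len(e_sig),
        "n_overlap": k,
        "overlap_sets": sorted(m_sig & e_sig),
        "p": p,
    }


def regulon_gsea(
    regulons: dict[str, list[str]],
    meth_ranking: pd.Series,
    expr_ranking: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    nes_thresh: float = 1.6,
    q_thresh: float = 0.01,
    min_size: int = 5,
    max_size: int = 500,
    weight_exponent: float = 0.0,
) -> pd.DataFrame:
    """Joint methylation/expression GSEA of regulon target sets.

    The default statistic is the classic unweighted KS (exponent 0): the
    gene-methylation score is strongly heavy-tailed, and on such rankings
    the exponent-1 permutation null saturates (every random set's weight
    mass concentrates in its top member), washing out NES. The unweighted
    statistic depends only on ranks and keeps the permutation null
    well-behaved; pass ``weight_exponent=1`` for the conventional weighting.

    Sign convention: the methylation ranking is the gene-methylation score
    (positive = hypermethylated) and the expression ranking is log2FC
    (negative = downregulated). A regulon whose targets are hypermethylated
    and downregulated therefore shows meth NES > 0 and expression NES < 0;
    ``hyper_down`` flags regulons passing |NES| > nes_thresh and q <
    q_thresh on both sides with those signs (``hyper_up`` mirrors it).
    """
    shared = set(meth_ranking.index) & set(expr_ranking.index)
    m = gsea_preranked(
        meth_ranking[meth_ranking.index.isin(shared)], regulons, n_perm, seed,
        weight_exponent=weight_exponent, min_size=min_size, max_size=max_size,
    ).set_index("set")
    e = gsea_preranked(
        expr_ranking[expr_ranking.index.isin(shared)], regulons, n_perm, seed + 1,
        weight_exponent=weight_exponent, min_size=min_size, max_size=max_size,
    ).set_index("set")
    common = m.index.intersection(e.index)
    out = pd.DataFrame(
        {
            "regulon": common,
            "meth_nes": m.nes[common].to_numpy(),
            "meth_q": m.q[common].to_numpy(),
            "expr_nes": e.nes[common].to_numpy(),
            "expr_q": e.q[common].to_numpy(),
        }
    )
    out["hyper_down"] = (
        (out.meth_nes > nes_thresh)
        & (out.meth_q < q_thresh)
        & (out.expr_nes < -nes_thresh)
        & (out.expr_q < q_thresh)
    )
    out["hyper_up"] = (
        (out.meth_nes > nes_thresh)
        & (out.meth_q < q_thresh)
        & (out.expr_nes > nes_thresh)
        & (out.expr_q < q_thresh)
    )
    return out.reset_index(drop=True)
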