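"""Regulon activity scoring and the motif-filtered TF-target network.

Regulon activity is an AUCell-style statistic: per cell, genes are ranked
by expression (ties broken by a seeded shuffle) and the activity of a
regulon is the normalised area under the recovery curve of its members
within the top fraction of that ranking, so it lies in [0, 1] and reaches 1
when the members occupy the top ranks.

The network stage takes regulons as *inputs* (their inference is upstream)
and keeps a TF -> target edge only when at least one accessibility peak
associated with the target contains the TF's binding motif. Retained edges
are annotated with the epigenetic state of their supporting peaks (DMC
containment, differential accessibility) and nodes carry the
gene-methylation score and DEG status.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# AUCell-style activity
# ---------------------------------------------------------------------------

def score_regulon_activity(
    expression: pd.DataFrame,
    regulons: dict[str, list[str]],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell recovery-curve AUC of each regulon within the top ranking.

    Parameters
    ----------
    expression : gene x cell matrix of counts (or any monotone expression
        measure).
    regulons : TF -> target gene list.
    top_frac : fraction of the ranking treated as "expressed" (the AUC
        integration window).

    Returns a cell x regulon activity matrix in [0, 1]. A regulon with no
    member in the expression matrix scores 0 everywhere.
    """
    if not 0 < top_frac <= 0.5:
        raise ValueError("top_frac must lie in (0, 0.5]")
    genes = expression.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    G, C = expression.shape
    k = max(1, int(np.ceil(top_frac * G)))
    rng = np.random.default_rng(seed)

    member_idx = {
        tf: np.array([gene_pos[g] for g in targets if g in gene_pos], dtype=int)
        for tf, targets in regulons.items()
    }

    X = expression.to_numpy()
    out = np.zeros((C, len(regulons)))
    tf_names = list(regulons)
    for c in range(C):
        tie_break = rng.permutation(G)
        order = np.lexsort((tie_break, -X[:, c]))  # descending expression
        rank_of_gene = np.empty(G, dtype=int)
        rank_of_gene[order] = np.arange(G)
        for j, tf in enumerate(tf_names):
            idx = member_idx[tf]
            if idx.size == 0:
                continue
            ranks = rank_of_gene[idx]
            in_top = ranks[ranks < k]
            m = idx.size
            # area under the step recovery curve over the first k ranks,
            # normalised by its maximum (all members at the very top)
            raw = float(np.sum(k - in_top))
            mm = min(m, k)
            max_area = mm * k - mm * (mm - 1) / 2
            out[c, j] = raw / max_area if max_area > 0 else 0.0
    return pd.DataFrame(out, index=expression.columns, columns=tf_names)


def expected_uniform_activity(n_members: int, n_genes: int, top_frac: float) -> float:
    """Closed-form expected activity when members are uniformly placed.

    E[hits above rank i] = m * i / G, so the expected raw area is
    m/G * sum_{i=1..k} i; dividing by the maximal area gives the expectation
    used as the null reference in calibration tests.
    """
    G, m = n_genes, n_members
    k = max(1, int(np.ceil(top_frac * G)))
    raw = m / G * k * (k + 1) / 2
    mm = min(m, k)
    max_area = mm * k - mm * (mm - 1) / 2
    return raw / max_area


def test_differential_activity(
    activity: pd.DataFrame,
    groups: pd.Series,
    q_thresh: float = 0.001,
    fc_thresh: float = 0.10,
) -> pd.DataFrame:
    """Rank-sum test of per-cell regulon activity between groups.

    ``fold_change`` is the relative change of mean activity,
    mean(LGA)/mean(CTRL) - 1; a regulon is flagged when q < q_thresh and
    |fold_change| > fc_thresh. A zero-mean control group leaves the fold
    undefined (NaN) and the regulon unflagged but marked.
    """
    groups = groups.reindex(activity.index)
    counts = groups.value_counts()
    if counts.get("CTRL", 0) < 20 or counts.get("LGA", 0) < 20:
        raise ValueError("need >= 20 cells per group")
    is_lga = (groups == "LGA").to_numpy()
    rows = []
    for reg in activity.columns:
        a = activity[reg].to_numpy()
        ctrl_mean, lga_mean = a[~is_lga].mean(), a[is_lga].mean()
        if np.all(a[~is_lga] == a[~is_lga][0]) and np.all(a[is_lga] == a[is_lga][0]) and ctrl_mean == lga_mean:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a[is_lga], a[~is_lga], alternative="two-sided").pvalue)
        fc = lga_mean / ctrl_mean - 1 if ctrl_mean > 0 else np.nan
        rows.append((reg, ctrl_mean, lga_mean, fc, p))
    out = pd.DataFrame(rows, columns=["regulon", "mean_ctrl", "mean_lga", "fold_change", "p"])
    out["q"] = multipletests(out.p, method="fdr_bh")[1]
    out["fold_undefined"] = out.fold_change.isna()
    out["flagged"] = (out.q < q_thresh) & (out.fold_change.abs() > fc_thresh) & ~out.fold_undefined
    return out


test_differential_activity.__test__ = False  # not a pytest test


# ---------------------------------------------------------------------------
# peak-gene association + network assembly
# ---------------------------------------------------------------------------

def associate_peaks_to_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 50_000
) -> dict[str, list[str]]:
    """gene -> peaks overlapping its promoter or within window of its TSS."""
    out: dict[str, list[str]] = {}
    for chrom, ge in genes.groupby("chrom", sort=False):
        pk = peaks[peaks.chrom == chrom]
        if not len(pk):
            continue
        ps, pe, pid = pk.start.to_numpy(), pk.end.to_numpy(), pk.peak_id.to_numpy()
        for _, g in ge.iterrows():
            overlap = (ps < g.promoter_end) & (pe > g.promoter_start)
            near = (ps < g.tss + window_bp) & (pe > g.tss - window_bp)
            sel = pid[overlap | near]
            if len(sel):
                out[g.gene_id] = list(sel)
    return out


def build_network(
    regulons: dict[str, list[str]],
    motif_hits: pd.DataFrame,
    peak_gene_map: dict[str, list[str]],
    peak_annotation: pd.DataFrame | None = None,
    da_results: pd.DataFrame | None = None,
    gene_scores: pd.DataFrame | None = None,
    deg_table: pd.DataFrame | None = None,
    tf_whitelist: list[str] | None = None,
    min_degree: int = 0,
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Assemble the motif-filtered TF-target network.

    Parameters
    ----------
    motif_hits : peak x motif boolean matrix (motif columns named by TF).
    peak_annotation : optional table with ``peak_id`` and ``contains_dmc``.
    da_results : optional differential-accessibility table with ``peak_id``
        and ``direction``.
    tf_whitelist : TFs to include (default: all regulon TFs).
    min_degree : drop nodes below this total degree from the returned graph
        (a presentation option, off by default).

    Returns the annotated directed graph and a per-TF concordance table
    (fraction of regulon targets supported by a motif-bearing peak).
    """
    tfs = list(tf_whitelist) if tf_whitelist is not None else list(regulons)
    dmc_by_peak = (
        peak_annotation.set_index("peak_id").contains_dmc.to_dict() if peak_annotation is not None else {}
    )
    dir_by_peak = (
        da_results.set_index("peak_id").direction.to_dict() if da_results is not None else {}
    )
    score_by_gene = (
        gene_scores.set_index("gene_id").score.to_dict() if gene_scores is not None else {}
    )
    deg_by_gene: dict[str, bool] = {}
    if deg_table is not None:
        deg_by_gene = deg_table.set_index("gene_id").is_deg.astype(bool).to_dict()

    graph = nx.DiGraph()
    conc_rows = []
    for tf in tfs:
        if tf not in regulons:
            raise KeyError(f"TF {tf!r} has no regulon")
        if tf not in motif_hits.columns:
            logger.error("TF %s has no motif in the library: all %d edges dropped", tf, len(regulons[tf]))
            conc_rows.append((tf, len(regulons[tf]), 0, 0.0))
            continue
        hit_peaks = set(motif_hits.index[motif_hits[tf].astype(bool)])
        n_kept = 0
        for target in regulons[tf]:
            supporting = [p for p in peak_gene_map.get(target, []) if p in hit_peaks]
            if not supporting:
                continue
            n_kept += 1
            _ensure_node(graph, tf, score_by_gene, deg_by_gene, is_tf=True)
            _ensure_node(graph, target, score_by_gene, deg_by_gene)
            graph.add_edge(
                tf,
                target,
                motif_in_peak=True,
                peak_has_dmc=bool(any(dmc_by_peak.get(p, False) for p in supporting)),
                peak_differentially_accessible=bool(
                    any(dir_by_peak.get(p, "ns") != "ns" for p in supporting)
                ),
                n_supporting_peaks=len(supporting),
            )
        n_total = len(regulons[tf])
        conc_rows.append((tf, n_total, n_kept, n_kept / n_total if n_total else np.nan))

    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree(node)
    if min_degree > 0:
        drop = [n for n in graph.nodes if graph.degree(n) < min_degree]
        graph.remove_nodes_from(drop)

    concordance = pd.DataFrame(conc_rows, columns=["tf", "n_targets", "n_supported", "concordance"])
    # stored as a JSON string so the graph stays GraphML-serialisable
    graph.graph["concordance"] = json.dumps(
        {r.tf: r.concordance for r in concordance.itertuples()}, sort_keys=True
    )
    return graph, concordance


def _ensure_node(graph: nx.DiGraph, gene: str, scores: dict, degs: dict, is_tf: bool = False) -> None:
    if gene in graph:
        if is_tf:
            graph.nodes[gene]["is_tf"] = True
        return
    graph.add_node(
        gene,
        gene_methylation_score=float(scores.get(gene, 0.0)),
        is_deg=bool(degs.get(gene, False)),
        is_tf=is_tf,
    )


def network_tables(graph: nx.DiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of an assembled network (for TSV export)."""
    nodes = pd.DataFrame(
        [{"gene_id": n, **attrs} for n, attrs in graph.nodes(data=True)]
    ).sort_values("gene_id", ignore_index=True) if graph.number_of_nodes() else pd.DataFrame(
        columns=["gene_id", "gene_methylation_score", "is_deg", "is_tf", "degree"]
    )
    edges = pd.DataFrame(
        [{"tf": u, "target": v, **attrs} for u, v, attrs in graph.edges(data=True)]
    ).sort_values(["tf", "target"], ignore_index=True) if graph.number_of_edges() else pd.DataFrame(
        columns=["tf", "target", "motif_in_peak", "peak_has_dmc", "peak_differentially_accessible", "n_supporting_peaks"]
    )
    return nodes, edges
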