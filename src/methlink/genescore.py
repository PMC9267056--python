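"""Per-link CpG scores and the dampened per-gene methylation score.

Each CpG-gene link is scored as

    CpGScore = (-log10(p_cpg) * meth_change) * LinkWeight * RegWeight

with ``p_cpg`` the nominal differential-methylation p-value and
``meth_change`` the LGA-minus-CTRL methylation difference in percentage
points, so the sign of the score carries the direction of the change.

Scores are then aggregated per gene separately over two compartments -
links whose CpG lies in that gene's promoter, and all other links - using a
dampening weight that removes the arbitrary influence of the number of CpGs
linked to a gene:

    W_c   = 1 / ( sum_i 1/|CpGScore_i| + k )      (k = 13.8 by default)
    score = W_c_promoter * sum(CpGScore)_promoter
          + W_c_other    * sum(CpGScore)_other

Zero scores are skipped in the harmonic term (a zero-score link contributes
nothing and must not annihilate the weight) and absolute values are used so
that mixed-sign genes keep a well-defined positive dampening weight.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_K_DAMP = 13.8


def score_links(dmc_records: pd.DataFrame, links: pd.DataFrame) -> pd.DataFrame:
    """Compute the per-link CpGScore.

    ``links`` must already carry ``link_weight`` and ``reg_weight``; every
    linked CpG must have a row in ``dmc_records``. p-values of exactly 0 are
    clamped to the smallest positive float (and logged).
    """
    rec = dmc_records.set_index("cpg_id")
    missing = set(links.cpg_id) - set(rec.index)
    if missing:
        raise KeyError(f"{len(missing)} linked CpGs lack differential-methylation records")
    out = links.copy()
    p = rec.p.reindex(out.cpg_id).to_numpy(dtype=float)
    if (p <= 0).any():
        logger.warning("%d p-values <= 0 clamped before log10", int((p <= 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, None)
    change = rec.meth_change.reindex(out.cpg_id).to_numpy(dtype=float)
    out["p"] = p
    out["meth_change"] = change
    out["cpg_score"] = (-np.log10(p)) * change * out.link_weight.to_numpy() * out.reg_weight.to_numpy()
    return out


def _dampened_component(scores: np.ndarray, k_damp: float) -> float:
    nz = scores[scores != 0]
    if nz.size == 0:
        return 0.0
    w = 1.0 / (np.sum(1.0 / np.abs(nz)) + k_damp)
    return float(w * nz.sum())


def aggregate_gene_scores(
    scored_links: pd.DataFrame,
    k_damp: float = DEFAULT_K_DAMP,
    all_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate CpGScores to one score per gene (promoter + distal parts).

    Genes listed in ``all_genes`` but carrying no link get a score of 0.
    """
    if k_damp <= 0:
        raise ValueError("k_damp must be positive")
    rows = []
    for gene, sub in scored_links.groupby("gene_id", sort=True):
        prom = sub.loc[sub.in_promoter, "cpg_score"].to_numpy()
        dist = sub.loc[~sub.in_promoter, "cpg_score"].to_numpy()
        pc = _dampened_component(prom, k_damp)
        dc = _dampened_component(dist, k_damp)
        rows.append((gene, pc + dc, pc, dc, len(prom), len(dist)))
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "score",
            "promoter_component",
            "distal_component",
            "n_cpg_promoter",
            "n_cpg_distal",
        ],
    )
    if all_genes is not None:
        missing = sorted(set(all_genes) - set(out.gene_id))
        if missing:
            pad = pd.DataFrame(
                {
                    "gene_id": missing,
                    "score": 0.0,
                    "promoter_component": 0.0,
                    "distal_component": 0.0,
                    "n_cpg_promoter": 0,
                    "n_cpg_distal": 0,
                }
            )
            out = pd.concat([out, pad], ignore_index=True).sort_values("gene_id", ignore_index=True)
    return out


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank-sum identity (probability a positive outranks a negative)."""
    pos, neg = values[labels], values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    r = stats.rankdata(np.concatenate([pos, neg]))
    u = r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _mw_abs_z(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """|z| and two-sided p of the Mann-Whitney test for labels on values."""
    pos, neg = values[labels], values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    mu = len(pos) * len(neg) / 2
    # normal approximation with tie correction via scipy's p-value
    z = stats.norm.isf(res.pvalue / 2) if res.pvalue > 0 else np.inf
    return float(z if res.statistic >= mu else z), float(res.pvalue)


def validate_score(
    scores: pd.DataFrame,
    dmc_records: pd.DataFrame,
    links: pd.DataFrame,
    deg_table: pd.DataFrame,
    true_target_genes: set[str] | None = None,
) -> dict:
    """Sanity panel for the gene-methylation score.

    Reports (a) rank correlations of the score with per-gene DMC count,
    closest linked-CpG distance, and promoter/enhancer context, and (b) the
    DEG-vs-non-DEG rank-test statistic of the score compared with single
    metrics (best per-gene -log10 p, best per-gene |meth change|). When
    planted target genes are supplied, the score's AUROC for recovering them
    is included.
    """
    rec = dmc_records.set_index("cpg_id")[["p", "meth_change"]].copy()
    rec["is_dmc"] = (
        dmc_records.set_index("cpg_id")["is_dmc"] if "is_dmc" in dmc_records.columns else False
    )
    merged = links.merge(rec, left_on="cpg_id", right_index=True, how="left")
    per_gene = merged.groupby("gene_id").agg(
        n_dmc=("is_dmc", lambda s: int(s.fillna(False).sum())),
        min_abs_dist=("distance_bp", lambda s: float(np.min(np.abs(s)))),
        any_promoter=("in_promoter", "any"),
        best_neglogp=("p", lambda s: float(-np.log10(np.clip(s.min(), np.finfo(float).tiny, None)))),
        best_change=("meth_change", lambda s: float(s.loc[s.abs().idxmax()])),
    )
    tab = scores.set_index("gene_id").join(per_gene, how="left")
    tab["abs_score"] = tab.score.abs()

    report: dict = {"associations": {}}
    ok = tab.n_dmc.notna()
    if ok.sum() >= 3:
        report["associations"]["score_vs_n_dmc_spearman"] = float(
            stats.spearmanr(tab.abs_score[ok], tab.n_dmc[ok]).statistic
        )
        report["associations"]["score_vs_min_distance_spearman"] = float(
            stats.spearmanr(tab.abs_score[ok], tab.min_abs_dist[ok]).statistic
        )
        prom = tab.any_promoter[ok].astype(bool).to_numpy()
        report["associations"]["score_promoter_auroc"] = _rank_auc(
            tab.abs_score[ok].to_numpy(), prom
        )

    deg = deg_table.set_index("gene_id")
    is_deg = deg.is_deg.reindex(tab.index).fillna(False).astype(bool).to_numpy()
    report["n_deg"] = int(is_deg.sum())
    report["underpowered"] = bool(is_deg.sum() < 10)

    metrics = {
        "gene_score": tab.abs_score.to_numpy(),
        "neglogp_alone": tab.best_neglogp.fillna(0).to_numpy(),
        "meth_change_alone": np.abs(tab.best_change.fillna(0).to_numpy()),
    }
    report["deg_rank_tests"] = {}
    for name, vals in metrics.items():
        z, p = _mw_abs_z(vals, is_deg)
        report["deg_rank_tests"][name] = {"abs_z": z, "p": p}

    if true_target_genes is not None:
        labels = tab.index.isin(true_target_genes)
        report["target_gene_auroc"] = _rank_auc(tab.abs_score.to_numpy(), labels)
    return report
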