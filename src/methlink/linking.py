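"""CpG-to-gene association with confidence and regulatory weights.

A CpG is associated with a gene either because it lies within a distance
window of the gene's TSS or because it falls in an eQTL region assigned to
that gene (eQTL links deliberately bypass the distance window: that is what
makes them informative). Duplicated pairs are merged with ``source="both"``.

Each link then receives:

* ``LinkWeight`` - confidence in the CpG-gene association: exponential decay
  in |distance to TSS| with a configurable half-life (floored), while
  eQTL-supported links get a constant weight; ``both`` takes the maximum;
* ``RegWeight`` - the estimated regulatory influence of the CpG's genomic
  context, looked up from cell-type-specific promoter/enhancer intervals
  with an optional second (Ensembl-regulatory-style) interval table
  consulted when the cell-specific class is "other".

The functional forms and weight values are explicit, overridable defaults:
distance half-life 10 kb with floor 0.1, eQTL weight 1.0, and class weights
promoter 1.0 / enhancer 0.75 / other 0.25.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import DEFAULT_REG_WEIGHTS

logger = logging.getLogger(__name__)

_CLASS_RANK = {"promoter": 0, "enhancer": 1, "other": 2}


def link_cpgs(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    eqtl: pd.DataFrame | None = None,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Build the CpG-gene link set from distance and eQTL evidence.

    Parameters
    ----------
    cpgs : table with ``cpg_id, chrom, pos``.
    genes : table with ``gene_id, chrom, tss, strand, promoter_start,
        promoter_end``.
    eqtl : optional table with ``chrom, start, end, gene_id`` (0-based
        half-open regions).
    window_bp : distance-link window around the TSS.

    Returns one row per (cpg, gene) pair with ``source`` in
    {distance, eqtl, both}, strand-aware signed ``distance_bp`` (upstream of
    the TSS is negative), and ``in_promoter`` (CpG inside that gene's
    promoter interval).
    """
    pairs: list[tuple[str, int]] = []  # (cpg row index, gene row index, source)
    rows = []

    gene_chroms = set(genes.chrom.unique())
    for chrom, cp in cpgs.groupby("chrom", sort=False):
        if chrom not in gene_chroms:
            logger.warning("CpGs on %s skipped: chromosome absent from gene annotation", chrom)
            continue
        ge = genes[genes.chrom == chrom].sort_values("tss")
        tss = ge.tss.to_numpy()
        gidx = ge.index.to_numpy()
        pos = cp.pos.to_numpy()
        lo = np.searchsorted(tss, pos - window_bp, side="left")
        hi = np.searchsorted(tss, pos + window_bp, side="right")
        for ci, l, h in zip(cp.index.to_numpy(), lo, hi):
            for gi in gidx[l:h]:
                rows.append((ci, gi, "distance"))

    if eqtl is not None and len(eqtl):
        trees: dict[str, IntervalTree] = {}
        for chrom, eq in eqtl.groupby("chrom", sort=False):
            t = IntervalTree()
            for ri, r in eq.iterrows():
                t[int(r.start) : int(r.end)] = r.gene_id
            trees[chrom] = t
        gene_row = {g: i for i, g in zip(genes.index, genes.gene_id)}
        for chrom, cp in cpgs.groupby("chrom", sort=False):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for ci, p in zip(cp.index.to_numpy(), cp.pos.to_numpy()):
                for iv in tree[int(p)]:
                    gi = gene_row.get(iv.data)
                    if gi is None:
                        raise ValueError(f"eQTL gene {iv.data!r} absent from gene annotation")
                    rows.append((ci, gi, "eqtl"))

    if not rows:
        return pd.DataFrame(
            columns=["cpg_id", "gene_id", "source", "distance_bp", "in_promoter"]
        )

    df = pd.DataFrame(rows, columns=["ci", "gi", "source"])
    # merge duplicate (cpg, gene) pairs; mixed evidence becomes "both"
    src = (
        df.groupby(["ci", "gi"])["source"]
        .agg(lambda s: s.iloc[0] if s.nunique() == 1 else "both")
        .reset_index()
    )
    cpg_pos = cpgs.pos
    cpg_ids = cpgs.cpg_id
    g_tss, g_strand = genes.tss, genes.strand
    g_ps, g_pe, g_ids = genes.promoter_start, genes.promoter_end, genes.gene_id

    pos = cpg_pos.loc[src.ci].to_numpy()
    tss = g_tss.loc[src.gi].to_numpy()
    strand = g_strand.loc[src.gi].to_numpy()
    dist = np.where(strand == "+", pos - tss, tss - pos)
    in_prom = (pos >= g_ps.loc[src.gi].to_numpy()) & (pos < g_pe.loc[src.gi].to_numpy())

    return pd.DataFrame(
        {
            "cpg_id": cpg_ids.loc[src.ci].to_numpy(),
            "gene_id": g_ids.loc[src.gi].to_numpy(),
            "source": src.source.to_numpy(),
            "distance_bp": dist.astype(int),
            "in_promoter": in_prom,
        }
    ).sort_values(["cpg_id", "gene_id"], ignore_index=True)


def regulatory_class_at(
    positions: pd.DataFrame, regset: pd.DataFrame, fallback: pd.DataFrame | None = None
) -> np.ndarray:
    """Class ("promoter"/"enhancer"/"other") at each ``chrom, pos`` row.

    When intervals of different classes overlap a position, promoter wins
    over enhancer. Positions covered by nothing are "other"; if a
    ``fallback`` interval table (e.g. an Ensembl-regulatory-style build) is
    supplied, it is consulted for those positions before defaulting.
    """
    def build(reg: pd.DataFrame) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in reg.groupby("chrom", sort=False):
            t = IntervalTree()
            for _, r in sub.iterrows():
                if int(r.end) <= int(r.start):
                    raise ValueError(f"zero-length regulatory interval at {chrom}:{r.start}")
                t[int(r.start) : int(r.end)] = r.reg_class
            trees[chrom] = t
        return trees

    primary = build(regset)
    secondary = build(fallback) if fallback is not None else {}

    out = np.empty(len(positions), dtype=object)
    for k, (chrom, p) in enumerate(zip(positions.chrom.to_numpy(), positions.pos.to_numpy())):
        hits = primary.get(chrom, IntervalTree())[int(p)]
        classes = {iv.data for iv in hits}
        if not classes and secondary:
            classes = {iv.data for iv in secondary.get(chrom, IntervalTree())[int(p)]}
        out[k] = min(classes, key=lambda c: _CLASS_RANK.get(c, 99)) if classes else "other"
    return out


def assign_weights(
    links: pd.DataFrame,
    cpgs: pd.DataFrame,
    regset: pd.DataFrame,
    decay_halflife_bp: float = 10_000.0,
    link_floor: float = 0.1,
    eqtl_weight: float = 1.0,
    reg_weights: dict[str, float] | None = None,
    ens_regset: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach ``link_weight``, ``reg_class`` and ``reg_weight`` to each link."""
    if reg_weights is None:
        reg_weights = DEFAULT_REG_WEIGHTS
    if not reg_weights["promoter"] >= reg_weights["enhancer"] >= reg_weights["other"] > 0:
        raise ValueError("require RegWeight(promoter) >= enhancer >= other > 0")

    out = links.copy()
    decay = np.maximum(
        link_floor, np.exp(-np.log(2.0) * np.abs(out.distance_bp.to_numpy()) / decay_halflife_bp)
    )
    src = out.source.to_numpy()
    w = np.where(src == "distance", decay, np.where(src == "eqtl", eqtl_weight, np.maximum(decay, eqtl_weight)))
    out["link_weight"] = w

    cpg_pos = cpgs.set_index("cpg_id")[["chrom", "pos"]]
    per_cpg = cpg_pos.loc[out.cpg_id.unique()]
    classes = regulatory_class_at(per_cpg, regset, fallback=ens_regset)
    class_map = dict(zip(per_cpg.index, classes))
    out["reg_class"] = out.cpg_id.map(class_map)
    out["reg_weight"] = out.reg_class.map(reg_weights)
    return out
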