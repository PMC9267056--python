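"""End-to-end orchestration with a reproducible run manifest.

``run_all`` executes simulate (or load) -> differential methylation ->
linking -> gene scores -> chromatin -> enrichment -> network, writing every
stage output under the configured directory and recording a manifest with
the seed, thresholds, per-stage row counts and sha256 checksums of all
outputs. With a fixed config and seed the manifest is identical across
runs. A failing stage aborts with the stage name; files it had begun
writing are kept with a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import PipelineConfig
from .synthetic import SyntheticDataset, simulate_all, write_dataset
from .diffmeth import fit_cpg_models, call_dmcs
from .linking import link_cpgs, assign_weights
from .genescore import score_links, aggregate_gene_scores
from .chromatin import (
    annotate_peaks,
    dmc_ocr_enrichment,
    lineage_dmc_enrichment,
    test_differential_accessibility,
    motif_enrichment,
    dmc_windows,
    sample_background_windows,
    scan_motifs,
    hit_matrix,
)
from .enrichment import regulon_gsea
from .regnet import (
    score_regulon_activity,
    test_differential_activity,
    associate_peaks_to_genes,
    build_network,
    network_tables,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, dataset: SyntheticDataset | None = None) -> dict:
    """Run the whole pipeline; returns (and writes) the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "p_thresh": config.p_thresh,
            "delta_thresh": config.delta_thresh,
            "da_q_thresh": config.da_q_thresh,
            "da_lfc_thresh": config.da_lfc_thresh,
            "regulon_q_thresh": config.regulon_q_thresh,
            "regulon_fc_thresh": config.regulon_fc_thresh,
            "nes_thresh": config.nes_thresh,
            "gsea_q_thresh": config.gsea_q_thresh,
        },
        "stages": {},
    }

    state: dict = {}

    def stage(name: str, fn):
        logger.info("stage %s (seed=%d)", name, config.seed)
        written: list[Path] = []
        state["_written"] = written
        try:
            counts = fn(written)
        except Exception as exc:
            for f in written:
                if f.exists():
                    f.rename(f.with_suffix(f.suffix + ".partial"))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "row_counts": counts,
            "outputs": {f.name: _sha256(f) for f in sorted(written)},
        }

    def _write(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
        mio.write_tsv(df, path)
        written.append(path)

    # ---- stage 1: simulate or load -----------------------------------
    def s_simulate(written):
        nonlocal dataset
        if dataset is None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            dataset = simulate_all(sim_cfg)
        paths = write_dataset(dataset, out / "data")
        written.extend(Path(p) for p in paths.values())
        return {
            "n_cpg": len(dataset.study.cpgs),
            "n_gene": len(dataset.annotation.genes),
            "n_sample": len(dataset.study.samples),
            "n_cell": len(dataset.sc.cells),
            "n_peak": len(dataset.sc.peaks),
        }

    stage("simulate", s_simulate)
    ds = dataset

    # ---- stage 2: differential methylation ---------------------------
    def s_diffmeth(written):
        records = fit_cpg_models(ds.study)
        dmcs = call_dmcs(records, config.p_thresh, config.delta_thresh)
        state["dmcs"] = dmcs
        _write(dmcs, out / "dmc.tsv", written)
        return {"n_cpg": len(dmcs), "n_hyper": dmcs.attrs["n_hyper"], "n_hypo": dmcs.attrs["n_hypo"]}

    stage("diffmeth", s_diffmeth)

    # ---- stage 3: linking --------------------------------------------
    def s_link(written):
        links = link_cpgs(ds.study.cpgs, ds.annotation.genes, ds.annotation.eqtl, config.window_bp)
        links = assign_weights(
            links,
            ds.study.cpgs,
            ds.annotation.regulatory,
            decay_halflife_bp=config.decay_halflife_bp,
            link_floor=config.link_floor,
            eqtl_weight=config.eqtl_weight,
            reg_weights=config.reg_weights,
        )
        state["links"] = links
        _write(links, out / "links.tsv", written)
        n_eqtl = int((links.source != "distance").sum())
        return {"n_links": len(links), "n_with_eqtl_support": n_eqtl}

    stage("link", s_link)

    # ---- stage 4: gene scores ----------------------------------------
    def s_score(written):
        scored = score_links(state["dmcs"], state["links"])
        scores = aggregate_gene_scores(scored, config.k_damp, all_genes=list(ds.annotation.genes.gene_id))
        state["scores"] = scores
        _write(scores, out / "genescore.tsv", written)
        return {"n_genes": len(scores)}

    stage("score", s_score)

    # ---- stage 5: chromatin ------------------------------------------
    def s_chromatin(written):
        dmc_set = state["dmcs"][state["dmcs"].is_dmc]
        annotated = annotate_peaks(ds.sc.peaks, ds.study.cpgs, dmc_set)
        state["annotated_peaks"] = annotated
        _write(annotated, out / "peaks_annotated.tsv", written)

        lineage = lineage_dmc_enrichment(annotated)
        _write(lineage, out / "lineage_dmc_enrichment.tsv", written)

        ocr = dmc_ocr_enrichment(
            n_queried=len(ds.study.cpgs),
            n_queried_in_ocr=int(_in_any_peak(ds.study.cpgs, ds.sc.peaks).sum()),
            n_dmc=max(len(dmc_set), 1),
            n_dmc_in_ocr=int(_in_any_peak(dmc_set, ds.sc.peaks).sum()) if len(dmc_set) else 0,
        )
        mio.write_json(ocr, out / "dmc_ocr_enrichment.json")
        written.append(out / "dmc_ocr_enrichment.json")

        da = test_differential_accessibility(
            ds.sc.accessibility, ds.sc.cells, config.da_q_thresh, config.da_lfc_thresh
        )
        state["da"] = da
        _write(da, out / "differential_accessibility.tsv", written)

        rng = np.random.default_rng(config.seed + 11)
        targets = dmc_windows(dmc_set) if len(dmc_set) else dmc_windows(ds.study.cpgs.head(0))
        background = sample_background_windows(ds.study.cpgs, max(len(targets) * 5, 50), 20, rng)
        genome = {ds.sc.chrom: ds.sc.genome}
        if len(targets):
            motif_table = motif_enrichment(targets, background, ds.sc.motifs, genome=genome)
        else:
            motif_table = pd.DataFrame()
        _write(motif_table, out / "dmc_motif_enrichment.tsv", written)
        return {
            "n_peaks": len(annotated),
            "n_da_down": int((da.direction == "down").sum()),
            "n_da_up": int((da.direction == "up").sum()),
        }

    stage("chromatin", s_chromatin)

    # ---- stage 6: enrichment -----------------------------------------
    def s_enrichment(written):
        meth_rank = state["scores"].set_index("gene_id").score
        expr_rank = ds.sc.deg.set_index("gene_id").log2fc
        table = regulon_gsea(
            ds.sc.regulons,
            meth_rank,
            expr_rank,
            n_perm=config.gsea_n_perm,
            seed=config.seed + 21,
            nes_thresh=config.nes_thresh,
            q_thresh=config.gsea_q_thresh,
        )
        state["regulon_gsea"] = table
        _write(table, out / "regulon_gsea.tsv", written)
        return {"n_regulons": len(table), "n_hyper_down": int(table.hyper_down.sum())}

    stage("enrichment", s_enrichment)

    # ---- stage 7: network --------------------------------------------
    def s_network(written):
        activity = score_regulon_activity(
            ds.sc.expression, ds.sc.regulons, top_frac=config.aucell_top_frac, seed=config.seed + 31
        )
        diff_act = test_differential_activity(
            activity, ds.sc.cells.set_index("cell_id").group,
            q_thresh=config.regulon_q_thresh, fc_thresh=config.regulon_fc_thresh,
        )
        _write(diff_act, out / "regulon_activity_diff.tsv", written)

        scan = scan_motifs(ds.sc.peaks, ds.sc.motifs, genome={ds.sc.chrom: ds.sc.genome})
        hits = hit_matrix(scan)
        peak_map = associate_peaks_to_genes(ds.sc.peaks, ds.annotation.genes, config.window_bp)
        graph, concordance = build_network(
            ds.sc.regulons,
            hits,
            peak_map,
            peak_annotation=state["annotated_peaks"],
            da_results=state["da"],
            gene_scores=state["scores"],
            deg_table=ds.sc.deg,
        )
        nodes, edges = network_tables(graph)
        mio.write_graphml(graph, out / "network.graphml")
        written.append(out / "network.graphml")
        _write(nodes, out / "network_nodes.tsv", written)
        _write(edges, out / "network_edges.tsv", written)
        _write(concordance, out / "network_concordance.tsv", written)
        return {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_regulons_flagged": int(diff_act.flagged.sum()),
        }

    stage("network", s_network)

    mio.write_json(manifest, out / "manifest.json")
    return manifest


def _in_any_peak(sites: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean per site: falls inside at least one peak (half-open)."""
    flags = np.zeros(len(sites), dtype=bool)
    for chrom, pk in peaks.groupby("chrom", sort=False):
        sel = sites.chrom.to_numpy() == chrom
        if not sel.any():
            continue
        pos = sites.pos.to_numpy()[sel]
        starts = np.sort(pk.start.to_numpy())
        ends = pk.end.to_numpy()[np.argsort(pk.start.to_numpy())]
        # peaks may overlap; check each site against candidate peaks by start
        inside = np.zeros(len(pos), dtype=bool)
        for s, e in zip(starts, ends):
            inside |= (pos >= s) & (pos < e)
        flags[sel] = inside
    return flags
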