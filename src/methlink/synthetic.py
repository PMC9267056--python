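"""Synthetic multi-omic data with planted ground truth.

The generator emulates the data layout of a neonatal HSPC programming study:
per-CpG methylation fractions for a CTRL/LGA contrast with clinical
covariates, a gene annotation with promoters and distal enhancers on one
synthetic chromosome, an eQTL link table, lineage-labelled accessibility
peaks with per-cell binary counts, PWMs with planted motif occurrences,
TF regulons, and a per-cell expression matrix with planted downregulation.

Every planted effect is recorded in a :class:`GroundTruth` object so each
downstream stage (differential methylation, gene scoring, differential
accessibility, motif scanning, network filtering) has a parameter-recovery
test surface.

Methylation is simulated on the logit (latent) scale: per-CpG baseline plus
additive covariate effects, a group shift for planted CpGs, and Gaussian
noise, then squashed through the logistic function. This keeps covariate
effects additive on a well-defined scale so the downstream linear model is
approximately well-specified, while fractions stay in [0, 1] by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .config import SimConfig
from . import io as mio

CHROM = "chrS"
GENE_SPACING = 30_000  # bp between consecutive TSSs on the synthetic chromosome
PROMOTER_UP = 1_500
PROMOTER_DOWN = 500
ENHANCER_LEN = 600
PEAK_HALF_WIDTH = 400
REGULON_SIZE = 12
MOTIF_LEN = 12  # long enough that chance consensus hits in random sequence are negligible

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """Gene/regulatory/eQTL annotation on one synthetic chromosome."""

    genes: pd.DataFrame          # gene_id, chrom, tss, strand, promoter_start, promoter_end
    regulatory: pd.DataFrame     # chrom, start, end, reg_class in {promoter, enhancer}
    eqtl: pd.DataFrame           # chrom, start, end, gene_id
    chrom: str = CHROM
    chrom_len: int = 0

    def __iter__(self):  # allow (genes, reg, eqtl) unpacking
        return iter((self.genes, self.regulatory, self.eqtl))


@dataclass
class MethylationStudy:
    """CpG-by-sample methylation fractions plus the sample sheet."""

    cpgs: pd.DataFrame           # cpg_id, chrom, pos
    meth: pd.DataFrame           # fractions in [0,1]; index cpg_id, columns sample_id
    samples: pd.DataFrame        # sample_id, group, age, sex, ethnicity, batch, complexity


@dataclass
class GroundTruth:
    """Identifiers of all planted effects."""

    true_dmc_ids: set[str] = field(default_factory=set)
    true_target_genes: set[str] = field(default_factory=set)
    true_da_peaks: set[str] = field(default_factory=set)
    true_downregulated: set[str] = field(default_factory=set)
    planted_motif_sites: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "true_dmc_ids": sorted(self.true_dmc_ids),
            "true_target_genes": sorted(self.true_target_genes),
            "true_da_peaks": sorted(self.true_da_peaks),
            "true_downregulated": sorted(self.true_downregulated),
            "planted_motif_sites": self.planted_motif_sites,
        }


@dataclass
class SingleCellData:
    """Chromatin accessibility, expression, regulons and motif layer."""

    peaks: pd.DataFrame          # peak_id, chrom, start, end, lineage
    cells: pd.DataFrame          # cell_id, group, total_fragments
    accessibility: pd.DataFrame  # binary, index cell_id, columns peak_id
    expression: pd.DataFrame     # counts, index gene_id, columns cell_id
    regulons: dict[str, list[str]]
    motifs: list
    deg: pd.DataFrame            # gene_id, log2fc, p, q, is_deg
    genome: str
    chrom: str = CHROM


@dataclass
class SyntheticDataset:
    config: SimConfig
    annotation: Annotation
    study: MethylationStudy
    truth: GroundTruth
    sc: SingleCellData


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Genes with TSS/strand/promoter, distal enhancers, and eQTL regions.

    eQTL regions tile the chromosome so that they cover approximately
    ``cfg.eqtl_frac`` of it; most are assigned to the nearest gene but a
    fraction point at a random (typically distant) gene, so eQTL-only
    CpG-gene links exist beyond any distance window.
    """
    rng = _rng(cfg, 1)
    n = cfg.n_gene
    chrom_len = (n + 2) * GENE_SPACING

    tss = (np.arange(1, n + 1) * GENE_SPACING + rng.integers(-2000, 2001, size=n)).astype(int)
    strand = rng.choice(["+", "-"], size=n)
    prom_start = np.where(strand == "+", tss - PROMOTER_UP, tss - PROMOTER_DOWN)
    prom_end = np.where(strand == "+", tss + PROMOTER_DOWN, tss + PROMOTER_UP)
    prom_start = np.clip(prom_start, 0, chrom_len - 1)
    prom_end = np.clip(prom_end, 1, chrom_len)

    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n)],
            "chrom": CHROM,
            "tss": tss,
            "strand": strand,
            "promoter_start": prom_start,
            "promoter_end": prom_end,
        }
    )

    reg_rows = [(CHROM, s, e, "promoter") for s, e in zip(prom_start, prom_end)]
    has_enh = rng.random(n) < 0.7
    enh_side = rng.choice([-1, 1], size=n)
    enh_dist = rng.integers(5_000, 30_000, size=n)
    for i in range(n):
        if not has_enh[i]:
            continue
        start = int(tss[i] + enh_side[i] * enh_dist[i])
        start = min(max(start, 0), chrom_len - ENHANCER_LEN)
        reg_rows.append((CHROM, start, start + ENHANCER_LEN, "enhancer"))
    regulatory = pd.DataFrame(reg_rows, columns=["chrom", "start", "end", "reg_class"])

    # eQTL slots: one region per slot, width = eqtl_frac * slot, so the total
    # covered fraction of the chromosome is ~eqtl_frac without self-overlap.
    n_slots = max(1, chrom_len // 6_000)
    slot = chrom_len / n_slots
    width = max(1, int(round(cfg.eqtl_frac * slot)))
    eqtl_rows = []
    far = rng.random(n_slots) < 0.3
    rand_gene = rng.integers(0, n, size=n_slots)
    for j in range(n_slots):
        start = int(j * slot + rng.integers(0, max(1, int(slot) - width)))
        end = min(start + width, chrom_len)
        if end <= start:
            continue
        mid = (start + end) // 2
        gi = int(rand_gene[j]) if far[j] else int(np.argmin(np.abs(tss - mid)))
        eqtl_rows.append((CHROM, start, end, genes.gene_id.iloc[gi]))
    eqtl = pd.DataFrame(eqtl_rows, columns=["chrom", "start", "end", "gene_id"])

    return Annotation(genes=genes, regulatory=regulatory, eqtl=eqtl, chrom=CHROM, chrom_len=chrom_len)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(cfg: SimConfig, annot: Annotation) -> tuple[MethylationStudy, GroundTruth]:
    """Per-CpG methylation fractions for two groups with planted hypermethylation.

    Planted CpGs are preferentially located in promoter/enhancer intervals of
    the planted target genes, and their latent-scale shift is calibrated so
    the expected group difference equals ``cfg.delta_meth`` percentage points
    at the baseline methylation level.
    """
    rng = _rng(cfg, 2)
    n_eff = int(round(cfg.effect_frac * cfg.n_cpg))
    truth = GroundTruth()
    if cfg.effect_frac > 0 and cfg.effect_frac * cfg.n_cpg < 1:
        warnings.warn("effect_frac * n_cpg < 1: no CpG carries an effect; ground truth is empty")
        n_eff = 0

    n_target = max(1, int(round(cfg.target_gene_frac * cfg.n_gene)))
    target_idx = rng.choice(cfg.n_gene, size=n_target, replace=False)
    target_genes = set(annot.genes.gene_id.iloc[sorted(target_idx)])
    truth.true_target_genes = target_genes

    # intervals eligible to receive planted CpGs: promoters + enhancers of targets
    tgt = annot.genes[annot.genes.gene_id.isin(target_genes)]
    intervals = [(int(s), int(e)) for s, e in zip(tgt.promoter_start, tgt.promoter_end)]
    enh = annot.regulatory[annot.regulatory.reg_class == "enhancer"]
    for _, g in tgt.iterrows():
        near = enh[(enh.start - g.tss).abs() < 35_000]
        intervals.extend((int(s), int(e)) for s, e in zip(near.start, near.end))

    pos_planted = []
    if n_eff:
        n_in = int(round(0.85 * n_eff))
        picks = rng.integers(0, len(intervals), size=n_in)
        for k in picks:
            s, e = intervals[k]
            pos_planted.append(int(rng.integers(s, e)))
        pos_planted.extend(int(p) for p in rng.integers(0, annot.chrom_len, size=n_eff - n_in))
    pos_bg = rng.integers(0, annot.chrom_len, size=cfg.n_cpg - n_eff)

    pos = np.concatenate([np.array(pos_planted, dtype=int), pos_bg]).astype(int)
    planted = np.zeros(cfg.n_cpg, dtype=bool)
    planted[: n_eff] = True
    order = np.argsort(pos, kind="stable")
    pos, planted = pos[order], planted[order]
    cpg_ids = np.array([f"cpg{i:06d}" for i in range(cfg.n_cpg)])
    truth.true_dmc_ids = set(cpg_ids[planted])
    cpgs = pd.DataFrame({"cpg_id": cpg_ids, "chrom": CHROM, "pos": pos})

    # sample sheet: balanced groups, randomized covariates; library complexity
    # correlated with batch to exercise confounder adjustment downstream
    n_s = 2 * cfg.n_sample_per_group
    group = np.array(["CTRL"] * cfg.n_sample_per_group + ["LGA"] * cfg.n_sample_per_group)
    batch = rng.choice(["B1", "B2"], size=n_s)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_s)],
            "group": group,
            "age": np.round(rng.normal(30, 4, size=n_s), 1),
            "sex": rng.choice(["F", "M"], size=n_s),
            "ethnicity": rng.choice(["E1", "E2", "E3"], size=n_s),
            "batch": batch,
            "complexity": np.round(rng.normal(0, 0.5, size=n_s) + 0.6 * (batch == "B2"), 3),
        }
    )

    m0 = np.where(planted, rng.uniform(0.25, 0.45, size=cfg.n_cpg), rng.uniform(0.05, 0.95, size=cfg.n_cpg))
    base = logit(m0)
    # planted strong effect plus a weak global hypermethylation bias on all
    # CpGs; both expressed in percentage points at each CpG's baseline level
    bias_pp = (
        rng.exponential(cfg.global_bias_frac * abs(cfg.delta_meth), size=cfg.n_cpg)
        if cfg.delta_meth != 0 and cfg.global_bias_frac > 0
        else np.zeros(cfg.n_cpg)
    )
    delta_pp = np.where(planted, cfg.delta_meth, 0.0) + bias_pp
    shift = np.clip(m0 + delta_pp / 100.0, 1e-4, 1 - 1e-4)
    delta_latent = logit(shift) - base

    cov = (
        0.01 * (samples.age.to_numpy() - 30)
        + 0.08 * (samples.sex.to_numpy() == "M")
        + 0.05 * (samples.ethnicity.to_numpy() == "E2")
        - 0.05 * (samples.ethnicity.to_numpy() == "E3")
        + 0.10 * (samples.batch.to_numpy() == "B2")
        + 0.10 * samples.complexity.to_numpy()
    )
    latent = base[:, None] + cov[None, :] + delta_latent[:, None] * (group == "LGA")[None, :]
    latent = latent + rng.normal(0, cfg.noise_sd, size=latent.shape)
    meth = pd.DataFrame(expit(latent), index=cpg_ids, columns=samples.sample_id)

    return MethylationStudy(cpgs=cpgs, meth=meth, samples=samples), truth


# ---------------------------------------------------------------------------
# chromatin + expression
# ---------------------------------------------------------------------------

def _make_pwm(rng: np.random.Generator) -> tuple[np.ndarray, str]:
    consensus_idx = rng.integers(0, 4, size=MOTIF_LEN)
    pwm = np.full((4, MOTIF_LEN), 0.05)
    pwm[consensus_idx, np.arange(MOTIF_LEN)] = 0.85
    return pwm, "".join(BASES[consensus_idx])


def simulate_chromatin_and_expression(
    cfg: SimConfig, annot: Annotation, truth: GroundTruth
) -> SingleCellData:
    """Peaks, per-cell binary accessibility, regulons, motifs, expression, DEGs.

    * peaks cover promoters and enhancers (target-gene peaks are labelled
      HSC so lineage enrichment is recoverable), with per-cell Bernoulli
      accessibility modulated by a cell depth factor;
    * planted differentially accessible peaks drop from
      ``cfg.da_open_prob[0]`` to ``cfg.da_open_prob[1]`` open probability in
      the LGA group;
    * each regulon TF gets a PWM whose consensus is written into one
      associated peak per target gene (recorded in the ground truth);
    * expression counts are negative binomial with planted downregulation of
      the target genes, and the DEG table is a Wilcoxon + BH summary of the
      generated counts.
    """
    from .chromatin import Motif  # deferred to avoid import cycle

    rng = _rng(cfg, 3)
    genes = annot.genes

    # ---- peaks: first over target promoters (HSC), then other promoters /
    # enhancers / random positions until n_peak
    tgt_genes = genes[genes.gene_id.isin(truth.true_target_genes)]
    centers = [int((s + e) // 2) for s, e in zip(tgt_genes.promoter_start, tgt_genes.promoter_end)]
    lineages = ["HSC"] * len(centers)

    other = genes[~genes.gene_id.isin(truth.true_target_genes)]
    pool: list[int] = [int((s + e) // 2) for s, e in zip(other.promoter_start, other.promoter_end)]
    enh = annot.regulatory[annot.regulatory.reg_class == "enhancer"]
    pool += [int((s + e) // 2) for s, e in zip(enh.start, enh.end)]
    pool_order = rng.permutation(len(pool))
    k = 0
    other_lineages = np.array(["MPP", "Myeloid", "Erythroid"])
    while len(centers) < cfg.n_peak and k < len(pool_order):
        centers.append(pool[pool_order[k]])
        lineages.append(str(other_lineages[rng.integers(0, 3)]))
        k += 1
    while len(centers) < cfg.n_peak:
        centers.append(int(rng.integers(PEAK_HALF_WIDTH, annot.chrom_len - PEAK_HALF_WIDTH)))
        lineages.append(str(other_lineages[rng.integers(0, 3)]))
    centers = centers[: cfg.n_peak]
    lineages = lineages[: cfg.n_peak]

    starts = np.clip(np.array(centers) - PEAK_HALF_WIDTH, 0, annot.chrom_len - 2 * PEAK_HALF_WIDTH)
    peaks = pd.DataFrame(
        {
            "peak_id": [f"peak{i:05d}" for i in range(cfg.n_peak)],
            "chrom": CHROM,
            "start": starts.astype(int),
            "end": (starts + 2 * PEAK_HALF_WIDTH).astype(int),
            "lineage": lineages,
        }
    )

    n_da = int(round(cfg.da_peak_frac * cfg.n_peak))
    da_idx = rng.choice(cfg.n_peak, size=n_da, replace=False)
    truth.true_da_peaks = set(peaks.peak_id.iloc[sorted(da_idx)])

    # ---- per-cell binary accessibility
    n_cells = 2 * cfg.n_cell_per_group
    cell_group = np.array(["CTRL"] * cfg.n_cell_per_group + ["LGA"] * cfg.n_cell_per_group)
    depth = rng.lognormal(mean=0.0, sigma=0.35, size=n_cells)
    base_p = rng.uniform(0.2, 0.5, size=cfg.n_peak)
    base_p[da_idx] = cfg.da_open_prob[0]
    logit_p = logit(base_p)[None, :] + np.log(depth)[:, None]
    is_lga = (cell_group == "LGA")[:, None]
    da_mask = np.zeros(cfg.n_peak, dtype=bool)
    da_mask[da_idx] = True
    delta = logit(cfg.da_open_prob[1]) - logit(cfg.da_open_prob[0])
    logit_p = logit_p + delta * (is_lga & da_mask[None, :])
    acc = (rng.random((n_cells, cfg.n_peak)) < expit(logit_p)).astype(np.int8)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "group": cell_group,
            "total_fragments": np.round(depth * 5000 * rng.uniform(0.9, 1.1, size=n_cells)).astype(int),
        }
    )
    accessibility = pd.DataFrame(acc, index=cells.cell_id, columns=peaks.peak_id)

    # ---- regulons: the first two TFs target planted (hypermethylated,
    # downregulated) genes; the rest target random genes
    truth.true_downregulated = set(truth.true_target_genes)
    all_genes = list(genes.gene_id)
    non_target = [g for g in all_genes if g not in truth.true_target_genes]
    tf_names = [f"TF{j}_{non_target[j]}" for j in range(cfg.n_regulon)]
    regulons: dict[str, list[str]] = {}
    tgt_list = sorted(truth.true_target_genes)
    for j, tf in enumerate(tf_names):
        if j < 2 and len(tgt_list) >= 3:
            size = min(REGULON_SIZE, len(tgt_list))
            members = list(rng.choice(tgt_list, size=size, replace=False))
        else:
            members = list(rng.choice(non_target, size=min(REGULON_SIZE, len(non_target)), replace=False))
        regulons[tf] = sorted(members)

    # ---- genome + PWMs + planted motif occurrences
    from .regnet import associate_peaks_to_genes

    genome = rng.integers(0, 4, size=annot.chrom_len)
    motifs = []
    peak_by_gene = associate_peaks_to_genes(peaks, genes, window_bp=50_000)
    for j, tf in enumerate(tf_names):
        pwm, consensus = _make_pwm(rng)
        max_score = float(np.log2(0.85 / 0.25) * MOTIF_LEN)
        motifs.append(
            Motif(name=tf, pwm=pwm, background=np.full(4, 0.25), threshold=0.85 * max_score)
        )
        offset = 50 + 16 * j  # disjoint per-TF offsets so plants never collide
        cons_idx = np.array([list("ACGT").index(b) for b in consensus])
        for g in regulons[tf]:
            for pk in peak_by_gene.get(g, [])[:1]:
                row = peaks.loc[peaks.peak_id == pk].iloc[0]
                site = int(row.start + offset)
                genome[site : site + MOTIF_LEN] = cons_idx
                truth.planted_motif_sites.append({"tf": tf, "peak_id": pk, "pos": site})
    genome_str = np.frombuffer(b"ACGT", dtype=np.uint8)[genome].tobytes().decode("ascii")

    # ---- expression counts (negative binomial) + DEG table
    mu = rng.lognormal(np.log(5), 1.0, size=cfg.n_gene)
    down = genes.gene_id.isin(truth.true_downregulated).to_numpy()
    fold = np.where(down, 2.0 ** cfg.delta_expr_lfc, 1.0)
    size_factor = rng.lognormal(0, 0.2, size=n_cells)
    mu_mat = mu[:, None] * np.where((cell_group == "LGA")[None, :], fold[:, None], 1.0) * size_factor[None, :]
    r = 2.0
    counts = rng.negative_binomial(r, r / (r + mu_mat))
    expression = pd.DataFrame(counts, index=genes.gene_id, columns=cells.cell_id)

    deg = _deg_table(expression, cell_group)

    return SingleCellData(
        peaks=peaks,
        cells=cells,
        accessibility=accessibility,
        expression=expression,
        regulons=regulons,
        motifs=motifs,
        deg=deg,
        genome=genome_str,
        chrom=CHROM,
    )


def _deg_table(expression: pd.DataFrame, cell_group: np.ndarray) -> pd.DataFrame:
    """Wilcoxon rank-sum DE summary of the generated counts (the DE input table)."""
    ctrl = expression.loc[:, cell_group == "CTRL"].to_numpy()
    lga = expression.loc[:, cell_group == "LGA"].to_numpy()
    pc = 0.1
    lfc = np.log2((lga.mean(axis=1) + pc) / (ctrl.mean(axis=1) + pc))
    pvals = np.array([ranksums(lga[i], ctrl[i]).pvalue for i in range(expression.shape[0])])
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": expression.index,
            "log2fc": lfc,
            "p": pvals,
            "q": q,
            "is_deg": (q < 0.05) & (np.abs(lfc) > 0.5),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# one-call convenience + on-disk layout
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig) -> SyntheticDataset:
    annot = simulate_annotation(cfg)
    study, truth = simulate_methylation(cfg, annot)
    sc = simulate_chromatin_and_expression(cfg, annot, truth)
    return SyntheticDataset(config=cfg, annotation=annot, study=study, truth=truth, sc=sc)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write the full dataset as plain-text files; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    meth = ds.study.meth.copy()
    meth.insert(0, "cpg_id", ds.study.cpgs.cpg_id.to_numpy())
    meth.insert(1, "chrom", ds.study.cpgs.chrom.to_numpy())
    meth.insert(2, "pos", ds.study.cpgs.pos.to_numpy())
    mio.write_tsv(meth, out / "methylation.tsv")
    mio.write_tsv(ds.study.samples, out / "samples.tsv")
    mio.write_tsv(ds.annotation.genes, out / "genes.tsv")
    mio.write_bed(ds.annotation.regulatory, out / "regulatory.bed", extra_cols=["reg_class"])
    mio.write_tsv(ds.annotation.eqtl, out / "eqtl.tsv")
    mio.write_bed(ds.sc.peaks, out / "peaks.bed", extra_cols=["peak_id", "lineage"])
    mio.write_tsv(ds.sc.cells, out / "cells.tsv")
    mio.write_mtx(
        ds.sc.accessibility.to_numpy().astype(np.int64),
        ds.sc.accessibility.index,
        ds.sc.accessibility.columns,
        out,
        "accessibility",
    )
    mio.write_mtx(
        ds.sc.expression.to_numpy().astype(np.int64),
        ds.sc.expression.index,
        ds.sc.expression.columns,
        out,
        "expression",
    )
    mio.write_gmt(ds.sc.regulons, out / "regulons.gmt")
    mio.write_motifs(ds.sc.motifs, out / "motifs.jaspar")
    mio.write_tsv(ds.sc.deg, out / "deg.tsv")
    mio.write_fasta({ds.sc.chrom: ds.sc.genome}, out / "genome.fa")
    mio.write_json(ds.truth.to_dict(), out / "ground_truth.json")

    for name in (
        "methylation.tsv samples.tsv genes.tsv regulatory.bed eqtl.tsv peaks.bed cells.tsv "
        "regulons.gmt motifs.jaspar deg.tsv genome.fa ground_truth.json".split()
    ):
        paths[name] = str(out / name)
    return paths
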