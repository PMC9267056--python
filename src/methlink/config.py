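"""Configuration objects for the simulator and the pipeline.

Both configs are plain dataclasses validated on construction; the pipeline
config can additionally be loaded from a single YAML file (unknown keys are
rejected so typos never silently fall back to defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic multi-omic dataset.

    The defaults describe the study conditions the generator emulates: two
    groups of cord-blood HSPC samples profiled for CpG methylation with
    clinical covariates, plus single-cell accessibility/expression for the
    same contrast. Counts are desk-scale, not cohort-scale.

    Parameters
    ----------
    n_cpg : total CpGs assayed on the synthetic chromosome.
    n_gene : genes with annotated TSS/strand/promoter.
    n_sample_per_group : methylation samples per group (CTRL and LGA).
    n_cell_per_group : single cells per group for ATAC/RNA modalities.
    n_peak : accessibility peaks.
    n_regulon : TF regulons (each TF also receives a PWM).
    effect_frac : fraction of CpGs carrying the planted group effect.
    delta_meth : planted methylation difference, percentage points.
    delta_expr_lfc : planted log2 fold change for downregulated genes
        (negative means lower expression in the LGA group).
    global_bias_frac : strength of the global hypermethylation bias as a
        fraction of ``delta_meth``: every CpG receives a weak positive
        LGA shift drawn Exponential(global_bias_frac * delta_meth)
        percentage points, so ``delta_meth = 0`` remains an exact null.
    noise_sd : per-sample noise s.d. on the logit (latent) methylation scale.
    da_open_prob : (CTRL, LGA) per-cell open probability of planted
        differentially accessible peaks; other peaks share the CTRL range.
    seed : master seed; a fixed seed yields byte-identical outputs.
    """

    n_cpg: int = 5000
    n_gene: int = 600
    n_sample_per_group: int = 16
    n_cell_per_group: int = 300
    n_peak: int = 400
    n_regulon: int = 8
    effect_frac: float = 0.05
    delta_meth: float = 30.0
    delta_expr_lfc: float = -1.0
    global_bias_frac: float = 0.07
    noise_sd: float = 0.3
    da_open_prob: tuple[float, float] = (0.4, 0.15)
    eqtl_frac: float = 0.34
    target_gene_frac: float = 0.03
    da_peak_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cpg", "n_gene", "n_sample_per_group", "n_cell_per_group", "n_peak", "n_regulon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.effect_frac <= 1.0:
            raise ValueError(f"effect_frac must lie in [0, 1], got {self.effect_frac}")
        if not 0.0 <= self.eqtl_frac <= 1.0:
            raise ValueError(f"eqtl_frac must lie in [0, 1], got {self.eqtl_frac}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.da_open_prob
        if not (0 < lo < 1 and 0 < hi < 1):
            raise ValueError("da_open_prob entries must lie in (0, 1)")


#: default per-class regulatory influence of a CpG's genomic context
DEFAULT_REG_WEIGHTS: dict[str, float] = {"promoter": 1.0, "enhancer": 0.75, "other": 0.25}


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Thresholds default to the values used for the HSPC study contrast:
    DMCs at nominal p < 0.001 and |methylation difference| > 25 percentage
    points; differential accessibility at BH q < 0.001 and |log2FC| > 0.25;
    differential regulon activity at q < 0.001 and |fold change| > 10%;
    GSEA calls at q < 0.01 and |NES| > 1.6.
    """

    out_dir: str = "methlink_run"
    seed: int = 0

    # differential methylation
    p_thresh: float = 0.001
    delta_thresh: float = 25.0

    # linking / scoring
    window_bp: int = 50_000
    decay_halflife_bp: float = 10_000.0
    link_floor: float = 0.1
    eqtl_weight: float = 1.0
    reg_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REG_WEIGHTS))
    k_damp: float = 13.8

    # differential accessibility
    da_q_thresh: float = 0.001
    da_lfc_thresh: float = 0.25

    # regulon activity
    regulon_q_thresh: float = 0.001
    regulon_fc_thresh: float = 0.10
    aucell_top_frac: float = 0.05

    # GSEA
    nes_thresh: float = 1.6
    gsea_q_thresh: float = 0.01
    gsea_n_perm: int = 1000

    # simulator (used when the pipeline starts from synthetic data)
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in (
            "p_thresh",
            "delta_thresh",
            "decay_halflife_bp",
            "da_q_thresh",
            "da_lfc_thresh",
            "regulon_q_thresh",
            "regulon_fc_thresh",
            "nes_thresh",
            "gsea_q_thresh",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not 0 < self.aucell_top_frac <= 0.5:
            raise ValueError("aucell_top_frac must lie in (0, 0.5]")
        missing = {"promoter", "enhancer", "other"} - set(self.reg_weights)
        if missing:
            raise ValueError(f"reg_weights missing classes: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim_raw = dict(raw["sim"])
            sim_known = {f.name for f in fields(SimConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            if "da_open_prob" in sim_raw:
                sim_raw["da_open_prob"] = tuple(sim_raw["da_open_prob"])
            raw = dict(raw)
            raw["sim"] = SimConfig(**sim_raw)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["sim"]["da_open_prob"] = list(d["sim"]["da_open_prob"])
        return d
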