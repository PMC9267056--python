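"""Peak-centric analyses: CpG/DMC containment, enrichment, differential
accessibility, and PWM motif scanning.

Differential accessibility follows the single-cell ATAC convention: for
each peak, binary per-cell accessibility is modelled by logistic regression
on group membership with log total fragment count as a latent depth
covariate, and the group effect is assessed by a likelihood-ratio test
against the depth-only model. Effect size is the log2 ratio of detection
fractions with a small pseudocount.

Motif scanning is a log-odds PWM scan of both strands; a region is a hit
when its best window score reaches the motif's threshold. Enrichment of
hits in a target region set against a background set is a hypergeometric
upper-tail test, BH-corrected across motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class Motif:
    """A PWM with background frequencies and a log-odds hit threshold.

    ``pwm`` is a 4 x L matrix of base probabilities (rows A, C, G, T);
    columns must each sum to 1 and L must be at least 4.
    """

    name: str
    pwm: np.ndarray
    background: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape[0] != 4 or self.pwm.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    def log_odds(self) -> np.ndarray:
        return np.log2(np.clip(self.pwm, 1e-4, None) / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


# ---------------------------------------------------------------------------
# containment + hypergeometric enrichment
# ---------------------------------------------------------------------------

def annotate_peaks(peaks: pd.DataFrame, cpgs: pd.DataFrame, dmcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag peaks containing queried CpGs / DMCs (half-open intervals).

    ``dmcs`` may be a called DMC table (rows are used as-is) or omitted.
    Summary fractions are attached to ``DataFrame.attrs``.
    """
    out = peaks.copy()
    out["contains_queried_cpg"] = _contains(peaks, cpgs)
    if dmcs is not None and len(dmcs):
        out["contains_dmc"] = _contains(peaks, dmcs)
    else:
        out["contains_dmc"] = False
    out.attrs["frac_contains_cpg"] = float(out.contains_queried_cpg.mean())
    out.attrs["frac_contains_dmc"] = float(out.contains_dmc.mean())
    return out


def _contains(peaks: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = np.sort(sub.pos.to_numpy())
        sel = peaks.chrom.to_numpy() == chrom
        s = peaks.start.to_numpy()[sel]
        e = peaks.end.to_numpy()[sel]
        # count sites with start <= pos < end
        n_in = np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
        flags[sel] |= n_in > 0
    return flags


def dmc_ocr_enrichment(n_queried: int, n_queried_in_ocr: int, n_dmc: int, n_dmc_in_ocr: int) -> dict:
    """Upper-tail hypergeometric enrichment of DMCs in open chromatin.

    Population: queried CpGs; successes: queried CpGs in OCRs; draws: DMCs;
    observed: DMCs in OCRs. Returns p, fold enrichment and the counts.
    """
    if n_dmc > n_queried:
        raise ValueError("n_dmc cannot exceed n_queried")
    if n_dmc_in_ocr > n_dmc:
        raise ValueError("observed DMCs in OCR cannot exceed draws")
    if n_queried_in_ocr > n_queried:
        raise ValueError("successes cannot exceed population")
    p = float(stats.hypergeom.sf(n_dmc_in_ocr - 1, n_queried, n_queried_in_ocr, n_dmc))
    expected = n_queried_in_ocr / n_queried
    observed = n_dmc_in_ocr / n_dmc if n_dmc else np.nan
    return {
        "p": p,
        "log10_p": float(
            stats.hypergeom.logsf(n_dmc_in_ocr - 1, n_queried, n_queried_in_ocr, n_dmc) / np.log(10)
        ),
        "fold_enrichment": float(observed / expected) if expected > 0 else np.inf,
        "frac_queried_in_ocr": expected,
        "frac_dmc_in_ocr": observed,
    }


def lineage_dmc_enrichment(annotated_peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage enrichment of DMC-containing peaks, BH across lineages.

    Universe: all CpG-containing peaks; draws: the lineage's CpG-containing
    peaks. Lineages without CpG-containing peaks are skipped (logged).
    """
    universe = annotated_peaks[annotated_peaks.contains_queried_cpg]
    N = len(universe)
    K = int(universe.contains_dmc.sum())
    rows = []
    for lineage, sub in universe.groupby("lineage", sort=True):
        n = len(sub)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            continue
        k = int(sub.contains_dmc.sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else np.nan
        rows.append((lineage, n, k, fold, p))
    skipped = set(annotated_peaks.lineage.unique()) - {r[0] for r in rows}
    for lin in sorted(skipped):
        logger.warning("lineage %s skipped: no CpG-containing peaks", lin)
    out = pd.DataFrame(rows, columns=["lineage", "n_peaks_with_cpg", "n_peaks_with_dmc", "fold_enrichment", "p"])
    if len(out):
        out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# differential accessibility (logistic-regression LRT)
# ---------------------------------------------------------------------------

def _logistic_fit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100) -> tuple[np.ndarray, float, bool]:
    """Newton fit of a logistic model; returns (beta, deviance, converged).

    ``ridge`` adds an L2 penalty used only as a separation fallback; the
    returned deviance is always the unpenalised -2 log-likelihood.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, -2.0 * loglik, converged


def _lrt_one_peak(y: np.ndarray, group: np.ndarray, logdepth: np.ndarray) -> tuple[float, bool]:
    """LRT p of the group term given depth; returns (p, used_fallback)."""
    X_full = np.column_stack([np.ones_like(logdepth), group, logdepth])
    X_null = X_full[:, [0, 2]]
    beta_f, dev_f, conv_f = _logistic_fit(X_full, y)
    beta_n, dev_n, conv_n = _logistic_fit(X_null, y)
    fallback = not (conv_f and conv_n) or np.max(np.abs(beta_f)) > 15
    if fallback:
        _, dev_f, _ = _logistic_fit(X_full, y, ridge=1e-3)
        _, dev_n, _ = _logistic_fit(X_null, y, ridge=1e-3)
    lr = max(dev_n - dev_f, 0.0)
    return float(stats.chi2.sf(lr, df=1)), fallback


def test_differential_accessibility(
    accessibility: pd.DataFrame,
    cells: pd.DataFrame,
    q_thresh: float = 0.001,
    lfc_thresh: float = 0.25,
    pseudocount: float = 1e-3,
) -> pd.DataFrame:
    """Per-peak logistic-regression LRT of group with depth as latent variable.

    Parameters
    ----------
    accessibility : binary cell x peak matrix (index = cell ids).
    cells : table with ``cell_id, group, total_fragments`` matching the
        matrix rows.
    q_thresh, lfc_thresh : strict thresholds for the up/down direction call
        on BH-adjusted p and |log2FC|.

    Returns peak_id, detection fractions, log2fc, p, q, direction.
    """
    if list(accessibility.index) != list(cells.cell_id):
        raise ValueError("accessibility rows must match the cell table order")
    counts = cells.group.value_counts()
    if counts.min() < 20:
        raise ValueError("need >= 20 cells per group")
    group = (cells.group.to_numpy() == "LGA").astype(float)
    logdepth = np.log(cells.total_fragments.to_numpy(dtype=float))
    logdepth = logdepth - logdepth.mean()

    is_lga = group == 1
    X = accessibility.to_numpy()
    f_lga = X[is_lga].mean(axis=0)
    f_ctrl = X[~is_lga].mean(axis=0)
    lfc = np.log2((f_lga + pseudocount) / (f_ctrl + pseudocount))

    pvals = np.ones(X.shape[1])
    n_fallback = 0
    for j in range(X.shape[1]):
        y = X[:, j].astype(float)
        if y.sum() == 0 or y.sum() == len(y):
            pvals[j] = 1.0
            continue
        pvals[j], fb = _lrt_one_peak(y, group, logdepth)
        n_fallback += fb
    if n_fallback:
        logger.info("penalised fallback used for %d peaks (separation/non-convergence)", n_fallback)

    q = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(
        (q < q_thresh) & (lfc < -lfc_thresh),
        "down",
        np.where((q < q_thresh) & (lfc > lfc_thresh), "up", "ns"),
    )
    return pd.DataFrame(
        {
            "peak_id": accessibility.columns,
            "frac_ctrl": f_ctrl,
            "frac_lga": f_lga,
            "log2fc": lfc,
            "p": pvals,
            "q": q,
            "direction": direction,
        }
    )


test_differential_accessibility.__test__ = False  # not a pytest test


# ---------------------------------------------------------------------------
# PWM scanning + enrichment
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _best_score(seq: str, motif: Motif) -> float:
    """Best log-odds window score over both strands; -inf if too short."""
    L = motif.length
    lo = motif.log_odds()
    best = -np.inf
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        idx = _encode(s)
        n = len(idx) - L + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        scores = lo[windows[valid], np.arange(L)].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def extract_sequences(intervals: pd.DataFrame, genome: dict[str, str] | str, chrom: str | None = None) -> list[str]:
    """Slice interval sequences out of a genome (dict of chrom -> sequence)."""
    if isinstance(genome, str):
        if chrom is None:
            chrom = intervals.chrom.iloc[0] if len(intervals) else ""
        genome = {chrom: genome}
    seqs = []
    for _, r in intervals.iterrows():
        seq = genome.get(r.chrom, "")
        seqs.append(seq[int(max(r.start, 0)) : int(r.end)])
    return seqs


def scan_motifs(sequences, motifs: list[Motif], genome=None) -> pd.DataFrame:
    """Scan regions (sequences, or an interval table plus genome) for motifs.

    Returns a long table: region (positional index or peak_id when
    available), motif, score, hit.
    """
    if isinstance(sequences, pd.DataFrame):
        if genome is None:
            raise ValueError("interval input requires a genome")
        ids = sequences.peak_id.tolist() if "peak_id" in sequences.columns else list(range(len(sequences)))
        seqs = extract_sequences(sequences, genome)
    else:
        seqs = list(sequences)
        ids = list(range(len(seqs)))
    rows = []
    for rid, seq in zip(ids, seqs):
        for m in motifs:
            sc = _best_score(seq, m)
            rows.append((rid, m.name, sc, bool(sc >= m.threshold)))
    return pd.DataFrame(rows, columns=["region", "motif", "score", "hit"])


def hit_matrix(scan: pd.DataFrame) -> pd.DataFrame:
    """Region x motif boolean hit matrix from a ``scan_motifs`` table."""
    return scan.pivot(index="region", columns="motif", values="hit").fillna(False).astype(bool)


def motif_enrichment(
    target_seqs, background_seqs, motifs: list[Motif], genome=None
) -> pd.DataFrame:
    """Hypergeometric enrichment of motif hits in targets vs background.

    Population = targets + background regions; successes = all hit regions;
    draws = target regions; observed = target hits. BH across motifs.
    """
    t = scan_motifs(target_seqs, motifs, genome=genome)
    b = scan_motifs(background_seqs, motifs, genome=genome)
    rows = []
    for m in motifs:
        ht = int(t.loc[t.motif == m.name, "hit"].sum())
        hb = int(b.loc[b.motif == m.name, "hit"].sum())
        nt = int((t.motif == m.name).sum())
        nb = int((b.motif == m.name).sum())
        N, K = nt + nb, ht + hb
        p = float(stats.hypergeom.sf(ht - 1, N, K, nt))
        exp_frac = K / N if N else np.nan
        fold = (ht / nt) / exp_frac if nt and exp_frac else np.nan
        rows.append((m.name, nt, ht, nb, hb, fold, p))
    out = pd.DataFrame(
        rows, columns=["motif", "n_target", "target_hits", "n_background", "background_hits", "fold_enrichment", "p"]
    )
    if len(out):
        out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out


def dmc_windows(dmcs: pd.DataFrame, flank: int = 20) -> pd.DataFrame:
    """Symmetric +/-``flank`` bp windows around DMC positions.

    On the 0-based half-open convention a window is [pos - flank,
    pos + flank + 1), i.e. 41 bp for the default 20 bp flank.
    """
    return pd.DataFrame(
        {
            "chrom": dmcs.chrom.to_numpy(),
            "start": np.maximum(dmcs.pos.to_numpy() - flank, 0),
            "end": dmcs.pos.to_numpy() + flank + 1,
        }
    )


def sample_background_windows(
    cpgs: pd.DataFrame, n: int, flank: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Size-matched background: windows around randomly sampled queried CpGs."""
    take = rng.choice(len(cpgs), size=min(n, len(cpgs)), replace=False)
    return dmc_windows(cpgs.iloc[np.sort(take)], flank=flank)
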