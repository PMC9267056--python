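"""Chromatin module: containment, hypergeometrics, DA-LRT, motif scanning."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import methlink as ml
from methlink.config import SimConfig
from methlink.chromatin import (
    Motif,
    annotate_peaks,
    dmc_ocr_enrichment,
    lineage_dmc_enrichment,
    test_differential_accessibility,
    scan_motifs,
    motif_enrichment,
    dmc_windows,
    _best_score,
    _logistic_fit,
    _lrt_one_peak,
)


# ---------------------------------------------------------------------------
# containment
# ---------------------------------------------------------------------------

def test_half_open_containment_boundaries():
    peaks = pd.DataFrame(
        {"peak_id": ["p0"], "chrom": "chrS", "start": [100], "end": [200], "lineage": "HSC"}
    )
    inside = pd.DataFrame({"cpg_id": ["a"], "chrom": "chrS", "pos": [150]})
    at_start = pd.DataFrame({"cpg_id": ["b"], "chrom": "chrS", "pos": [100]})
    at_end = pd.DataFrame({"cpg_id": ["c"], "chrom": "chrS", "pos": [200]})
    assert annotate_peaks(peaks, inside).contains_queried_cpg.iloc[0]
    assert annotate_peaks(peaks, at_start).contains_queried_cpg.iloc[0]
    assert not annotate_peaks(peaks, at_end).contains_queried_cpg.iloc[0]


def test_containment_matches_brute_force():
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 5_000, 10)
    peaks = pd.DataFrame(
        {
            "peak_id": [f"p{i}" for i in range(10)],
            "chrom": "chrS",
            "start": starts,
            "end": starts + rng.integers(50, 400, 10),
            "lineage": "HSC",
        }
    )
    cpgs = pd.DataFrame(
        {"cpg_id": [f"c{i}" for i in range(20)], "chrom": "chrS", "pos": rng.integers(0, 5_500, 20)}
    )
    out = annotate_peaks(peaks, cpgs)
    for _, p in out.iterrows():
        expected = any((p.start <= pos < p.end) for pos in cpgs.pos)
        assert p.contains_queried_cpg == expected


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def test_enrichment_at_expected_proportion_is_null():
    res = dmc_ocr_enrichment(1000, 340, 100, 34)
    assert res["fold_enrichment"] == pytest.approx(1.0)
    assert 0.2 < res["p"] < 0.8


def test_enrichment_matches_exhaustive_enumeration():
    """N=20, K=5, n=4, k=3 upper tail equals counting all combinations."""
    res = dmc_ocr_enrichment(20, 5, 4, 3)
    total, at_least = 0, 0
    for draw in combinations(range(20), 4):
        total += 1
        if sum(1 for x in draw if x < 5) >= 3:
            at_least += 1
    assert res["p"] == pytest.approx(at_least / total, rel=1e-10)


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        dmc_ocr_enrichment(100, 30, 200, 10)   # draws > population
    with pytest.raises(ValueError):
        dmc_ocr_enrichment(100, 30, 10, 20)    # observed > draws


def test_lineage_enrichment_planted_hsc_only(ds, dmc_records):
    """DMCs planted in HSC-labelled peaks light up only the HSC lineage."""
    dmcs = dmc_records[dmc_records.is_dmc]
    annotated = annotate_peaks(ds.sc.peaks, ds.study.cpgs, dmcs)
    table = lineage_dmc_enrichment(annotated).set_index("lineage")
    assert table.loc["HSC", "q"] < 0.001
    assert table.loc["HSC", "fold_enrichment"] > 1.5
    others = table.drop(index="HSC")
    assert (others.fold_enrichment < 1.5).all()


def test_lineage_enrichment_consistent_with_global_test():
    """Per-lineage p equals the plain hypergeometric on the same counts."""
    peaks = pd.DataFrame(
        {
            "peak_id": [f"p{i}" for i in range(40)],
            "chrom": "chrS",
            "start": np.arange(40) * 100,
            "end": np.arange(40) * 100 + 50,
            "lineage": ["A"] * 10 + ["B"] * 30,
            "contains_queried_cpg": [True] * 40,
            "contains_dmc": [True] * 6 + [False] * 4 + [True] * 4 + [False] * 26,
        }
    )
    table = lineage_dmc_enrichment(peaks).set_index("lineage")
    ref = dmc_ocr_enrichment(40, 10, 10, 6)  # population peaks, DMC peaks, draws, observed
    # population=40 CpG peaks, successes=10 DMC peaks, draws=lineage A (10), observed 6
    assert table.loc["A", "p"] == pytest.approx(ref["p"], rel=1e-10)


# ---------------------------------------------------------------------------
# differential accessibility
# ---------------------------------------------------------------------------

def _toy_cells(n_per_group, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n)],
            "group": ["CTRL"] * n_per_group + ["LGA"] * n_per_group,
            "total_fragments": rng.integers(2000, 8000, n),
        }
    )


def test_lrt_matches_statsmodels_logit():
    """Own Newton fit reproduces the statsmodels Logit likelihood-ratio p."""
    rng = np.random.default_rng(1)
    n = 120
    group = np.repeat([0.0, 1.0], n // 2)
    logdepth = rng.normal(0, 0.3, n)
    eta = -0.5 + 0.8 * group + logdepth
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

    p_own, fallback = _lrt_one_peak(y, group, logdepth)
    assert not fallback

    X_full = sm.add_constant(np.column_stack([group, logdepth]))
    X_null = sm.add_constant(logdepth)
    llf_full = sm.Logit(y, X_full).fit(disp=0).llf
    llf_null = sm.Logit(y, X_null).fit(disp=0).llf
    p_ref = stats.chi2.sf(2 * (llf_full - llf_null), 1)
    assert p_own == pytest.approx(p_ref, rel=1e-6)


def test_logistic_deviance_matches_2x2_g_test():
    """With no covariate the LRT deviance is the closed-form 2x2 G-statistic."""
    # 30 CTRL (18 open) vs 30 LGA (6 open)
    y = np.array([1.0] * 18 + [0.0] * 12 + [1.0] * 6 + [0.0] * 24)
    group = np.array([0.0] * 30 + [1.0] * 30)
    X_full = np.column_stack([np.ones(60), group])
    X_null = np.ones((60, 1))
    _, dev_full, _ = _logistic_fit(X_full, y)
    _, dev_null, _ = _logistic_fit(X_null, y)

    def g_term(obs, exp):
        return 2 * obs * np.log(obs / exp) if obs > 0 else 0.0

    table = np.array([[18, 12], [6, 24]], dtype=float)
    row, col, tot = table.sum(1), table.sum(0), table.sum()
    g = sum(
        g_term(table[i, j], row[i] * col[j] / tot) for i in range(2) for j in range(2)
    )
    assert dev_null - dev_full == pytest.approx(g, rel=1e-6)


def test_da_group_relabel_invariant():
    rng = np.random.default_rng(2)
    cells = _toy_cells(40)
    acc = pd.DataFrame(
        rng.integers(0, 2, size=(80, 5)),
        index=cells.cell_id,
        columns=[f"p{i}" for i in range(5)],
    )
    a = test_differential_accessibility(acc, cells)
    swapped = cells.assign(group=cells.group.map({"CTRL": "LGA", "LGA": "CTRL"}))
    b = test_differential_accessibility(acc, swapped)
    np.testing.assert_allclose(a.p, b.p, rtol=1e-6)
    np.testing.assert_allclose(a.log2fc, -b.log2fc, rtol=1e-6, atol=1e-12)


def test_da_all_closed_peak_ns():
    cells = _toy_cells(25)
    acc = pd.DataFrame(0, index=cells.cell_id, columns=["p0"])
    out = test_differential_accessibility(acc, cells)
    assert out.p.iloc[0] == 1.0 and out.direction.iloc[0] == "ns"


def test_da_requires_twenty_cells_per_group():
    cells = _toy_cells(10)
    acc = pd.DataFrame(1, index=cells.cell_id, columns=["p0"])
    with pytest.raises(ValueError, match="20 cells"):
        test_differential_accessibility(acc, cells)


def test_da_null_calibration():
    """No planted shift: p<0.05 fraction within binomial bounds of 0.05."""
    cfg = SimConfig(da_peak_frac=0.0, seed=23)
    annot = ml.simulate_annotation(cfg)
    study, truth = ml.simulate_methylation(cfg, annot)
    sc = ml.simulate_chromatin_and_expression(cfg, annot, truth)
    da = test_differential_accessibility(sc.accessibility, sc.cells)
    frac = (da.p < 0.05).mean()
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(da))
    assert abs(frac - 0.05) <= half_width
    assert (da.direction == "ns").all()


def test_da_recovers_planted_peaks(ds, da_results):
    planted = da_results.peak_id.isin(ds.truth.true_da_peaks).to_numpy()
    sensitivity = (da_results.loc[planted, "direction"] == "down").mean()
    assert sensitivity >= 0.8
    false_calls = (da_results.loc[~planted, "direction"] != "ns").sum()
    assert false_calls <= max(2, 0.01 * (~planted).sum())


# ---------------------------------------------------------------------------
# motif scanning + enrichment
# ---------------------------------------------------------------------------

def _uniform_motif(name="M", L=6):
    pwm = np.full((4, L), 0.25)
    return Motif(name=name, pwm=pwm, background=np.full(4, 0.25), threshold=0.0)


def _consensus_motif(consensus="ACGTAC", name="M"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((4, len(consensus)), 0.05)
    for j, b in enumerate(consensus):
        pwm[idx[b], j] = 0.85
    m = Motif(name=name, pwm=pwm, background=np.full(4, 0.25), threshold=0.0)
    m.threshold = 0.85 * m.max_score()
    return m


def test_pwm_validation():
    with pytest.raises(ValueError):
        Motif("bad", np.full((4, 3), 0.25), np.full(4, 0.25), 0.0)   # too short
    with pytest.raises(ValueError):
        Motif("bad", np.full((4, 6), 0.3), np.full(4, 0.25), 0.0)    # columns not normalised


def test_reverse_complement_score_symmetry():
    m = _consensus_motif("ACGGTA")
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 50))
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert _best_score(seq, m) == pytest.approx(_best_score(rc, m), rel=1e-12)


def test_planted_consensus_is_hit():
    m = _consensus_motif("ACGTTGCA")
    seq = "TTTTT" + "ACGTTGCA" + "GGGGG"
    scan = scan_motifs([seq], [m])
    assert bool(scan.hit.iloc[0])
    assert scan.score.iloc[0] == pytest.approx(m.max_score())


def test_region_shorter_than_motif_no_hit():
    m = _consensus_motif("ACGTTGCA")
    scan = scan_motifs(["ACG"], [m])
    assert not scan.hit.iloc[0]
    assert np.isneginf(scan.score.iloc[0])


def test_uninformative_pwm_uniform_background_fold_one():
    """A flat PWM hits everything: enrichment fold is exactly 1."""
    rng = np.random.default_rng(4)
    seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
    m = _uniform_motif()
    table = motif_enrichment(seqs[:10], seqs[10:], [m])
    assert table.fold_enrichment.iloc[0] == pytest.approx(1.0)
    assert table.p.iloc[0] > 0.5


def test_planted_motif_enrichment_recovered(ds):
    """DMC windows are enriched for the planted TF motifs vs background."""
    # use promoter-planted peak sequences as targets instead of tiny windows:
    # the planted sites sit inside target-gene peaks
    planted_peaks = {s["peak_id"] for s in ds.truth.planted_motif_sites}
    peaks = ds.sc.peaks
    targets = peaks[peaks.peak_id.isin(planted_peaks)]
    background = peaks[~peaks.peak_id.isin(planted_peaks)].head(200)
    table = motif_enrichment(
        targets, background, ds.sc.motifs, genome={ds.sc.chrom: ds.sc.genome}
    )
    assert (table.q < 0.05).any()
    assert table.fold_enrichment.max() > 2


def test_dmc_windows_are_41bp():
    dmcs = pd.DataFrame({"cpg_id": ["c"], "chrom": "chrS", "pos": [100]})
    w = dmc_windows(dmcs, flank=20)
    assert w.start.iloc[0] == 80 and w.end.iloc[0] == 121
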