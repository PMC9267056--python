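"""Covariate-adjusted per-CpG differential methylation and DMC calling.

Each CpG's methylation percentage is regressed on group plus clinical and
technical covariates (maternal age, sex, ethnicity, batch, library
complexity) by ordinary least squares; the group coefficient is tested with
a t-test. Because the design matrix is shared across CpGs the fits are fully
vectorised.

Two deliberate conventions:

* the reported ``meth_change`` is the *unadjusted* difference of group means
  (LGA% - CTRL%), while the p-value comes from the covariate-adjusted model;
* a CpG is called a DMC when ``p < p_thresh`` and ``|meth_change| >
  delta_thresh`` with strict inequalities (defaults 0.001 and 25 percentage
  points).

An optional empirical-Bayes variance moderation (limma-style squeezing of
the residual variances) is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import MethylationStudy

DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "batch", "complexity")


class RankDeficientDesignError(ValueError):
    """The design matrix lost full rank; the message names the covariate."""


def _design_matrix(samples: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, int]:
    """Build [intercept | group | covariate columns]; returns (X, group_col).

    Categorical covariates are dummy-coded dropping the first level. Columns
    are added covariate by covariate; any covariate whose columns are
    collinear with what precedes them is reported by name.
    """
    n = len(samples)
    cols = [np.ones(n), (samples["group"].to_numpy() == "LGA").astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} not in sample table")
        vals = samples[cov]
        if pd.api.types.is_numeric_dtype(vals):
            new = [vals.to_numpy(dtype=float)]
        else:
            levels = sorted(pd.unique(vals))
            new = [(vals.to_numpy() == lev).astype(float) for lev in levels[1:]]
        before = np.column_stack(cols)
        candidate = np.column_stack(cols + new)
        if np.linalg.matrix_rank(candidate) < np.linalg.matrix_rank(before) + len(new):
            raise RankDeficientDesignError(
                f"design matrix rank-deficient after adding covariate {cov!r}"
            )
        cols.extend(new)
        names.extend([cov] * len(new))
    return np.column_stack(cols), 1


def _squeeze_var(s2: np.ndarray, dof: int) -> tuple[np.ndarray, float]:
    """Moment-based empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse-chi-square prior to the observed variances via the
    moments of log(s2) and returns the posterior variances plus the extra
    prior degrees of freedom.
    """
    from scipy.special import digamma, polygamma

    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(dof / 2) + np.log(dof / 2)
    ev = np.var(e, ddof=1) - polygamma(1, dof / 2)
    if ev <= 0:
        d0 = np.inf
        s0 = np.exp(np.mean(e))
    else:
        # solve trigamma(d0/2) = ev by Newton on the inverse
        x = ev
        y = 0.5 + 1.0 / x
        for _ in range(50):
            tri = polygamma(1, y)
            dif = tri - x
            if abs(dif) < 1e-12:
                break
            y = y - dif / polygamma(2, y)
        d0 = 2 * y
        s0 = np.exp(np.mean(e) - digamma(y) + np.log(y))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + dof * s2) / (d0 + dof)
    return post, float(d0)


def fit_cpg_models(
    study: MethylationStudy,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    moderate: bool = False,
) -> pd.DataFrame:
    """OLS fit of methylation% ~ group + covariates for every CpG.

    Returns a DataFrame with one row per CpG: ``cpg_id, chrom, pos, p, q,
    meth_change`` (percentage points, LGA minus CTRL). Requires at least 3
    samples per group and a full-rank design.
    """
    samples = study.samples
    counts = samples.group.value_counts()
    if counts.get("CTRL", 0) < 3 or counts.get("LGA", 0) < 3:
        raise ValueError("need >= 3 samples per group")
    if list(study.meth.columns) != list(samples.sample_id):
        raise ValueError("methylation matrix columns must match sample table order")

    X, g = _design_matrix(samples, covariates)
    Y = study.meth.to_numpy().T * 100.0  # samples x cpgs, percent scale
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, p={p})")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / dof

    t_dof = float(dof)
    if moderate:
        s2, d0 = _squeeze_var(s2, dof)
        if np.isfinite(d0):
            t_dof = dof + d0

    se = np.sqrt(np.maximum(s2, 0) * xtx_inv[g, g])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[g] / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), t_dof)

    is_lga = (samples.group == "LGA").to_numpy()
    change = Y[is_lga].mean(axis=0) - Y[~is_lga].mean(axis=0)

    constant = Y.std(axis=0) == 0
    pvals = np.where(constant, 1.0, np.clip(pvals, np.finfo(float).tiny, 1.0))
    change = np.where(constant, 0.0, change)

    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cpg_id": study.cpgs.cpg_id.to_numpy(),
            "chrom": study.cpgs.chrom.to_numpy(),
            "pos": study.cpgs.pos.to_numpy(),
            "p": pvals,
            "q": q,
            "meth_change": change,
        }
    )


def call_dmcs(
    records: pd.DataFrame, p_thresh: float = 0.001, delta_thresh: float = 25.0
) -> pd.DataFrame:
    """Call DMCs at strict thresholds and partition hyper/hypo.

    Adds ``is_dmc`` and ``status`` in {hyper, hypo, ns}; attaches the hyper
    and hypo counts as ``DataFrame.attrs['n_hyper'] / ['n_hypo']``.
    """
    out = records.copy()
    sig = (out.p < p_thresh) & (out.meth_change.abs() > delta_thresh)
    out["is_dmc"] = sig
    out["status"] = np.where(~sig, "ns", np.where(out.meth_change > 0, "hyper", "hypo"))
    out.attrs["n_hyper"] = int((out.status == "hyper").sum())
    out.attrs["n_hypo"] = int((out.status == "hypo").sum())
    return out
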