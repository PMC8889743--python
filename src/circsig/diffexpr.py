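"""Differential expression of circRNAs and genes between paired tumor/normal samples.

The engine is a negative-binomial Wald test in the DESeq-family mould,
implemented here directly and vectorised over features:

1. size factors by median-of-ratios over features with a positive geometric
   mean;
2. per-feature NB dispersion by method of moments on normalized counts,
   pooled across the two conditions and floored at 1e-8;
3. an NB log-link GLM per feature (intercept + condition, plus patient
   indicator covariates when the design is paired), fitted by iteratively
   reweighted least squares with the log size factor as offset;
4. a Wald test on the condition coefficient, referred to a t distribution
   whose degrees of freedom reflect the information behind the dispersion
   estimate (n_samples minus the number of condition groups), which keeps
   the test calibrated at the cohort sizes this pipeline targets;
5. Benjamini-Hochberg adjustment across tested features.

A feature is called up (down) only when both gates pass: BH-adjusted
p < ``de_max_padj`` and |fold change| >= ``de_min_fold_change``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    ExpressionMatrix,
    JunctionCountMatrix,
    PipelineConfig,
    SampleMeta,
    paired_samples,
)

_DISPERSION_FLOOR = 1e-8


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples input)."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no feature has a positive geometric mean")
    ratios = log_counts[usable, :] - log_geo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return sf


def estimate_dispersion(
    counts: np.ndarray, sf: np.ndarray, condition: np.ndarray
) -> np.ndarray:
    """Method-of-moments NB dispersion per feature on normalized counts.

    For normalized counts q within one condition, E[var(q)] ~ mean(1/sf)*m
    + alpha*m^2; solving for alpha within each condition and averaging
    removes the condition effect from the moment estimate.
    """
    q = counts / sf[None, :]
    alphas = []
    for g in np.unique(condition):
        cols = condition == g
        if cols.sum() < 2:
            continue
        m = q[:, cols].mean(axis=1)
        v = q[:, cols].var(axis=1, ddof=1)
        shot = np.mean(1.0 / sf[cols])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - shot * m) / np.square(m)
        alphas.append(np.where(m > 0, a, np.nan))
    if not alphas:
        raise ValueError("need >= 2 samples per condition to estimate dispersion")
    alpha = np.nanmean(np.vstack(alphas), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def _nb_irls(
    counts: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit NB log-link GLMs for all features at once.

    Returns (beta, cov) with beta of shape (F, p) and cov the batched
    inverse Fisher information (F, p, p).
    """
    F, n = counts.shape
    p = X.shape[1]
    y = counts.astype(float)
    # least-squares init on the working response of a log-linear model
    z0 = np.log(y + 0.5) - offset[None, :]
    beta = z0 @ np.linalg.pinv(X).T
    eye = np.eye(p) * 1e-10
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        XtWX = np.einsum("fn,ni,nj->fij", W, X, X) + eye
        XtWz = np.einsum("fn,ni,fn->fi", W, X, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(new - beta).max()
        beta = new
        if step < tol:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("fn,ni,nj->fij", W, X, X) + np.eye(p) * 1e-12
    cov = np.linalg.inv(XtWX)
    return beta, cov


def _design(samples: list[SampleMeta], paired: bool) -> tuple[np.ndarray, int]:
    """Design matrix (intercept, condition, patient blocks); returns (X, condition column)."""
    n = len(samples)
    cond = np.array([1.0 if s.condition == "tumor" else 0.0 for s in samples])
    cols = [np.ones(n), cond]
    if paired:
        patients = sorted({s.patient_id for s in samples})
        for pat in patients[1:]:  # drop one for identifiability
            cols.append(
                np.array([1.0 if s.patient_id == pat else 0.0 for s in samples])
            )
    X = np.column_stack(cols)
    return X, 1


def de_test(
    counts: np.ndarray,
    feature_ids: list[str],
    samples: list[SampleMeta],
    cancer: str = "",
    paired: bool = True,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """NB Wald differential expression, tumor vs. normal.

    ``counts`` is an integer features-by-samples matrix from one cancer
    cohort.  All-zero features are excluded from testing and reported
    ``ns`` with NaN statistics.  Returns one row per feature with
    base_mean, log2fc (tumor relative to normal), p_value, padj, direction.
    """
    config = config or PipelineConfig()
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("de_test requires integer counts")
        counts = np.round(counts).astype(int)
    conditions = {s.condition for s in samples}
    if conditions != {"tumor", "normal"}:
        raise ValueError("need both tumor and normal samples")
    if paired:
        pairs = paired_samples(samples)
        if len(pairs) < 3:
            raise ValueError("paired design requires >= 3 tumor/normal pairs")
        keep_ids = [s.sample_id for pair in pairs for s in pair]
        idx = [i for i, s in enumerate(samples) if s.sample_id in set(keep_ids)]
        samples = [samples[i] for i in idx]
        counts = counts[:, idx]

    testable = counts.sum(axis=1) > 0
    cond = np.array([s.condition for s in samples])
    sf = size_factors(counts[testable, :])
    alpha = estimate_dispersion(counts[testable, :], sf, cond)
    X, cond_col = _design(samples, paired)
    beta, cov = _nb_irls(counts[testable, :], X, alpha, np.log(sf))
    lfc = beta[:, cond_col] / np.log(2.0)
    se = np.sqrt(cov[:, cond_col, cond_col])
    # df of the Wald t reference: the dispersion moments pool all samples
    # within each condition, so n - n_conditions observations back the
    # variance estimate (the pairing covariates don't consume dispersion df)
    df = max(counts.shape[1] - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, cond_col] / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    n_features = counts.shape[0]
    out = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "cancer": cancer,
            "base_mean": np.full(n_features, np.nan),
            "log2fc": np.full(n_features, np.nan),
            "p_value": np.full(n_features, np.nan),
            "padj": np.full(n_features, np.nan),
            "direction": "ns",
        }
    )
    t_idx = np.flatnonzero(testable)
    out.loc[t_idx, "base_mean"] = (counts[testable, :] / sf[None, :]).mean(axis=1)
    out.loc[t_idx, "log2fc"] = lfc
    out.loc[t_idx, "p_value"] = pvals
    padj = multipletests(pvals, method="fdr_bh")[1]
    out.loc[t_idx, "padj"] = padj
    min_lfc = np.log2(config.de_min_fold_change)
    sig = padj < config.de_max_padj
    up = sig & (lfc >= min_lfc)
    down = sig & (lfc <= -min_lfc)
    direction = np.where(up, "up", np.where(down, "down", "ns"))
    out.loc[t_idx, "direction"] = direction
    return out


def prevalence_filter(
    rpm: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> list[str]:
    """Features with RPM >= 0.1 in at least 10% of that cohort's samples.

    The required count is ``ceil(fraction * n_samples)``; both tumor and
    normal samples of the cohort count toward prevalence.
    """
    config = config or PipelineConfig()
    n = len(rpm.sample_ids)
    need = int(np.ceil(config.de_prevalence_fraction * n))
    hits = (rpm.values >= config.de_prevalence_min_rpm).sum(axis=1)
    return [f for f, h in zip(rpm.feature_ids, hits) if h >= need]


def de_per_cancer(
    jcm: JunctionCountMatrix,
    paired: bool = True,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Prevalence-filter and test each cancer (tissue) cohort separately."""
    from .quantify import rpm_matrix

    config = config or PipelineConfig()
    results: dict[str, pd.DataFrame] = {}
    for tissue in sorted({s.tissue for s in jcm.samples}):
        sub = jcm.for_tissue(tissue)
        kept_ids = prevalence_filter(rpm_matrix(sub), config)
        keep_idx = [i for i, c in enumerate(sub.circ_ids) if c in set(kept_ids)]
        sub = sub.subset_records(keep_idx)
        results[tissue] = de_test(
            sub.back_spliced,
            sub.circ_ids,
            sub.samples,
            cancer=tissue,
            paired=paired,
            config=config,
        )
    return results


def global_abundance_test(
    rpm: ExpressionMatrix,
) -> pd.DataFrame:
    """Total circRNA RPM per sample, compared tumor vs. normal per cancer.

    Uses the two-sided Wilcoxon rank-sum test; cohorts with fewer than
    3 tumor/normal pairs report NaN p.
    """
    if rpm.samples is None:
        raise ValueError("RPM matrix needs attached sample metadata")
    totals = rpm.values.sum(axis=0)
    rows = []
    for tissue in sorted({s.tissue for s in rpm.samples}):
        t_tot = [
            totals[j]
            for j, s in enumerate(rpm.samples)
            if s.tissue == tissue and s.condition == "tumor"
        ]
        n_tot = [
            totals[j]
            for j, s in enumerate(rpm.samples)
            if s.tissue == tissue and s.condition == "normal"
        ]
        if min(len(t_tot), len(n_tot)) >= 3:
            p = stats.mannwhitneyu(t_tot, n_tot, alternative="two-sided").pvalue
        else:
            p = np.nan
        rows.append(
            {
                "cancer": tissue,
                "tumor_median_total_rpm": float(np.median(t_tot)) if t_tot else np.nan,
                "normal_median_total_rpm": float(np.median(n_tot)) if n_tot else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def count_de(de_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cancer counts of up- and down-regulated features."""
    if de_table.empty:
        return pd.DataFrame(columns=["cancer", "n_up", "n_down", "n_total"])
    rows = []
    for cancer, grp in de_table.groupby("cancer"):
        n_up = int((grp["direction"] == "up").sum())
        n_down = int((grp["direction"] == "down").sum())
        rows.append(
            {"cancer": cancer, "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
        )
    return pd.DataFrame(rows)
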