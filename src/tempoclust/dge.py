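"""Per-timepoint differential expression (MUT vs WT) with batch correction.

This stage is a deliberately simple, fully self-contained stand-in for a
negative-binomial GLM package: counts are normalized by median-of-ratios
size factors, transformed to ``log2(normalized count + pseudocount)``
(a variance-stabilizing-transformation-like scale), and per gene an
ordinary-least-squares model ``expression ~ genotype + batch`` is fit within
each timepoint. The genotype coefficient is the log2 fold-change, its
two-sided t-test p-value is adjusted by Benjamini-Hochberg within the
timepoint, and genes are called differentially expressed at adjusted
p < 0.1. The output table is also an accepted *input* format, so results
from a dedicated count-model fit (e.g. a DESeq2 run on real data) can be
substituted for this stage without touching anything downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DE_TABLE_COLUMNS, CountMatrix, ValidationError

__all__ = [
    "size_factors_median_of_ratios",
    "vst_like",
    "bh_adjust",
    "de_per_timepoint",
    "de_all_timepoints",
]

DEFAULT_ADJP_THRESHOLD = 0.1


class ConfoundedDesignError(ValueError):
    """Genotype contrast is not estimable separately from batch."""


def size_factors_median_of_ratios(
    counts: CountMatrix | pd.DataFrame,
    fallback_total_count: bool = False,
) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample the factor is the median, over genes with positive counts
    in every sample, of the ratio of the sample's count to the gene's
    geometric mean across samples. If no gene is expressed in all samples the
    call fails unless ``fallback_total_count`` is set, in which case factors
    are total counts scaled to geometric mean one.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        if not fallback_total_count:
            raise ValidationError(
                "no gene has positive counts in every sample; "
                "pass fallback_total_count=True to normalize by library totals"
            )
        totals = vals.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        pos = vals[all_pos]
        log_geomean = np.mean(np.log(pos), axis=1)
        ratios = pos / np.exp(log_geomean)[:, None]
        factors = np.median(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise ValidationError("size factors must be finite and positive")
    return pd.Series(factors, index=mat.columns, name="size_factor")


def vst_like(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """``log2(count / size_factor + pseudocount)`` expression matrix."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if np.any(size_factors.to_numpy() <= 0):
        raise ValidationError("size factors must be positive")
    norm = mat.to_numpy(dtype=float) / size_factors.reindex(mat.columns).to_numpy()
    return pd.DataFrame(np.log2(norm + pseudocount), index=mat.index, columns=mat.columns)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j with p_(j) >= p_(i) of min(1, m * p_(j) / rank(j));
    monotone in the input ranks and never below the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Intercept + MUT indicator + batch dummies; returns (X, genotype column)."""
    geno = (design["genotype"] == "MUT").to_numpy(dtype=float)
    cols = [np.ones(len(design)), geno]
    batches = pd.unique(design["batch"])
    for b in batches[1:]:  # first level absorbed by the intercept
        cols.append((design["batch"] == b).to_numpy(dtype=float))
    return np.column_stack(cols), 1


def de_per_timepoint(
    vst: pd.DataFrame,
    design: pd.DataFrame,
    timepoint: str,
    adjp_within: bool = True,
) -> pd.DataFrame:
    """OLS differential expression for one timepoint.

    Fits, per gene, expression on a mutant-genotype indicator plus batch
    indicators over that timepoint's samples. Genes with identical expression
    in every sample of the timepoint get coefficient 0 and p = 1 (no
    fabricated significance from zero variance).
    """
    sub = design[design["timepoint"] == timepoint]
    if sub.empty:
        raise ValidationError(f"no samples at timepoint {timepoint!r}")
    genos = set(sub["genotype"])
    if genos != {"WT", "MUT"}:
        raise ValidationError(f"timepoint {timepoint!r} lacks both genotypes (has {sorted(genos)})")
    for geno in ("WT", "MUT"):
        if (sub["genotype"] == geno).sum() < 2:
            raise ValidationError(f"timepoint {timepoint!r}: fewer than 2 {geno} samples")

    X, geno_col = _design_matrix(sub)
    n, p_cols = X.shape
    if np.linalg.matrix_rank(X) < p_cols:
        raise ConfoundedDesignError(
            f"timepoint {timepoint!r}: genotype is confounded with batch "
            "(design matrix is rank deficient)"
        )
    df_resid = n - p_cols
    if df_resid <= 0:
        raise ValidationError(f"timepoint {timepoint!r}: zero residual degrees of freedom")

    # contiguous copy: reduction order (and thus the last float ulp) must not
    # depend on how the caller's expression matrix happens to be laid out
    Y = np.ascontiguousarray(vst.loc[:, sub.index].to_numpy(dtype=float))
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # p x n
    beta = Y @ proj.T  # genes x p
    resid = Y - beta @ X.T
    rss = np.sum(resid**2, axis=1)
    sigma2 = rss / df_resid
    var_beta = sigma2 * xtx_inv[geno_col, geno_col]

    coef = beta[:, geno_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / np.sqrt(var_beta)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    # zero residual variance: perfect fit -> call significant only if the
    # contrast is nonzero; all-constant genes are handled below anyway
    pval = np.where(np.isnan(pval), np.where(coef != 0.0, 0.0, 1.0), pval)

    constant = np.ptp(Y, axis=1) == 0.0
    coef = np.where(constant, 0.0, coef)
    pval = np.where(constant, 1.0, pval)

    out = pd.DataFrame(
        {
            "gene_id": vst.index,
            "timepoint": timepoint,
            "log2fc": coef,
            "pvalue": pval,
            "mean_expr": Y.mean(axis=1),
        }
    )
    out["adjp"] = bh_adjust(out["pvalue"].to_numpy()) if adjp_within else np.nan
    return out[DE_TABLE_COLUMNS]


def de_all_timepoints(
    counts: CountMatrix,
    pseudocount: float = 1.0,
    fallback_total_count: bool = False,
) -> pd.DataFrame:
    """Complete DE table: one row per gene per timepoint, BH within timepoint."""
    sf = size_factors_median_of_ratios(counts, fallback_total_count=fallback_total_count)
    vst = vst_like(counts, sf, pseudocount=pseudocount)
    parts = [de_per_timepoint(vst, counts.design, tp) for tp in counts.timepoints]
    return pd.concat(parts, ignore_index=True)
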