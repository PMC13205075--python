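"""Two-group negative-binomial differential expression.

The chain is the classic bulk RNA-seq recipe: median-of-ratios size
factors, per-feature method-of-moments dispersion, a Wald test on the log
ratio of group means of normalized counts (delta-method standard error
under variance = mu + alpha * mu^2), and class-specific volcano
classification on the base-10 log fold change.

Fold changes are base-10 logs throughout, and classification uses raw
p-values with class-specific cutoffs: |log10 FC| >= 0.6 (about four-fold)
with p < 0.05 for mRNA and lncRNA and p < 0.01 for miRNA and circRNA.
This is deliberately a direct Wald test, not an IRLS GLM with dispersion
shrinkage: with three replicates per group the simple estimator is
transparent, and its calibration is verified by simulation rather than by
equivalence to any particular GLM fitter.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, FormatError
from .types import DERecord, ExpressionMatrix, GROUPS

#: volcano thresholds: |log10 FC| cut and per-class raw-p cutoffs
LFC_CUT = 0.6
P_CUTOFFS = {"mRNA": 0.05, "lncRNA": 0.05, "miRNA": 0.01, "circRNA": 0.01}
DEFAULT_PSEUDOCOUNT = 0.5

_DISPERSION_FLOOR = 1e-8
_P_FLOOR = 1e-300


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    Features with any zero count are excluded from the reference (their
    geometric mean would be zero). Raises if no feature is eligible.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise FormatError(
            "no feature has nonzero counts in every sample; cannot form a "
            "median-of-ratios reference (consider a pseudo-reference fallback)"
        )
    ref = counts[eligible]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns)


def normalized_counts(matrix: ExpressionMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return matrix.counts.div(factors.loc[matrix.counts.columns], axis=1)


def estimate_dispersion(
    matrix: ExpressionMatrix,
    factors: pd.Series,
) -> pd.Series:
    """Per-feature NB dispersion alpha by method of moments on normalized counts.

    alpha_i = max(0, (s2 - m) / m^2) with m the grand mean and s2 the pooled
    within-group variance of normalized counts, floored at 1e-8. Features
    with all-zero counts get NaN (flagged, excluded downstream). Requires
    >= 2 samples per group.
    """
    for g in GROUPS:
        if len(matrix.samples_in_group(g)) < 2:
            raise ConsistencyError(f"group {g!r} needs >= 2 samples for dispersion")
    norm = normalized_counts(matrix, factors)
    n_total = norm.shape[1]
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in GROUPS:
        cols = matrix.samples_in_group(g)
        x = norm[cols].to_numpy()
        gm = x.mean(axis=1, keepdims=True)
        ss += ((x - gm) ** 2).sum(axis=1)
        dof += len(cols) - 1
    s2 = ss / dof
    m = norm.to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, np.maximum((s2 - m) / np.where(m > 0, m, 1.0) ** 2, 0.0), np.nan)
    alpha = np.where(np.isnan(alpha), np.nan, np.maximum(alpha, _DISPERSION_FLOOR))
    return pd.Series(alpha, index=norm.index)


def moderate_dispersion(
    alpha: pd.Series,
    residual_df: int,
    prior_df: float = 10.0,
    common: float | None = None,
) -> pd.Series:
    """Shrink per-feature dispersions toward the common dispersion.

    Weighted combination (residual_df * alpha_i + prior_df * common) /
    (residual_df + prior_df), the classic empirical-Bayes moderation for
    tag-wise NB dispersion. With few replicates the raw method-of-moments
    estimate has so few degrees of freedom that plugging it into the Wald
    statistic inflates the type-I rate; moderation restores calibration.
    ``common`` defaults to the mean of the finite per-feature estimates
    (the mean, unlike the median, is nearly unbiased for a shared alpha
    because the per-feature estimator is right-skewed).
    """
    if residual_df < 1:
        raise ConsistencyError("moderation needs >= 1 residual degree of freedom")
    if prior_df < 0:
        raise FormatError("prior_df must be >= 0")
    if common is None:
        finite = alpha[np.isfinite(alpha)]
        if finite.empty:
            raise ConsistencyError("no finite dispersion estimates to pool")
        common = float(finite.mean())
    moderated = (residual_df * alpha + prior_df * common) / (residual_df + prior_df)
    return moderated.where(np.isfinite(alpha), np.nan)


def pooled_residual_df(matrix: ExpressionMatrix) -> int:
    """Within-group residual degrees of freedom: sum over groups of (n_g - 1)."""
    return sum(len(matrix.samples_in_group(g)) - 1 for g in GROUPS)


def nb_wald_test(
    matrix: ExpressionMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DERecord]:
    """Wald test on the log ratio of group means of normalized counts.

    With m1, m2 the control and cold group means and c the pseudocount,
    log10_fc = log10((m2 + c) / (m1 + c)) and the natural-log standard
    error follows the delta method for an NB mean:
    SE^2 = (1/n1) (1/(m1+c) + alpha) + (1/n2) (1/(m2+c) + alpha).
    Two-sided p from the standard normal. Features whose dispersion is NaN
    (all-zero counts) are skipped.
    """
    if pseudocount <= 0:
        raise FormatError("pseudocount must be > 0")
    for g in GROUPS:
        if len(matrix.samples_in_group(g)) == 0:
            raise ConsistencyError(f"group {g!r} has zero samples")
    norm = normalized_counts(matrix, factors)
    cold = matrix.samples_in_group("cold")
    control = matrix.samples_in_group("control")
    n2, n1 = len(cold), len(control)
    m2 = norm[cold].to_numpy().mean(axis=1)
    m1 = norm[control].to_numpy().mean(axis=1)
    base_mean = norm.to_numpy().mean(axis=1)
    alpha = dispersions.loc[norm.index].to_numpy()
    c = pseudocount
    records: list[DERecord] = []
    ln_fc = np.log(m2 + c) - np.log(m1 + c)
    se2 = (1.0 / n1) * (1.0 / (m1 + c) + alpha) + (1.0 / n2) * (1.0 / (m2 + c) + alpha)
    se = np.sqrt(se2)
    with np.errstate(invalid="ignore"):
        z = ln_fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, _P_FLOOR, 1.0)
    for i, fid in enumerate(norm.index):
        if np.isnan(alpha[i]):
            continue  # all-zero feature: test undefined
        records.append(
            DERecord(
                feature_id=fid,
                rna_class=matrix.rna_class.loc[fid],
                base_mean=float(base_mean[i]),
                log10_fc=float(ln_fc[i] / np.log(10.0)),
                se_log=float(se[i]),
                p=float(p[i]),
            )
        )
    return records


def classify_features(
    records: Sequence[DERecord],
    lfc_cut: float = LFC_CUT,
    p_cutoffs: Mapping[str, float] = P_CUTOFFS,
) -> list[DERecord]:
    """Fill volcano status: up/down/ns under the class-specific cutoffs.

    up iff log10_fc >= lfc_cut and p < class cutoff (boundary inclusive on
    the fold change, strict on p); down symmetric; otherwise ns.
    """
    out = []
    for r in records:
        if r.rna_class not in p_cutoffs:
            raise FormatError(f"no p cutoff for RNA class {r.rna_class!r}")
        cut = p_cutoffs[r.rna_class]
        if r.p < cut and r.log10_fc >= lfc_cut:
            status = "up"
        elif r.p < cut and r.log10_fc <= -lfc_cut:
            status = "down"
        else:
            status = "ns"
        r.status = status
        out.append(r)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise FormatError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def attach_bh(records: Sequence[DERecord]) -> list[DERecord]:
    """Fill ``p_adj`` on DE records (BH across all provided records)."""
    if not records:
        return []
    adj = bh_adjust([r.p for r in records])
    for r, a in zip(records, adj):
        r.p_adj = float(a)
    return list(records)


def pca(
    matrix: ExpressionMatrix,
    factors: pd.Series,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA on log10(normalized + 1), feature-centered, via SVD.

    Returns (scores, variance_explained): scores is samples x components,
    variance fractions sum to 1. Component signs are fixed by making the
    largest-magnitude feature loading of each component positive, so the
    result is deterministic. Raises on < 3 samples or a constant matrix.
    """
    if matrix.counts.shape[1] < 3:
        raise ConsistencyError("PCA needs >= 3 samples")
    x = np.log10(normalized_counts(matrix, factors).to_numpy().T + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(x) > 1e-12):
        raise FormatError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > max(s) * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    var_frac = s**2 / np.sum(s**2)
    score_df = pd.DataFrame(
        scores,
        index=matrix.counts.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, var_frac


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """Tabulate DE records (one row per feature, stable feature order)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "rna_class": [r.rna_class for r in records],
            "base_mean": [r.base_mean for r in records],
            "log10_fc": [r.log10_fc for r in records],
            "se_log": [r.se_log for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
            "status": [r.status for r in records],
        }
    )
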