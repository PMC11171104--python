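"""Two-condition negative-binomial differential expression.

The engine follows the standard count-model workflow: median-of-ratios
size factors, method-of-moments dispersion estimation on normalised counts,
a Wald test on the log2 ratio of condition means with a delta-method
standard error from the NB mean-variance relation (Var = mu + alpha*mu^2),
and Benjamini-Hochberg adjustment. Features are then filtered with
inclusive thresholds on total raw count, adjusted p value and |log2 fold
change|, plus an optional reads-per-million abundance floor applied to the
condition means.

This is a deliberately transparent reimplementation of the workflow popular
count-based DE tools implement; it performs no fold-change shrinkage,
independent filtering or outlier moderation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, NormalizationError, ValidationError
from .types import CONTROL, TREATED, CountMatrix

ALPHA_FLOOR = 1e-8
PSEUDO_COUNT = 0.5

DE_COLUMNS = [
    "feature_id", "base_mean", "log2fc", "pvalue", "padj",
    "total_raw_count", "rpm_control", "rpm_treated", "direction",
]


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median, over features with no zero
    count in any sample, of the ratio of the sample's count to the feature's
    geometric mean across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError(
            "no feature has positive counts in every sample; "
            "median-of-ratios normalisation needs at least one such feature"
        )
    logs = np.log(mat[usable])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.counts.columns, name="size_factor")


def estimate_dispersion(counts: CountMatrix, sf: pd.Series) -> pd.Series:
    """Per-feature method-of-moments NB dispersion on normalised counts.

    ``alpha = max(ALPHA_FLOOR, (pooled within-condition variance - mean) / mean^2)``
    where the variance pools the two conditions' sample variances by their
    degrees of freedom and the mean is taken over all normalised counts.
    """
    norm = counts.counts.div(sf, axis=1)
    ctrl = norm[counts.samples_of(CONTROL)]
    trt = norm[counts.samples_of(TREATED)]
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise InsufficientDataError("dispersion estimation needs >=2 samples per condition")
    df_c, df_t = ctrl.shape[1] - 1, trt.shape[1] - 1
    pooled_var = (ctrl.var(axis=1, ddof=1) * df_c + trt.var(axis=1, ddof=1) * df_t) / (df_c + df_t)
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean.pow(2)
    alpha = alpha.replace([np.inf, -np.inf], np.nan).fillna(ALPHA_FLOOR)
    return alpha.clip(lower=ALPHA_FLOOR).rename("dispersion")


def moderate_dispersion(alpha: pd.Series, prior_df: float = 10.0, resid_df: float = 4.0) -> pd.Series:
    """Shrink per-feature dispersions toward their across-feature mean.

    With a handful of replicates the per-feature moment estimate is far too
    noisy to plug into a Wald variance, so each estimate is averaged with
    the across-feature mean, weighted by the residual degrees of freedom
    against a prior weight. The mean (not the median) is the centre because
    the per-feature estimates are right-skewed at small sample sizes: their
    mean stays close to the underlying dispersion while the median sits
    below it, which would make the Wald test anti-conservative.
    """
    centre = float(np.mean(alpha.clip(lower=ALPHA_FLOOR)))
    if centre <= ALPHA_FLOOR:
        return alpha.copy()
    w = resid_df / (resid_df + prior_df)
    mod = w * alpha.clip(lower=ALPHA_FLOOR) + (1 - w) * centre
    return mod.clip(lower=ALPHA_FLOOR).rename("dispersion")


def nb_wald_test(
    counts: CountMatrix,
    sf: pd.Series,
    dispersions: pd.Series,
    pseudo_count: float = PSEUDO_COUNT,
) -> pd.DataFrame:
    """Wald test of treated-vs-control log2 fold change per feature.

    The fold change is ``log2((mean_t + c) / (mean_c + c))`` on normalised
    counts with pseudo-count ``c``. Its standard error comes from the delta
    method with ``Var(mean_g) = mean_g * sum(1/s_j) / n_g^2 + alpha *
    mean_g^2 / n_g``; the two-sided p value uses the normal reference.
    All-zero features get ``log2fc = 0, pvalue = 1``.
    """
    norm = counts.counts.div(sf, axis=1)
    ctrl_samples = counts.samples_of(CONTROL)
    trt_samples = counts.samples_of(TREATED)
    if len(ctrl_samples) < 2 or len(trt_samples) < 2:
        raise InsufficientDataError("Wald test needs >=2 samples per condition")

    m_c = norm[ctrl_samples].mean(axis=1)
    m_t = norm[trt_samples].mean(axis=1)
    base_mean = norm.mean(axis=1)
    alpha = dispersions.reindex(norm.index)

    log2fc = np.log2((m_t + pseudo_count) / (m_c + pseudo_count))

    inv_s_c = float((1.0 / sf[ctrl_samples]).sum())
    inv_s_t = float((1.0 / sf[trt_samples]).sum())
    n_c, n_t = len(ctrl_samples), len(trt_samples)
    var_mc = m_c * inv_s_c / n_c**2 + alpha * m_c**2 / n_c
    var_mt = m_t * inv_s_t / n_t**2 + alpha * m_t**2 / n_t
    se_log2 = np.sqrt(
        var_mt / (m_t + pseudo_count) ** 2 + var_mc / (m_c + pseudo_count) ** 2
    ) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    pvalue = 2.0 * stats.norm.sf(np.abs(z.to_numpy()))
    pvalue = pd.Series(pvalue, index=norm.index).fillna(1.0)

    degenerate = (counts.counts.sum(axis=1) == 0)
    log2fc[degenerate] = 0.0
    pvalue[degenerate] = 1.0

    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "pvalue": pvalue.clip(0.0, 1.0)}
    )


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (the only supported method)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    if method != "BH":
        raise ValidationError(f"unsupported adjustment method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


def rpm(counts: CountMatrix) -> pd.DataFrame:
    """Reads-per-million per sample: count * 1e6 / column sum."""
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("cannot compute RPM with a zero library size")
    return counts.counts * 1e6 / totals


def rpm_filter(counts: CountMatrix, threshold: float) -> set[str]:
    """Features whose condition-mean RPM reaches ``threshold`` in BOTH conditions."""
    r = rpm(counts)
    mean_c = r[counts.samples_of(CONTROL)].mean(axis=1)
    mean_t = r[counts.samples_of(TREATED)].mean(axis=1)
    kept = (mean_c >= threshold) & (mean_t >= threshold)
    return set(kept.index[kept])


def de_results(
    counts: CountMatrix,
    min_total_count: int = 50,
    max_padj: float = 0.05,
    min_abs_lfc: float = 1.0,
    moderate: bool = True,
) -> pd.DataFrame:
    """Run the full DE chain and annotate each feature with its direction.

    ``direction`` is ``up``/``down`` for features passing all three filters
    (total raw count, adjusted p, |log2FC|, all inclusive) and ``ns``
    otherwise. Rows keep the input feature order.
    """
    sf = size_factors(counts)
    alpha = estimate_dispersion(counts, sf)
    if moderate:
        alpha = moderate_dispersion(alpha)
    wald = nb_wald_test(counts, sf, alpha)
    padj = adjust_pvalues(wald["pvalue"].to_numpy())

    r = rpm(counts)
    res = pd.DataFrame(
        {
            "feature_id": counts.counts.index,
            "base_mean": wald["base_mean"].to_numpy(),
            "log2fc": wald["log2fc"].to_numpy(),
            "pvalue": wald["pvalue"].to_numpy(),
            "padj": padj,
            "total_raw_count": counts.counts.sum(axis=1).to_numpy(),
            "rpm_control": r[counts.samples_of(CONTROL)].mean(axis=1).to_numpy(),
            "rpm_treated": r[counts.samples_of(TREATED)].mean(axis=1).to_numpy(),
        }
    )
    passing = (
        (res["total_raw_count"] >= min_total_count)
        & (res["padj"] <= max_padj)
        & (res["log2fc"].abs() >= min_abs_lfc)
    )
    res["direction"] = np.where(
        passing & (res["log2fc"] > 0), "up", np.where(passing, "down", "ns")
    )
    return res


def filter_de(
    records: pd.DataFrame,
    min_total_count: int = 50,
    max_padj: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (up, down) record tables by the inclusive filters."""
    keep = (
        (records["total_raw_count"] >= min_total_count)
        & (records["padj"] <= max_padj)
        & (records["log2fc"].abs() >= min_abs_lfc)
    )
    kept = records[keep]
    up = kept[kept["log2fc"] > 0].reset_index(drop=True)
    down = kept[kept["log2fc"] < 0].reset_index(drop=True)
    return up, down


def concordance(lfc_a: Mapping[str, float], lfc_b: Mapping[str, float]) -> float:
    """Pearson correlation of two log2FC maps over their shared features."""
    shared = sorted(
        f for f in set(lfc_a) & set(lfc_b)
        if np.isfinite(lfc_a[f]) and np.isfinite(lfc_b[f])
    )
    if len(shared) < 3:
        raise InsufficientDataError(
            f"concordance needs >=3 shared finite features, got {len(shared)}"
        )
    a = np.array([lfc_a[f] for f in shared])
    b = np.array([lfc_b[f] for f in shared])
    return float(stats.pearsonr(a, b).statistic)


def write_de_results(res: pd.DataFrame, path) -> None:
    res.loc[:, DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_de_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing DE columns {sorted(missing)}")
    return df
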