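"""Two-group negative-binomial differential expression on counts.

A deliberately simple NB Wald test: counts are normalized by median-of-ratios
size factors, per-feature dispersions are estimated by method of moments on
the within-group pooled variance and moderated toward the across-feature
median, and the log2 fold-change of group means is tested against a normal
reference using the NB variance model ``Var = mu + alpha * mu^2``.  No
shrinkage of fold-changes, no outlier filtering, no independent filtering —
those belong to full-featured DE packages; here the point is the downstream
thresholding (|log2 FC| >= 1 and p < 0.05) and cluster/pathway use.

A paired variant tests within-patient log-ratios with a one-sample t-test,
matching the paired biopsy design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from irsom.io import CountMatrix, ValidationError

#: Pseudo-mean added to normalized group means before the fold-change log.
EPSILON = 0.5

#: Dispersion floor (features with sub-Poisson moments are clamped here).
MIN_DISPERSION = 1e-8

#: Prior weight (pseudo-degrees-of-freedom) of the across-feature median
#: dispersion in the moderated estimate.
DISPERSION_PRIOR_DF = 20.0


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample column.

    Each sample's factor is the median, over features with a positive
    geometric mean across samples, of count / geometric-mean.  Raises when
    no feature is positive in every sample (a pseudo-reference would then be
    needed; not implemented here).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValidationError("counts must be a 2-D features x samples array")
    if counts.shape[1] == 1:
        return np.ones(1)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no feature has positive counts in all samples; size factors are "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geo = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


def _moderated_dispersion(normalized: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion pooled within groups, shrunk to the median.

    Per feature: ``alpha = (pooled within-group variance - pooled mean) /
    pooled mean^2`` floored at :data:`MIN_DISPERSION`, then moderated as a
    degrees-of-freedom-weighted average with the across-feature median
    (prior weight :data:`DISPERSION_PRIOR_DF`).  Moderation restores the
    normal calibration of the Wald statistic at the small group sizes this
    design has.
    """
    n_total = sum(g.size for g in groups)
    df = n_total - len(groups)
    var_num = np.zeros(normalized.shape[0])
    mean_num = np.zeros(normalized.shape[0])
    for idx in groups:
        block = normalized[:, idx]
        if idx.size > 1:
            var_num += (idx.size - 1) * block.var(axis=1, ddof=1)
        mean_num += block.sum(axis=1)
    pooled_var = var_num / max(df, 1)
    pooled_mean = mean_num / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / np.maximum(pooled_mean, 1e-12) ** 2
    alpha = np.where(np.isfinite(alpha), alpha, MIN_DISPERSION)
    alpha = np.maximum(alpha, MIN_DISPERSION)
    testable = pooled_mean > 0
    prior = float(np.median(alpha[testable])) if testable.any() else MIN_DISPERSION
    return (df * alpha + DISPERSION_PRIOR_DF * prior) / (df + DISPERSION_PRIOR_DF)


def nb_test(
    matrix: CountMatrix,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature differential expression of ``group_b`` over ``group_a``.

    Returns a frame with feature_id, mean_a, mean_b (size-factor-normalized
    group means), log2_fc, p_value, adj_p (Benjamini-Hochberg), significant
    (|log2_fc| >= 1 and raw p < 0.05) and untestable (all-zero in both
    groups; such features get p = 1 and log2_fc = 0).
    """
    cond = design.set_index("sample")["condition"]
    sample_idx = {s: j for j, s in enumerate(matrix.sample_ids)}
    idx_a = np.array(
        [sample_idx[s] for s in matrix.sample_ids if cond.get(s) == group_a], dtype=int
    )
    idx_b = np.array(
        [sample_idx[s] for s in matrix.sample_ids if cond.get(s) == group_b], dtype=int
    )
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {idx_a.size} {group_a!r}, "
            f"{idx_b.size} {group_b!r})"
        )
    used = np.concatenate([idx_a, idx_b])
    factors = np.ones(len(matrix.sample_ids))
    factors[used] = size_factors(matrix.counts[:, used])
    normalized = matrix.counts / factors
    mean_a = normalized[:, idx_a].mean(axis=1)
    mean_b = normalized[:, idx_b].mean(axis=1)
    untestable = (mean_a == 0) & (mean_b == 0)
    log2_fc = np.log2((mean_b + EPSILON) / (mean_a + EPSILON))
    log2_fc[untestable] = 0.0
    if paired:
        p_value = _paired_p(normalized, matrix, design, idx_a, idx_b)
    else:
        alpha = _moderated_dispersion(normalized, [idx_a, idx_b])
        safe_a = np.maximum(mean_a, EPSILON)
        safe_b = np.maximum(mean_b, EPSILON)
        var_mean_a = (safe_a + alpha * safe_a**2) / idx_a.size
        var_mean_b = (safe_b + alpha * safe_b**2) / idx_b.size
        se = np.sqrt(var_mean_a / safe_a**2 + var_mean_b / safe_b**2) / np.log(2.0)
        wald = log2_fc / se
        p_value = 2.0 * stats.norm.sf(np.abs(wald))
    p_value = np.where(untestable, 1.0, p_value)
    adj_p = bh_vector(p_value)
    significant = (np.abs(log2_fc) >= 1.0) & (p_value < 0.05) & ~untestable
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "p_value": p_value,
            "adj_p": adj_p,
            "significant": significant,
            "untestable": untestable,
        }
    )


def _paired_p(
    normalized: np.ndarray,
    matrix: CountMatrix,
    design: pd.DataFrame,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
) -> np.ndarray:
    """One-sample t-test on within-patient log2 ratios (group B over A)."""
    info = design.set_index("sample")
    patients_a = {info.loc[matrix.sample_ids[j], "patient"]: j for j in idx_a}
    patients_b = {info.loc[matrix.sample_ids[j], "patient"]: j for j in idx_b}
    shared = sorted(set(patients_a) & set(patients_b))
    if len(shared) < 2:
        raise ValidationError("paired test needs >= 2 patients present in both groups")
    ratios = np.column_stack(
        [
            np.log2(
                (normalized[:, patients_b[p]] + EPSILON)
                / (normalized[:, patients_a[p]] + EPSILON)
            )
            for p in shared
        ]
    )
    with np.errstate(all="ignore"):
        t_stat, p = stats.ttest_1samp(ratios, 0.0, axis=1)
    return np.where(np.isfinite(p), p, 1.0)


def bh_vector(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (delegates to statsmodels)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method="fdr_bh")[1]


def select_degs(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split significant features into up- and down-regulated sets.

    up: log2_fc >= lfc_threshold and p < p_threshold; down: log2_fc <=
    -lfc_threshold and p < p_threshold.  Disjoint for any positive
    threshold.
    """
    sig = results["p_value"] < p_threshold
    up = set(results.loc[sig & (results["log2_fc"] >= lfc_threshold), "feature_id"])
    down = set(results.loc[sig & (results["log2_fc"] <= -lfc_threshold), "feature_id"])
    return up, down
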