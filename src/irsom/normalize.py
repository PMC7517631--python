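"""TPM normalization, log2 transform, per-condition medians and signal filters.

This stage turns a transcript x sample count matrix into the SOM input: a
per-transcript profile of three condition medians of log2 TPM.  Zeros are
removed, not shifted — a zero TPM yields an undefined (NaN) log2 value and
medians are taken over the defined samples only.  Transcripts with an
all-undefined condition, or whose strongest condition median falls below
``log2(3)``, are filtered out before clustering.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from irsom.io import CONDITIONS, CountMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Low-signal cutoff on log2 TPM (transcripts quieter than TPM=3 everywhere are dropped).
DEFAULT_MIN_LOG2 = math.log2(3.0)

_MEDIAN_COLUMNS = {"pre_ischemia": "p_med", "ischemia": "i_med", "reperfusion": "r_med"}


def compute_tpm(matrix: CountMatrix) -> np.ndarray:
    """Transcripts-per-million for every sample column.

    Per sample: rate_t = count_t / efflen_t, TPM_t = 1e6 * rate_t / sum(rate).
    Non-degenerate columns sum to 1e6; an all-zero sample stays all-zero
    (with a warning) rather than producing NaNs.
    """
    rate = matrix.counts / matrix.efflen_matrix
    totals = rate.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        for j in np.flatnonzero(zero_cols):
            logger.warning("sample %s has zero total counts; TPM left all-zero",
                           matrix.sample_ids[j])
    safe = np.where(zero_cols, 1.0, totals)
    return rate / safe * 1e6


def log2_tpm(tpm: np.ndarray) -> np.ndarray:
    """Elementwise log2 with zeros mapped to NaN (no pseudocount)."""
    tpm = np.asarray(tpm, dtype=float)
    if (tpm < 0).any():
        raise ValidationError("TPM values must be non-negative")
    out = np.full(tpm.shape, np.nan)
    mask = tpm > 0
    out[mask] = np.log2(tpm[mask])
    return out


def condition_medians(
    log2tpm: np.ndarray,
    feature_ids: list[str],
    sample_ids: list[str],
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-transcript median of defined log2 TPM within each condition.

    Returns a frame with columns transcript_id, p_med, i_med, r_med.  A
    condition median is NaN only when every sample of that condition is
    undefined for the transcript.  Even-count medians use the midpoint
    convention.
    """
    assigned = design.set_index("sample")["condition"]
    missing = [s for s in sample_ids if s not in assigned.index]
    if missing:
        raise ValidationError(f"samples {missing[:3]} missing from the design table")
    out = pd.DataFrame({"transcript_id": feature_ids})
    cols = np.asarray(sample_ids)
    for condition in CONDITIONS:
        members = [s for s in sample_ids if assigned[s] == condition]
        if not members:
            raise ValidationError(f"condition {condition!r} has no samples")
        idx = [int(np.flatnonzero(cols == s)[0]) for s in members]
        block = log2tpm[:, idx]
        # all-NaN rows (a condition fully dropped out) are a legitimate
        # outcome here; they are what filter_transcripts removes
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(block, axis=1)
        out[_MEDIAN_COLUMNS[condition]] = med
    return out


def filter_transcripts(
    profiles: pd.DataFrame,
    min_log2: float = DEFAULT_MIN_LOG2,
    aggregation: str = "max",
) -> pd.DataFrame:
    """Zero-removal and low-signal filtering of condition profiles.

    Drops transcripts with any undefined condition median, then those whose
    maximum (or, with ``aggregation='mean'``, mean) condition median is below
    ``min_log2``.  Idempotent; output rows are a subset of input rows.
    """
    value_cols = list(_MEDIAN_COLUMNS.values())
    defined = profiles[value_cols].notna().all(axis=1)
    if aggregation == "max":
        agg = profiles[value_cols].max(axis=1)
    elif aggregation == "mean":
        agg = profiles[value_cols].mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}; use 'max' or 'mean'")
    keep = defined & (agg >= min_log2)
    retained = profiles.loc[keep].reset_index(drop=True)
    if retained.empty:
        logger.warning("low-signal filter retained 0 of %d transcripts", len(profiles))
    return retained


def aggregate_to_genes(matrix: CountMatrix, tx2gene: dict[str, str]) -> CountMatrix:
    """Sum transcript counts into genes; effective length = count-weighted mean.

    Unmapped transcripts are flagged (warning) and carried through under
    their own identifier rather than silently dropped.  When all member
    counts of a gene are zero in a sample the unweighted mean length is used.
    """
    unmapped = [t for t in matrix.feature_ids if t not in tx2gene]
    if unmapped:
        logger.warning(
            "%d transcript(s) absent from the tx2gene map (e.g. %s); kept as their own genes",
            len(unmapped), unmapped[:3],
        )
    gene_of = {t: tx2gene.get(t, t) for t in matrix.feature_ids}
    genes: list[str] = []
    seen: set[str] = set()
    for t in matrix.feature_ids:
        g = gene_of[t]
        if g not in seen:
            seen.add(g)
            genes.append(g)
    gi = {g: i for i, g in enumerate(genes)}
    nf, ns = len(genes), len(matrix.sample_ids)
    counts = np.zeros((nf, ns))
    wlen = np.zeros((nf, ns))
    ulen_sum = np.zeros(nf)
    n_members = np.zeros(nf)
    efflen = matrix.efflen_matrix
    for row, t in enumerate(matrix.feature_ids):
        i = gi[gene_of[t]]
        counts[i] += matrix.counts[row]
        wlen[i] += matrix.counts[row] * efflen[row]
        ulen_sum[i] += efflen[row].mean()
        n_members[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = wlen / counts
    fallback = (ulen_sum / n_members)[:, None]
    mean_len = np.where(counts > 0, mean_len, fallback)
    return CountMatrix(
        feature_ids=genes,
        sample_ids=list(matrix.sample_ids),
        counts=counts,
        effective_lengths=mean_len,
    )
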