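"""Condition-specific selection of SOM modules into trajectory clusters.

Each module's members are summarized by the mean linear-scale TPM per
condition (P-bar, I-bar, R-bar: pre-ischemia, ischemia, reperfusion),
back-transformed from the per-transcript condition medians of log2 TPM.
Four fold-change rules then pick modules into clusters:

* ischemia-up:      log2(I/P) >= t  and  log2(R/P) >= t
* ischemia-down:    log2(I/P) <= -t and  log2(R/P) <= -t
* reperfusion-up:   log2(R/I) >= t  and  log2(R/P) >= t
* reperfusion-down: log2(R/I) <= -t and  log2(R/P) <= -t

with threshold t = 1 (a 2-fold change) by default.  The down rules mirror
the up rules with a negated threshold; ``literal_table1=True`` switches to
a non-mirrored ``<= +t`` variant kept only for comparison, which is
near-vacuous and not used by default.  A module may satisfy an ischemia and
a reperfusion rule simultaneously and is then reported in both clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cluster labels in reporting order.
CLUSTER_LABELS = (
    "C1_ischemia_up",
    "C2_ischemia_down",
    "C3_reperfusion_up",
    "C4_reperfusion_down",
)

_LABEL_TO_RULE = {
    "C1_ischemia_up": ("ischemia", "up"),
    "C2_ischemia_down": ("ischemia", "down"),
    "C3_reperfusion_up": ("reperfusion", "up"),
    "C4_reperfusion_down": ("reperfusion", "down"),
}


@dataclass
class ClusterDefinition:
    """A labeled union of modules selected by one condition-specific rule."""

    label: str
    module_ids: set[int] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)

    @property
    def n_genes(self) -> int:
        return len(self.transcript_ids)


def summarize_modules(
    assignment: dict[str, int],
    profiles: pd.DataFrame,
    n_modules: int,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-module member count and mean condition abundance.

    ``scale='log2'`` (default) averages the members' log2 medians and
    exponentiates — the geometric mean TPM, which weights every member's
    fold-change equally; ``scale='linear'`` averages ``2**median_log2_tpm``
    arithmetically (the literal "mean TPM", dominated by the brightest
    members).  Empty modules carry NaN means.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"unknown module mean scale {scale!r}")
    prof = profiles.set_index("transcript_id")
    missing = [t for t in assignment if t not in prof.index]
    if missing:
        raise ValueError(f"assigned transcripts missing a profile: {missing[:3]}")
    rows = []
    by_module: dict[int, list[str]] = {}
    for tx, module in assignment.items():
        by_module.setdefault(module, []).append(tx)
    for module in range(1, n_modules + 1):
        members = by_module.get(module, [])
        if not members:
            rows.append((module, 0, np.nan, np.nan, np.nan))
            continue
        med = prof.loc[members, ["p_med", "i_med", "r_med"]].to_numpy(dtype=float)
        if scale == "linear":
            bars = np.mean(2.0 ** med, axis=0)
        else:
            bars = 2.0 ** np.mean(med, axis=0)
        rows.append((module, len(members), *bars))
    return pd.DataFrame(
        rows, columns=["module_id", "n_transcripts", "p_bar", "i_bar", "r_bar"]
    )


def apply_criterion(
    summary: pd.Series,
    effect: str,
    direction: str,
    threshold: float = 1.0,
    literal_table1: bool = False,
) -> bool:
    """Evaluate one condition-specific selection rule on a module summary.

    ``summary`` needs fields p_bar, i_bar, r_bar.  Returns False (with a
    warning) when a mean is missing or non-positive, since the log ratios
    are then undefined.
    """
    if effect not in ("ischemia", "reperfusion"):
        raise ValueError(f"unknown effect {effect!r}")
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    bars = np.array([summary["p_bar"], summary["i_bar"], summary["r_bar"]], dtype=float)
    if np.any(~np.isfinite(bars)) or np.any(bars <= 0):
        logger.warning(
            "module %s has undefined or non-positive condition means; excluded",
            summary.get("module_id", "?"),
        )
        return False
    p_bar, i_bar, r_bar = bars
    if effect == "ischemia":
        first = np.log2(i_bar / p_bar)
    else:
        first = np.log2(r_bar / i_bar)
    second = np.log2(r_bar / p_bar)
    if direction == "up":
        return bool(first >= threshold and second >= threshold)
    low = threshold if literal_table1 else -threshold
    return bool(first <= low and second <= low)


def assemble_clusters(
    summaries: pd.DataFrame,
    assignment: dict[str, int],
    threshold: float = 1.0,
    literal_table1: bool = False,
) -> dict[str, ClusterDefinition]:
    """Collect the modules passing each rule, with their member transcripts.

    Returns the four clusters keyed by label; also logs modules selected by
    both an ischemia and a reperfusion rule (the clusters are reported as
    overlapping, not pruned).
    """
    members: dict[int, set[str]] = {}
    for tx, module in assignment.items():
        members.setdefault(module, set()).add(tx)
    clusters = {label: ClusterDefinition(label=label) for label in CLUSTER_LABELS}
    for _, row in summaries.iterrows():
        if row["n_transcripts"] == 0:
            continue
        module = int(row["module_id"])
        for label, (effect, direction) in _LABEL_TO_RULE.items():
            if apply_criterion(row, effect, direction, threshold, literal_table1):
                clusters[label].module_ids.add(module)
                clusters[label].transcript_ids.update(members.get(module, set()))
    overlap = (
        clusters["C1_ischemia_up"].module_ids | clusters["C2_ischemia_down"].module_ids
    ) & (
        clusters["C3_reperfusion_up"].module_ids
        | clusters["C4_reperfusion_down"].module_ids
    )
    if overlap:
        logger.info(
            "modules %s satisfy both an ischemia and a reperfusion rule",
            sorted(overlap),
        )
    return clusters


def cluster_overlap_table(clusters: dict[str, ClusterDefinition]) -> pd.DataFrame:
    """Pairwise module overlaps between clusters (diagnostic output)."""
    labels = list(clusters)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            shared = clusters[a].module_ids & clusters[b].module_ids
            rows.append((a, b, len(shared), ",".join(map(str, sorted(shared)))))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "n_shared_modules", "shared_modules"])


def cluster_trajectory_report(
    clusters: dict[str, ClusterDefinition],
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Mean linear-TPM trajectory of each cluster, relative to pre-ischemia.

    Per cluster: the mean over member transcripts of the per-condition
    linear TPM (2**median log2), divided by the pre-ischemia value so the
    baseline plots at 1.0.  Empty clusters are omitted.
    """
    prof = profiles.set_index("transcript_id")
    rows = []
    for label, cluster in clusters.items():
        if not cluster.transcript_ids:
            continue
        ids = sorted(cluster.transcript_ids)
        med = prof.loc[ids, ["p_med", "i_med", "r_med"]].to_numpy(dtype=float)
        means = np.mean(2.0 ** med, axis=0)
        rows.append((label, 1.0, means[1] / means[0], means[2] / means[0]))
    return pd.DataFrame(
        rows, columns=["cluster", "pre_ischemia", "ischemia", "reperfusion"]
    )
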