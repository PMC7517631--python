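"""Gene-set over-representation: Fisher's exact right tail + Benjamini-Hochberg.

For each cluster and gene set the overlap is tested against the
hypergeometric null: ``p = P(X >= k)`` for ``X ~ Hypergeom(N=n_universe,
K=m_set, n=n_cluster)`` — the one-sided (over-representation) Fisher exact
test.  P-values are adjusted per cluster (the family is all sets tested for
that one cluster) and a set is called enriched when its adjusted p falls
below ``alpha``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from irsom.io import GeneSet, ValidationError
from irsom.select import ClusterDefinition

logger = logging.getLogger(__name__)


def fisher_right_tail(k: int, n_cluster: int, m_set: int, n_universe: int) -> float:
    """Right-tail hypergeometric probability P(X >= k).

    ``X`` counts the overlap of a random ``n_cluster``-subset of a universe
    of ``n_universe`` genes with a fixed set of ``m_set`` genes.  Stable for
    universes up to ~1e6 (log-gamma arithmetic inside scipy).
    """
    if not (0 <= m_set <= n_universe and 0 <= n_cluster <= n_universe):
        raise ValidationError(
            f"inconsistent margins: m_set={m_set}, n_cluster={n_cluster}, "
            f"n_universe={n_universe}"
        )
    if not 0 <= k <= min(n_cluster, m_set):
        raise ValidationError(
            f"overlap k={k} outside [0, min({n_cluster}, {m_set})]"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, m_set, n_cluster))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sets(
    query: set[str],
    sets: Iterable[GeneSet],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set against ``universe``.

    Query genes outside the universe are dropped with a warning; set members
    are intersected with the universe before counting.  Rows are sorted by
    adjusted p then set name.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
    query_in = query & universe
    rows = []
    for gs in sets:
        members = gs.members & universe
        k = len(query_in & members)
        p = fisher_right_tail(k, len(query_in), len(members), len(universe))
        rows.append((gs.name, k, len(query_in), len(members), len(universe), p))
    frame = pd.DataFrame(
        rows,
        columns=["set_name", "k_overlap", "n_cluster", "m_set", "n_universe", "p_value"],
    )
    frame["adj_p"] = bh_adjust(frame["p_value"]) if len(frame) else frame["p_value"]
    frame["enriched"] = frame["adj_p"] < alpha
    return frame.sort_values(["adj_p", "set_name"], kind="mergesort").reset_index(drop=True)


def enrich_clusters(
    clusters: Mapping[str, ClusterDefinition],
    collection: Sequence[GeneSet],
    universe: set[str],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-cluster enrichment tables; BH families are per cluster."""
    return {
        label: enrich_sets(set(cluster.transcript_ids), collection, universe, alpha)
        for label, cluster in clusters.items()
    }
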