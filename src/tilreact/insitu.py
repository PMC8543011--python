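"""In situ classification of single T cells by marker-gene positivity.

Single cells are partitioned by binary positivity of the reactivity
marker genes (*TNFRSF9*, *TNF*, *IFNG*) into the 2^3 combination
clusters, grouped into Triple Negative / Single / Double / Triple
Positive by the count of positive markers, and summarized as
gene-set × cluster Z-score heatmaps.  The same machinery handles the
two-gene tumor-specificity panel (*ENTPD1*, *ITGAE*) and its 4-cluster
partition, plus the 8 × 4 cross-tabulation between the two partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

from .flow import ConfigurationError, ChannelError

logger = logging.getLogger(__name__)

REACTIVITY_MARKERS: tuple[str, ...] = ("TNFRSF9", "TNF", "IFNG")
SPECIFICITY_MARKERS: tuple[str, ...] = ("ENTPD1", "ITGAE")

GROUPED_LABELS: Mapping[int, str] = {
    0: "Triple Negative",
    1: "Single Positive",
    2: "Double Positive",
    3: "Triple Positive",
}
GROUPED_ORDER: tuple[str, ...] = tuple(GROUPED_LABELS[i] for i in range(4))


@dataclass
class FunctionalClusters:
    """Cell partition by a marker-positivity combination.

    ``labels`` assigns each cell its combination label (e.g.
    ``TNFRSF9+TNF-IFNG+``); for three-marker panels ``grouped`` holds
    the Triple Negative / Single / Double / Triple Positive labels
    keyed on the number of positive markers.
    """

    markers: tuple[str, ...]
    labels: pd.Series
    grouped: pd.Series | None = None

    @property
    def cluster_order(self) -> list[str]:
        """All 2^k combination labels, fewest positives first."""
        k = len(self.markers)
        out = []
        for n_pos in range(k + 1):
            for bits in range(2 ** k):
                state = [(bits >> (k - 1 - i)) & 1 for i in range(k)]
                if sum(state) == n_pos:
                    out.append(self._label(state))
        return out

    def _label(self, state: Sequence[int]) -> str:
        return "".join(
            f"{m}{'+' if s else '-'}" for m, s in zip(self.markers, state)
        )

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.cluster_order, fill_value=0)


@dataclass
class ClusterHeatmap:
    """Row-standardized summary of expression across clusters.

    ``zscores`` is genes (or panels) × clusters with each row scaled to
    mean 0 / SD 1 across clusters (population denominator); ``means``
    keeps the underlying per-cluster means.
    """

    zscores: pd.DataFrame
    means: pd.DataFrame


def _expression_frame(adata: ad.AnnData, genes: Sequence[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ChannelError(f"genes absent from the matrix: {missing}")
    X = adata[:, list(genes)].X
    if sparse.issparse(X):
        X = X.toarray()
    return pd.DataFrame(np.asarray(X), index=adata.obs_names, columns=list(genes))


def binarize_markers(
    adata: ad.AnnData, markers: Sequence[str] = REACTIVITY_MARKERS,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Call binary positivity per cell and marker gene.

    A cell is positive when its expression is strictly greater than
    ``threshold`` (default 0: any detected expression counts, the
    natural rule for deep full-length single-cell data).
    """
    expr = _expression_frame(adata, markers)
    return expr > threshold


def assign_clusters(calls: pd.DataFrame) -> FunctionalClusters:
    """Assign each cell to its marker-combination cluster.

    Accepts 2 or 3 boolean marker columns; every cell lands in exactly
    one of the 2^k combination clusters.  For three markers the grouped
    labels (TN/SP/DP/TP) are attached.
    """
    markers = tuple(calls.columns)
    if len(markers) not in (2, 3):
        raise ConfigurationError(f"expected 2 or 3 marker columns, got {len(markers)}")
    parts = [
        np.where(calls[m].to_numpy(), f"{m}+", f"{m}-") for m in markers
    ]
    labels = pd.Series(
        [("".join(p)) for p in zip(*parts)], index=calls.index, name="cluster"
    )
    grouped = None
    if len(markers) == 3:
        n_pos = calls.sum(axis=1)
        grouped = n_pos.map(GROUPED_LABELS).rename("grouped")
    return FunctionalClusters(markers=markers, labels=labels, grouped=grouped)


def _zscore_rows(means: pd.DataFrame) -> pd.DataFrame:
    values = means.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=means.index, columns=means.columns)


def _cluster_means(
    values: pd.DataFrame, labels: pd.Series, order: Sequence[str]
) -> pd.DataFrame:
    means = values.groupby(labels, observed=True).mean()
    present = [c for c in order if c in means.index]
    empty = [c for c in order if c not in means.index]
    if empty:
        logger.warning("dropping empty clusters from heatmap: %s", empty)
    if len(present) < 2:
        raise ConfigurationError("need at least 2 non-empty clusters")
    return means.loc[present].T  # genes × clusters


def cluster_geneset_heatmap(
    adata: ad.AnnData,
    clusters: FunctionalClusters,
    gene_set: Sequence[str],
    use_grouped: bool = False,
) -> ClusterHeatmap:
    """Per-gene per-cluster mean expression, Z-scored across clusters.

    ``use_grouped=True`` summarizes over the TN/SP/DP/TP grouping
    instead of the full combination partition.  Genes constant across
    clusters get an all-zero row; empty clusters are dropped with a
    logged warning.
    """
    labels, order = _labels_and_order(clusters, use_grouped)
    expr = _expression_frame(adata, gene_set)
    means = _cluster_means(expr, labels, order)
    return ClusterHeatmap(zscores=_zscore_rows(means), means=means)


def _labels_and_order(clusters: FunctionalClusters, use_grouped: bool):
    if use_grouped:
        if clusters.grouped is None:
            raise ConfigurationError("grouped labels require a 3-marker partition")
        return clusters.grouped, list(GROUPED_ORDER)
    return clusters.labels, clusters.cluster_order


def normalize_for_scoring(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Per-cell total-count scaling plus log1p, on a copy."""
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def score_signature_panels(
    adata: ad.AnnData,
    clusters: FunctionalClusters,
    panels: Mapping[str, Sequence[str]],
    use_grouped: bool = True,
    normalize: bool = True,
) -> ClusterHeatmap:
    """Summarize signature panels (exhaustion, co-stimulation, ...) per cluster.

    Each panel's per-cell score is the mean normalized expression of its
    genes; scores are averaged per cluster and Z-scored across clusters.
    Panel genes absent from the matrix are dropped with a warning; a
    panel empty after dropping is an error.
    """
    if not panels:
        raise ConfigurationError("no panels supplied")
    source = normalize_for_scoring(adata) if normalize else adata
    labels, order = _labels_and_order(clusters, use_grouped)
    scores = {}
    for name, genes in panels.items():
        present = [g for g in genes if g in source.var_names]
        dropped = sorted(set(genes) - set(present))
        if dropped:
            logger.warning("panel %r: dropping absent genes %s", name, dropped)
        if not present:
            raise ConfigurationError(f"panel {name!r} has no genes in the matrix")
        scores[name] = _expression_frame(source, present).mean(axis=1)
    score_df = pd.DataFrame(scores, index=source.obs_names)
    means = _cluster_means(score_df, labels, order)
    return ClusterHeatmap(zscores=_zscore_rows(means), means=means)


def crosstab_specificity_markers(
    calls_3: pd.DataFrame, calls_2: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate the reactivity and specificity partitions.

    Returns the 8 × 4 contingency table of reactivity combinations
    (rows) vs *ENTPD1*/*ITGAE* clusters (columns) with row and column
    fractions.
    """
    if not calls_3.index.equals(calls_2.index):
        raise ConfigurationError("cell ids differ between the two call matrices")
    c3 = assign_clusters(calls_3)
    c2 = assign_clusters(calls_2)
    counts = (
        pd.crosstab(c3.labels, c2.labels)
        .reindex(index=c3.cluster_order, columns=c2.cluster_order, fill_value=0)
    )
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    col_tot = counts.sum(axis=0).replace(0, np.nan)
    return {
        "counts": counts,
        "row_fractions": counts.div(row_tot, axis=0).fillna(0.0),
        "col_fractions": counts.div(col_tot, axis=1).fillna(0.0),
    }
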