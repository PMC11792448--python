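"""Profiling of unclassified ASVs: contaminants and cross-contamination.

Unclassified ASVs recurring across mock and control samples are mostly
reagent-borne contaminants (the "kitome", dominated by the extraction
buffers) or cross-contamination from co-processed environmental samples.
They are selected by prevalence, k-means clustered on their relative
abundance profiles across all non-environmental samples, and each cluster
is assigned an origin by an explicit ratio rule: a cluster that is
consistently abundant in samples of one extraction buffer but not the
other is labeled with that buffer; one dominated by skin samples is
skin-like; everything else is inconclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import ClassificationResult
from .io import AsvTable, PipelineConfig
from .stats import spearman

logger = logging.getLogger(__name__)

ORIGIN_LABELS = ("buffer_q", "buffer_z", "skin_like", "inconclusive")


def select_prevalent_unclassified(
    table: AsvTable,
    results: dict[str, ClassificationResult],
    min_samples: int = 3,
) -> list[str]:
    """Unclassified ASVs with nonzero counts in >= min_samples non-skin samples."""
    non_skin = [m.sample_id for m in table.metadata if m.sample_class != "skin"]
    counts = table.counts.loc[non_skin]
    out = []
    for asv_id in table.counts.columns:
        if results[asv_id].category != "unclassified":
            continue
        if int((counts[asv_id] > 0).sum()) >= min_samples:
            out.append(asv_id)
    return out


def cluster_contaminants(relabund: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.Series:
    """k-means of contaminant ASV relative-abundance profiles.

    Rows are ASVs, columns samples; raw relative abundances are clustered
    (no standardization). k-means++ with 10 restarts, deterministic for a
    given seed. Fewer ASVs than k reduces k with a warning.
    """
    n = len(relabund)
    if n == 0:
        raise ValueError("no ASVs to cluster")
    if n < k:
        logger.warning("only %d ASVs for k=%d; reducing k", n, k)
        k = n
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(relabund.to_numpy(dtype=float))
    return pd.Series(labels, index=relabund.index, name="cluster")


def label_cluster_origins(
    clusters: pd.Series,
    relabund: pd.DataFrame,
    table: AsvTable,
    ratio_threshold: float = 5.0,
) -> dict[int, str]:
    """Assign each cluster an origin by mean-abundance ratios between sample groups.

    buffer_x: mean relative abundance of the cluster's ASVs in buffer-x
    samples exceeds ratio_threshold times its mean in the other buffer
    (skin samples excluded from the buffer comparison). skin_like: mean in
    skin samples exceeds ratio_threshold times the non-skin mean. Otherwise
    inconclusive. Without skin samples the skin_like label is unavailable.
    """
    meta = {m.sample_id: m for m in table.metadata}
    skin = [s for s in relabund.columns if meta[s].sample_class == "skin"]
    non_skin = [s for s in relabund.columns if meta[s].sample_class != "skin"]
    by_buffer = {
        b: [s for s in non_skin if meta[s].buffer == b]
        for b in ("q", "z")
    }
    eps = 1e-12
    origins: dict[int, str] = {}
    for c in sorted(clusters.unique()):
        asvs = clusters.index[clusters == c]
        block = relabund.loc[asvs]
        mean_q = block[by_buffer["q"]].to_numpy().mean() if by_buffer["q"] else 0.0
        mean_z = block[by_buffer["z"]].to_numpy().mean() if by_buffer["z"] else 0.0
        if mean_q > ratio_threshold * (mean_z + eps):
            origins[c] = "buffer_q"
            continue
        if mean_z > ratio_threshold * (mean_q + eps):
            origins[c] = "buffer_z"
            continue
        if skin:
            mean_skin = block[skin].to_numpy().mean()
            mean_other = block[non_skin].to_numpy().mean() if non_skin else 0.0
            if mean_skin > ratio_threshold * (mean_other + eps):
                origins[c] = "skin_like"
                continue
        origins[c] = "inconclusive"
    return origins


@dataclass
class ContaminantClusterReport:
    asv_clusters: pd.Series  # asv_id -> cluster id
    cluster_origins: dict[int, str]
    fractions: pd.DataFrame  # per-sample contaminant / cross-contaminant fractions


def contamination_fractions(
    table: AsvTable,
    results: dict[str, ClassificationResult],
    accept_lv: int = 4,
    cross_origins: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample contaminant and cross-contaminant read fractions.

    contaminant_fraction is the unclassified read fraction. Cross-
    contamination is directional: in non-mock samples (skin, controls) it is
    the fraction of reads from ASVs accepted as mock taxa; in mock samples
    it is the fraction of unclassified reads whose ASVs sit in skin-like
    clusters (``cross_origins`` maps asv_id -> origin label when cluster
    labels are available).
    """
    rows = []
    mock_classes = {"even_mock", "staggered_mock", "spike_in", "dna_mock"}
    for m in table.metadata:
        counts = table.counts.loc[m.sample_id]
        total = counts.sum()
        if total == 0:
            rows.append({"sample_id": m.sample_id, "contaminant_fraction": np.nan, "cross_fraction": np.nan})
            continue
        unclassified = sum(
            counts[a] for a in counts.index if results[a].category == "unclassified"
        )
        mock_reads = sum(
            counts[a]
            for a in counts.index
            if results[a].min_lv <= accept_lv and results[a].category in ("exact", "sequence_error")
        )
        if m.sample_class in mock_classes:
            if cross_origins:
                cross = sum(
                    counts[a]
                    for a in counts.index
                    if cross_origins.get(a) == "skin_like"
                )
            else:
                cross = 0
        else:
            cross = mock_reads
        rows.append({
            "sample_id": m.sample_id,
            "contaminant_fraction": unclassified / total,
            "cross_fraction": cross / total,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def correlate_fraction_with_input(fractions, input_cells) -> tuple[float, float]:
    """Spearman correlation of a per-sample read fraction with input cell number.

    Tie-corrected rho; two-sided p exact (full permutation enumeration) for
    n <= 9, large-sample otherwise.
    """
    return spearman(fractions, input_cells)


def profile_contaminants(
    table: AsvTable,
    results: dict[str, ClassificationResult],
    config: PipelineConfig,
    seed: int = 0,
) -> ContaminantClusterReport:
    """Full contaminant workflow: prevalence filter, cluster, label, fractions."""
    subset = select_prevalent_unclassified(table, results, config.min_prevalence)
    if subset:
        totals = table.counts.sum(axis=1).replace(0, np.nan)
        relabund = table.counts[subset].div(totals, axis=0).fillna(0.0).T  # ASVs x samples
        # clustering features are the mock and control samples; skin samples
        # only enter afterwards, to assign skin origin
        non_skin = [m.sample_id for m in table.metadata if m.sample_class != "skin"]
        clusters = cluster_contaminants(relabund[non_skin], k=config.kmeans_k, seed=seed)
        origins = label_cluster_origins(clusters, relabund, table, config.origin_ratio_threshold)
        cross_origins = {a: origins[clusters[a]] for a in subset}
    else:
        clusters = pd.Series(dtype=int, name="cluster")
        origins = {}
        cross_origins = {}
    fractions = contamination_fractions(table, results, config.accept_lv, cross_origins)
    return ContaminantClusterReport(asv_clusters=clusters, cluster_origins=origins, fractions=fractions)
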