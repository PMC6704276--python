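"""Label-free microproteomics statistics for the microdissected segments.

Downstream of protein identification and MaxLFQ quantification, each
segment contributes one LFQ intensity column.  Processing mirrors the
standard Perseus-style workflow: drop quality-control-flagged rows
(decoy "reverse" hits, "only identified by site", "potential contaminant"),
log2-transform, z-score each protein across segments, call a protein
exclusively over-expressed in a segment when only that segment's z-score
reaches +1 (under-expression symmetric at −1), and order the proteins by
complete-linkage hierarchical clustering with a k-means pre-clustering step
(default 300 clusters, 10 iterations, 1 restart).

Zero or missing LFQ values are treated as missing, not as ``log2(0)``; rows
with fewer than ``min_valid`` finite values are excluded and reported.
With only three segments the attainable |z| is bounded by 2/√3 ≈ 1.1547
(sample SD), so the ±1 threshold sits close to the ceiling — see the
methods note for the consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ("reverse", "only_identified_by_site", "potential_contaminant")

#: MaxQuant proteinGroups column names for the three QC flags.
MAXQUANT_FLAG_COLUMNS = {
    "Reverse": "reverse",
    "Only identified by site": "only_identified_by_site",
    "Potential contaminant": "potential_contaminant",
}


@dataclass
class ProteinTable:
    """Proteins × segments LFQ intensities with QC flags.

    ``intensities`` is a DataFrame indexed by protein id with one column per
    segment; ``flags`` is a boolean DataFrame with the three QC flag columns.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape[1] < 2:
            raise ValueError("at least 2 segment columns are required")
        if not self.intensities.index.is_unique:
            raise ValueError("protein ids must be unique")
        if not np.isfinite(self.intensities.to_numpy()).all():
            raise ValueError("intensities must be finite (use 0 for missing)")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("LFQ intensities must be >= 0")
        missing = [c for c in FLAG_COLUMNS if c not in self.flags.columns]
        if missing:
            raise ValueError(f"flags lacks columns: {missing}")
        self.flags = self.flags.reindex(self.intensities.index).fillna(False).astype(bool)

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def segment_names(self) -> list[str]:
        return list(self.intensities.columns)

    @classmethod
    def read_maxquant(cls, path: str | Path) -> "ProteinTable":
        """Read a MaxQuant-style proteinGroups TSV.

        Expects ``Protein IDs``, the three flag columns marked with ``+``,
        and one ``LFQ intensity <segment>`` column per segment.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "Protein IDs" not in df.columns:
            raise ValueError(f"{path}: missing 'Protein IDs' column")
        lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
        if len(lfq_cols) < 2:
            raise ValueError(f"{path}: need >= 2 'LFQ intensity <segment>' columns")
        intens = df[lfq_cols].astype(float)
        intens.columns = [c[len("LFQ intensity "):] for c in lfq_cols]
        intens.index = pd.Index(df["Protein IDs"], name="protein_id")
        flags = pd.DataFrame(index=intens.index)
        for col, name in MAXQUANT_FLAG_COLUMNS.items():
            flags[name] = (
                df[col].fillna("").str.strip().eq("+").to_numpy()
                if col in df.columns
                else False
            )
        return cls(intensities=intens, flags=flags)


def filter_flagged(table: ProteinTable) -> tuple[ProteinTable, dict]:
    """Remove rows carrying any QC flag.

    Returns the filtered table and a per-flag removal report; a row with
    several flags is removed once but counted under each flag.
    """
    flagged = table.flags[list(FLAG_COLUMNS)].any(axis=1)
    report = {c: int(table.flags[c].sum()) for c in FLAG_COLUMNS}
    report["removed"] = int(flagged.sum())
    kept = table.intensities.loc[~flagged]
    if flagged.any():
        logger.info("filter_flagged: removed %d row(s): %s", report["removed"], report)
    return ProteinTable(intensities=kept, flags=table.flags.loc[~flagged]), report


@dataclass
class ZScoreResult:
    """Row-wise z-scores plus the bookkeeping of excluded / constant rows."""

    z: pd.DataFrame
    constant_ids: list
    excluded_ids: list


def log2_zscore(
    table: ProteinTable,
    min_valid: int = 2,
    ddof: int = 1,
) -> ZScoreResult:
    """Log2-transform and z-score each protein across segments.

    Zeros are treated as missing.  Rows with fewer than ``min_valid`` finite
    log2 values are excluded and reported; constant rows get z = 0
    everywhere and are flagged.  ``ddof=1`` (sample SD) by default, ``ddof=0``
    for the population-SD variant.
    """
    x = table.intensities.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), np.nan)
    n_valid = np.isfinite(logx).sum(axis=1)
    keep = n_valid >= max(min_valid, ddof + 1)
    excluded = list(table.protein_ids[~keep])
    if excluded:
        logger.info("log2_zscore: excluded %d row(s) with < %d valid values",
                    len(excluded), min_valid)
    logx = logx[keep]
    mean = np.nanmean(logx, axis=1, keepdims=True)
    sd = np.nanstd(logx, axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    z = (logx - mean) / sd
    z[constant] = np.where(np.isfinite(logx[constant]), 0.0, np.nan)
    zdf = pd.DataFrame(z, index=table.protein_ids[keep], columns=table.segment_names)
    return ZScoreResult(
        z=zdf,
        constant_ids=list(zdf.index[constant]),
        excluded_ids=excluded,
    )


@dataclass(frozen=True)
class RegulationCall:
    """An exclusive regulation call: one protein, one segment, one direction."""

    protein_id: str
    segment: str
    direction: Literal["over", "under"]


def classify_exclusive(z: pd.DataFrame, threshold: float = 1.0) -> list[RegulationCall]:
    """Exclusive over/under-expression calls at ``±threshold``.

    A protein is called over-expressed in segment ``s`` iff ``z(s) >=
    threshold`` and ``z(t) < threshold`` for every other segment ``t``;
    under-expression is symmetric at ``-threshold``.  A protein crossing the
    bound in two or more segments yields no call in that direction.  NaN
    entries never cross the bound.
    """
    calls: list[RegulationCall] = []
    zv = z.to_numpy()
    over = np.nan_to_num(zv, nan=-np.inf) >= threshold
    under = np.nan_to_num(zv, nan=np.inf) <= -threshold
    for mat, direction in ((over, "over"), (under, "under")):
        exclusive = mat.sum(axis=1) == 1
        rows, cols = np.nonzero(mat & exclusive[:, None])
        for r, c in zip(rows, cols):
            calls.append(RegulationCall(str(z.index[r]), str(z.columns[c]), direction))
    return calls


def calls_to_frame(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.protein_id, c.segment, c.direction) for c in calls],
        columns=["protein_id", "segment", "direction"],
    )


@dataclass
class ClusteringResult:
    """Complete-linkage dendrogram over k-means centroids plus the row order."""

    linkage_matrix: np.ndarray  # scipy linkage over centroids
    centroid_of_row: np.ndarray  # centroid index per protein row
    row_order: np.ndarray  # protein row indices in leaf order
    row_ids: list

    def to_newick(self) -> str:
        """Newick serialization of the centroid dendrogram (leaves are
        centroid ids ``c<i>``)."""
        from skbio.tree import TreeNode

        n = len(self.linkage_matrix) + 1
        tree = TreeNode.from_linkage_matrix(
            self.linkage_matrix, [f"c{i}" for i in range(n)]
        )
        return str(tree).strip()


def hierarchical_cluster(
    z: pd.DataFrame,
    n_pre_clusters: int = 300,
    kmeans_iterations: int = 10,
    kmeans_restarts: int = 1,
    seed: int = 0,
) -> ClusteringResult:
    """Complete-linkage Euclidean clustering with k-means preprocessing.

    Rows are first partitioned into ``min(n_pre_clusters, n_rows)`` groups
    by seeded k-means (capped iterations, given restarts); the centroids are
    then clustered agglomeratively (complete linkage, Euclidean).  Each
    protein inherits its centroid's leaf position; within a centroid the
    original row order is kept.
    """
    x = z.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("clustering needs at least 2 proteins")
    x = np.nan_to_num(x, nan=0.0)  # missing entries contribute no distance
    n_clusters = min(n_pre_clusters, len(x))
    km = KMeans(
        n_clusters=n_clusters,
        init="random",
        n_init=kmeans_restarts,
        max_iter=kmeans_iterations,
        random_state=seed,
    ).fit(x)
    centroids = km.cluster_centers_
    if n_clusters == 1:
        raise ValueError("pre-clustering collapsed to a single centroid")
    lk = linkage(centroids, method="complete", metric="euclidean")
    leaf_order = leaves_list(lk)
    rank = np.empty(n_clusters, dtype=int)
    rank[leaf_order] = np.arange(n_clusters)
    row_order = np.lexsort((np.arange(len(x)), rank[km.labels_]))
    return ClusteringResult(
        linkage_matrix=lk,
        centroid_of_row=km.labels_,
        row_order=row_order,
        row_ids=list(z.index),
    )
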