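"""Tissue Expression Clustering: UMAP -> density-seeded k-means -> merging.

The gene-level clustering pipeline:

1. log10(TMM + 1) transform of the sample-wise TMM-corrected matrix,
   Z-scored per gene (rows with zero SD are set to all-zero).
2. 2-D UMAP embedding of the Z-scores (n_neighbors=15, n_epochs=1000,
   no input rescaling), deterministic for a fixed seed.
3. k-means seeding: DBSCAN (eps=0.1, min_pts=5) on the embedding yields
   one center per density cluster (its centroid); the two largest density
   clusters receive extra centers, drawn by seeded sampling of member
   coordinates in proportion to the cluster's approximate area (convex
   hull), so large clouds are not underfit by a single center.
4. Lloyd k-means from exactly those centers (no re-initialization),
   at most ``kmeans_iterations`` rounds; empty clusters are dropped.
5. Enrichment-guided merging: clusters significantly enriched
   (BH-adjusted p < merge_alpha) for the same non-empty tissue set and
   spatially adjacent are merged; repeated until a fixed point.  Final
   cluster-tissue associations are recomputed at association_alpha.

The result assigns every gene to exactly one Tissue Expression Cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .datatypes import ExpressionMatrix, PipelineConfig, Stage
from .enrichment import cluster_tissue_enrichment

logger = logging.getLogger(__name__)


def zscore_transform(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z-score of log10(value + 1); zero-SD rows become all zero."""
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    logged = np.log10(data.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    # constant rows can yield sd ~ 1e-16 from float round-off, not exactly 0
    zero = sd <= 1e-10 * (1.0 + np.abs(mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[np.broadcast_to(zero, z.shape)] = 0.0
    return pd.DataFrame(z, index=data.index, columns=data.columns)


@dataclass
class Embedding:
    """2-D gene embedding with the parameters that produced it."""

    coords: pd.DataFrame  # columns x, y; index = gene ids
    n_neighbors: int
    n_epochs: int
    seed: int

    def __post_init__(self) -> None:
        if list(self.coords.columns) != ["x", "y"]:
            raise ValueError("embedding coords must have columns ['x', 'y']")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("embedding coordinates must be finite")


def embed_umap(z: pd.DataFrame, cfg: PipelineConfig, seed: int | None = None) -> Embedding:
    """Project gene Z-score profiles onto two dimensions with UMAP.

    Inputs are used as-is (no internal rescaling).  A fixed seed makes the
    embedding deterministic (UMAP falls back to single-threaded layout).
    """
    import umap

    seed = cfg.random_seed if seed is None else seed
    if z.shape[0] < cfg.umap_n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {cfg.umap_n_neighbors + 1} genes, got {z.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=cfg.umap_n_neighbors,
            n_epochs=cfg.umap_n_epochs,
            min_dist=cfg.umap_min_dist,
            random_state=seed,
        )
        xy = reducer.fit_transform(z.to_numpy(dtype=np.float32))
    coords = pd.DataFrame(np.asarray(xy, dtype=float), index=z.index, columns=["x", "y"])
    return Embedding(coords, cfg.umap_n_neighbors, cfg.umap_n_epochs, seed)


@dataclass
class SeedCenters:
    """Initial k-means centers with per-center provenance."""

    centers: np.ndarray  # (k, 2)
    provenance: list[str] = field(default_factory=list)  # density_centroid | area_sample
    dbscan_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.centers) < 1:
            raise ValueError("need at least one center")


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2-D point set; 0 for degenerate sets."""
    unique = np.unique(points, axis=0)
    if len(unique) < 3:
        return 0.0
    try:
        return float(ConvexHull(unique).volume)  # 2-D: volume is the area
    except QhullError:
        return 0.0


def seed_centers(emb: Embedding, cfg: PipelineConfig, seed: int | None = None) -> SeedCenters:
    """DBSCAN-derived k-means centers, with area-proportional extras.

    One center at the centroid of every density cluster; the two largest
    clusters (by member count) receive round(area / area_unit) additional
    centers sampled from their member coordinates.  area_unit defaults to
    (total hull area of all density clusters) / 50.  Noise points are
    ignored for seeding.  Zero density clusters fall back to one global
    centroid with a warning.
    """
    seed = cfg.random_seed if seed is None else seed
    xy = emb.coords.to_numpy()
    db = DBSCAN(eps=cfg.dbscan_eps, min_samples=cfg.dbscan_min_pts).fit(xy)
    labels = db.labels_
    cluster_ids = sorted(set(labels) - {-1})
    if not cluster_ids:
        warnings.warn("DBSCAN found no density clusters; falling back to the global centroid")
        return SeedCenters(xy.mean(axis=0, keepdims=True), ["density_centroid"], labels)
    members = {c: xy[labels == c] for c in cluster_ids}
    centers = [members[c].mean(axis=0) for c in cluster_ids]
    provenance = ["density_centroid"] * len(cluster_ids)
    areas = {c: _hull_area(members[c]) for c in cluster_ids}
    total_area = sum(areas.values())
    if total_area > 0:
        area_unit = cfg.area_unit if cfg.area_unit is not None else total_area / 50.0
        rng = np.random.default_rng(seed)
        two_largest = sorted(cluster_ids, key=lambda c: (-len(members[c]), c))[:2]
        for c in two_largest:
            n_extra = int(round(areas[c] / area_unit))
            if n_extra <= 0:
                continue
            pool = members[c]
            replace = n_extra > len(pool)
            idx = rng.choice(len(pool), size=n_extra, replace=replace)
            for i in idx:
                centers.append(pool[i])
                provenance.append("area_sample")
        logger.info(
            "seed_centers: %d density clusters, %d extra area-sampled centers (area_unit=%.4g)",
            len(cluster_ids), provenance.count("area_sample"), area_unit,
        )
    return SeedCenters(np.asarray(centers, dtype=float), provenance, labels)


def kmeans_partition(
    emb: Embedding, centers: SeedCenters | np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    """Lloyd k-means from the given centers; labels are 1-based contiguous.

    No re-initialization: iteration starts exactly from the seed centers
    and stops at convergence or after ``kmeans_iterations`` rounds.
    Centers that lose all their points are dropped with a warning.
    """
    xy = emb.coords.to_numpy()
    mu = np.array(centers.centers if isinstance(centers, SeedCenters) else centers, dtype=float)
    if len(mu) < 1:
        raise ValueError("need at least one center")
    labels = None
    for _ in range(cfg.kmeans_iterations):
        assign = np.argmin(cdist(xy, mu), axis=1)
        occupied = np.unique(assign)
        if len(occupied) < len(mu):
            warnings.warn(f"dropped {len(mu) - len(occupied)} empty k-means cluster(s)")
            remap = {old: new for new, old in enumerate(occupied)}
            assign = np.array([remap[a] for a in assign])
            mu = mu[occupied]
        new_mu = np.vstack([xy[assign == j].mean(axis=0) for j in range(len(mu))])
        if labels is not None and np.array_equal(assign, labels) and np.allclose(new_mu, mu):
            break
        labels, mu = assign, new_mu
    return labels + 1


@dataclass
class ClusterAssignment:
    """Final Tissue Expression Cluster membership and per-cluster summary."""

    gene_ids: pd.Index
    labels: np.ndarray  # 1-based contiguous cluster ids
    clusters: pd.DataFrame  # cluster_id, n_genes, centroid_x/y, significant_tissues, min_fdr
    enrichment: pd.DataFrame  # final cluster x tissue tests at association_alpha
    merge_rounds: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("one label per gene required")
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("cluster ids must be contiguous integers from 1")
        if len(self.clusters) and int(self.clusters["n_genes"].sum()) != len(self.gene_ids):
            raise ValueError("cluster member counts must sum to the gene count")

    @property
    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="cluster_id")

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    def to_gene_frame(self, emb: Embedding | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.gene_ids, "cluster_id": self.labels})
        if emb is not None:
            out.insert(1, "x", emb.coords["x"].to_numpy())
            out.insert(2, "y", emb.coords["y"].to_numpy())
        return out


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    mapping = {old: new for new, old in enumerate(sorted(set(labels)), start=1)}
    return np.array([mapping[l] for l in labels])


def _significant_sets(
    labels: pd.Series, spec_calls: pd.DataFrame, cfg: PipelineConfig, alpha: float
) -> tuple[dict[int, frozenset[str]], pd.DataFrame]:
    table = cluster_tissue_enrichment(labels, spec_calls, cfg, alpha=alpha)
    sets: dict[int, frozenset[str]] = {int(c): frozenset() for c in np.unique(labels)}
    if len(table):
        for cluster_id, sub in table[table["significant"]].groupby("cluster_id"):
            sets[int(cluster_id)] = frozenset(sub["tissue"])
    return sets, table


def _adjacent(xy: np.ndarray, labels: np.ndarray, a: int, b: int, eps: float) -> bool:
    pa = xy[labels == a]
    pb = xy[labels == b]
    # chunk the distance computation to bound memory on large clusters
    step = 2048
    for i in range(0, len(pa), step):
        if cdist(pa[i : i + step], pb).min() <= eps:
            return True
    return False


def merge_adjacent_clusters(
    labels: np.ndarray,
    emb: Embedding,
    spec_calls: pd.DataFrame,
    cfg: PipelineConfig,
) -> ClusterAssignment:
    """Merge adjacent clusters enriched for identical tissue sets.

    Each round tests every cluster x tissue pair (BH across the round's
    batch), derives the significant-tissue set per cluster at merge_alpha,
    and merges every adjacent pair whose non-empty sets are equal (merging
    is transitive within a round via connected components).  Rounds repeat
    until no merge applies; the loop terminates because the cluster count
    strictly decreases.  Final associations are recomputed at
    association_alpha and clusters renumbered contiguously.
    """
    labels = _relabel_contiguous(np.asarray(labels))
    xy = emb.coords.to_numpy()
    eps = cfg.effective_adjacency_eps
    rounds = 0
    while True:
        label_series = pd.Series(labels, index=emb.coords.index)
        sets, _ = _significant_sets(label_series, spec_calls, cfg, cfg.merge_alpha)
        cluster_ids = sorted(sets)
        parent = {c: c for c in cluster_ids}

        def find(c: int) -> int:
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        merged_any = False
        for i, a in enumerate(cluster_ids):
            if not sets[a]:
                continue  # empty significant sets never trigger merges
            for b in cluster_ids[i + 1 :]:
                if sets[a] != sets[b]:
                    continue
                if find(a) == find(b):
                    continue
                if _adjacent(xy, labels, a, b, eps):
                    parent[find(b)] = find(a)
                    merged_any = True
        if not merged_any:
            break
        rounds += 1
        labels = _relabel_contiguous(np.array([find(c) for c in labels]))
        logger.info("merge round %d -> %d clusters", rounds, len(set(labels)))

    label_series = pd.Series(labels, index=emb.coords.index)
    final_sets, final_table = _significant_sets(
        label_series, spec_calls, cfg, cfg.association_alpha
    )
    summaries = []
    for c in sorted(final_sets):
        members = xy[labels == c]
        sub = final_table[final_table["cluster_id"] == c] if len(final_table) else final_table
        summaries.append(
            {
                "cluster_id": c,
                "n_genes": int((labels == c).sum()),
                "centroid_x": float(members[:, 0].mean()),
                "centroid_y": float(members[:, 1].mean()),
                "significant_tissues": sorted(final_sets[c]),
                "min_fdr": float(sub["fdr"].min()) if len(sub) else float("nan"),
            }
        )
    clusters = pd.DataFrame(
        summaries,
        columns=["cluster_id", "n_genes", "centroid_x", "centroid_y", "significant_tissues", "min_fdr"],
    )
    return ClusterAssignment(emb.coords.index, labels, clusters, final_table, rounds)


def run_tissue_expression_clustering(
    sample_tmm: ExpressionMatrix,
    spec_calls: pd.DataFrame,
    cfg: PipelineConfig,
    seed: int | None = None,
    merge: bool = True,
) -> tuple[Embedding, ClusterAssignment]:
    """Full pipeline: Z-score -> UMAP -> seeded k-means -> merging."""
    seed = cfg.random_seed if seed is None else seed
    if sample_tmm.stage not in (Stage.tmm, Stage.ptpm, Stage.tpm):
        raise ValueError("clustering expects a sample-level (TMM-corrected) matrix")
    z = zscore_transform(sample_tmm)
    emb = embed_umap(z, cfg, seed)
    centers = seed_centers(emb, cfg, seed)
    labels = kmeans_partition(emb, centers, cfg)
    logger.info(
        "clustering: %d genes, %d seed centers, %d k-means clusters",
        len(labels), len(centers.centers), len(set(labels)),
    )
    if merge:
        assignment = merge_adjacent_clusters(labels, emb, spec_calls, cfg)
    else:
        label_series = pd.Series(labels, index=emb.coords.index)
        sets, table = _significant_sets(label_series, spec_calls, cfg, cfg.association_alpha)
        xy = emb.coords.to_numpy()
        clusters = pd.DataFrame(
            [
                {
                    "cluster_id": c,
                    "n_genes": int((labels == c).sum()),
                    "centroid_x": float(xy[labels == c, 0].mean()),
                    "centroid_y": float(xy[labels == c, 1].mean()),
                    "significant_tissues": sorted(sets[c]),
                    "min_fdr": float("nan"),
                }
                for c in sorted(sets)
            ]
        )
        assignment = ClusterAssignment(emb.coords.index, labels, clusters, table, 0)
    logger.info("final assignment: %d clusters", assignment.n_clusters)
    return emb, assignment
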