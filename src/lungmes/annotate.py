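"""Leiden clustering, doublet exclusion, marker-rule subtype assignment,
atlas co-embedding, and PCA-ellipse reannotation.

Clustering runs Leiden community detection on the k-nearest-neighbor
graph in PC space.  Doublets are excluded the classic way: small clusters
and single cells coexpressing markers of incompatible cell types.
Subtypes are assigned per cluster from an ordered marker-rule table;
clusters matching no rule but positive for the Acta1 panel are reported
as novel hyperoxia-associated populations.
"""

from __future__ import annotations

import dataclasses

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.neighbors import NearestNeighbors

from .io_core import CountMatrix, NormalizedMatrix
from .preprocess import Embedding, EmbeddingParams, embed_pca, normalize_cpm, select_features
from .rules import GROUP_DOUBLET, GROUP_NOVEL, HA_PANEL, MarkerRule

#: cluster-level positivity: a gene is "positive" in a cluster when its
#: mean CPM and expressing-cell fraction both clear these thresholds.
#: A cell counts as expressing only above a small CPM floor so that
#: stray single-molecule counts of silent genes do not qualify.
POSITIVITY_MEAN_CPM = 50.0
POSITIVITY_FRACTION = 0.25
POSITIVITY_EXPRESSING_CPM = 10.0

#: per-cell coexpression threshold for doublet flagging
DOUBLET_CPM = 100.0
MIN_CLUSTER_SIZE = 10


def knn_graph(coords: np.ndarray, n_neighbors: int) -> igraph.Graph:
    """Undirected unweighted kNN graph (Euclidean) over the rows of coords."""
    n = coords.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_leiden(
    embedding: Embedding,
    n_neighbors: int = 10,
    resolution: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels on the kNN graph, renumbered by decreasing size."""
    g = knn_graph(embedding.coords, n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


def _positive_cells(nm: NormalizedMatrix, genes, threshold: float) -> np.ndarray:
    """Boolean (cells,) — cell expresses at least one of ``genes`` above threshold."""
    present = [g for g in genes if g in set(nm.gene_ids)]
    if not present:
        return np.zeros(nm.n_cells, dtype=bool)
    gi = nm.gene_index(present)
    return (nm.values[gi, :] > threshold).any(axis=0)


def flag_doublets(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    incompatible_pairs: list[tuple[frozenset, frozenset]],
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    cpm_threshold: float = DOUBLET_CPM,
) -> np.ndarray:
    """Flag cells in small clusters or coexpressing incompatible markers."""
    labels = np.asarray(labels)
    if labels.shape != (nm.n_cells,):
        raise ValueError("labels must cover all cells")
    flags = np.zeros(nm.n_cells, dtype=bool)
    sizes = pd.Series(labels).value_counts()
    small = {c for c in sizes.index if sizes[c] < min_cluster_size}
    if small:
        flags |= np.isin(labels, list(small))
    for side_a, side_b in incompatible_pairs:
        pa = _positive_cells(nm, side_a, cpm_threshold)
        pb = _positive_cells(nm, side_b, cpm_threshold)
        flags |= pa & pb
    return flags


def cluster_positivity(
    nm: NormalizedMatrix,
    cell_mask: np.ndarray,
    mean_cpm: float = POSITIVITY_MEAN_CPM,
    frac: float = POSITIVITY_FRACTION,
    expressing_cpm: float = POSITIVITY_EXPRESSING_CPM,
) -> set[str]:
    """Genes positive in the masked cell population (mean CPM AND fraction)."""
    vals = nm.values[:, cell_mask]
    means = vals.mean(axis=1)
    fracs = (vals > expressing_cpm).mean(axis=1)
    pos = (means > mean_cpm) & (fracs > frac)
    return {g for g, p in zip(nm.gene_ids, pos) if p}


def assign_subtypes(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    rules: list[MarkerRule],
    doublet_flags: np.ndarray | None = None,
    ha_panel: tuple[str, ...] = HA_PANEL,
    mean_cpm: float = POSITIVITY_MEAN_CPM,
    frac: float = POSITIVITY_FRACTION,
) -> pd.DataFrame:
    """Assign each cluster the first rule whose positives/negatives all hold.

    Returns the AnnotationTable: one row per cell with columns cell_id,
    cluster_id, group, subtype, proliferating, doublet.  Doublet cells get
    no subtype; clusters matching no rule but positive for the whole
    Acta1 panel are labeled ``HA-novel-k``.
    """
    if not rules:
        raise ValueError("empty rule list")
    labels = np.asarray(labels)
    if doublet_flags is None:
        doublet_flags = np.zeros(nm.n_cells, dtype=bool)
    doublet_flags = np.asarray(doublet_flags, dtype=bool)

    cluster_subtype: dict[int, tuple[str, str, bool]] = {}
    ha_counter = 0
    for cl in sorted(set(labels.tolist())):
        mask = (labels == cl) & ~doublet_flags
        if not mask.any():
            cluster_subtype[cl] = ("unassigned", GROUP_NOVEL, False)
            continue
        positive = cluster_positivity(nm, mask, mean_cpm, frac)
        proliferating = "Mki67" in positive
        assigned = None
        for rule in rules:
            if rule.required_positive <= positive and not (
                rule.required_negative & positive
            ):
                assigned = (rule.subtype, rule.group, proliferating)
                break
        if assigned is None:
            if set(ha_panel) <= positive:
                ha_counter += 1
                assigned = (f"HA-novel-{ha_counter}", GROUP_NOVEL, proliferating)
            else:
                assigned = ("unassigned", GROUP_NOVEL, proliferating)
        cluster_subtype[cl] = assigned

    rows = []
    for i, cell in enumerate(nm.cell_ids):
        cl = int(labels[i])
        if doublet_flags[i]:
            rows.append(
                {
                    "cell_id": cell,
                    "cluster_id": cl,
                    "group": GROUP_DOUBLET,
                    "subtype": "",
                    "proliferating": False,
                    "doublet": True,
                }
            )
        else:
            subtype, group, prolif = cluster_subtype[cl]
            rows.append(
                {
                    "cell_id": cell,
                    "cluster_id": cl,
                    "group": group,
                    "subtype": subtype,
                    "proliferating": prolif,
                    "doublet": False,
                }
            )
    ann = pd.DataFrame.from_records(rows)
    ann = ann.merge(
        nm.cell_meta.reset_index()[["cell_id", "timepoint", "condition", "mouse_id"]],
        on="cell_id",
    )
    return ann


@dataclasses.dataclass
class JointEmbedding:
    """Co-embedding of query + atlas cells with per-cell source tags."""

    coords: np.ndarray
    cell_ids: list[str]
    source: np.ndarray  # "query" or "atlas" per cell
    feature_genes: list[str]
    params: EmbeddingParams


def harmonize_embed(
    query: CountMatrix,
    atlas: CountMatrix,
    params: EmbeddingParams = EmbeddingParams(),
    k: int = 10,
) -> JointEmbedding:
    """Joint PCA on the shared gene space + batch-balanced kNN smoothing.

    Each cell's coordinates are averaged with its nearest neighbors drawn
    equally from each source (ceil(k/2) per source, k total), which pulls
    same-type cells from the two sources together without any model of
    the batch effect.  k=0 degenerates to plain joint PCA.
    """
    shared = [g for g in query.gene_ids if g in set(atlas.gene_ids)]
    if not shared:
        raise ValueError("query and atlas share no genes")
    qi = [query.gene_ids.index(g) for g in shared]
    ai = [atlas.gene_ids.index(g) for g in shared]
    counts = np.concatenate([query.counts[qi, :], atlas.counts[ai, :]], axis=1)
    cell_ids = [f"query:{c}" for c in query.cell_ids] + [
        f"atlas:{c}" for c in atlas.cell_ids
    ]
    meta = pd.concat(
        [query.cell_meta.reset_index(drop=True), atlas.cell_meta.reset_index(drop=True)],
        ignore_index=True,
    )
    # prefix mouse ids so sources never share a "mouse" in feature selection
    src = np.array(["query"] * query.n_cells + ["atlas"] * atlas.n_cells)
    meta = meta.copy()
    meta["mouse_id"] = [f"{s}:{m}" for s, m in zip(src, meta["mouse_id"])]
    joint = CountMatrix(counts=counts, gene_ids=shared, cell_ids=cell_ids, cell_meta=meta)
    nm = normalize_cpm(joint)
    eff = dataclasses.replace(
        params,
        n_features=min(params.n_features, len(shared)),
        n_pcs=min(params.n_pcs, min(params.n_features, len(shared)) - 1),
    )
    features = select_features(nm, eff)
    if len(features) <= eff.n_pcs:
        eff = dataclasses.replace(eff, n_pcs=len(features) - 1)
    emb = embed_pca(nm, features, eff)
    coords = emb.coords
    if k > 0:
        per_source = int(np.ceil(k / 2))
        for source in ("query", "atlas"):
            if (src == source).sum() < per_source:
                raise ValueError(f"source {source!r} has fewer than {per_source} cells")
        smoothed = np.empty_like(coords)
        idx_by_source = {s: np.flatnonzero(src == s) for s in ("query", "atlas")}
        nn_by_source = {
            s: NearestNeighbors(n_neighbors=per_source).fit(coords[idx])
            for s, idx in idx_by_source.items()
        }
        for i in range(coords.shape[0]):
            neigh = [coords[i]]
            for s, idx in idx_by_source.items():
                _, jj = nn_by_source[s].kneighbors(coords[i][np.newaxis, :])
                neigh.append(coords[idx[jj[0]]].mean(axis=0))
            smoothed[i] = np.mean(neigh, axis=0)
        coords = smoothed
    return JointEmbedding(
        coords=coords,
        cell_ids=cell_ids,
        source=src,
        feature_genes=features,
        params=eff,
    )


@dataclasses.dataclass(frozen=True)
class EllipseParams:
    n_ellipse_dims: int = 2
    expansion: float = 1.5
    quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.n_ellipse_dims < 1:
            raise ValueError("n_ellipse_dims must be >= 1")
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")


def ellipse_reannotate(
    joint: JointEmbedding,
    focal_cells: set[str],
    other_source_cells: set[str],
    params: EllipseParams = EllipseParams(),
) -> list[str]:
    """Other-source cells inside a rigidly expanded PCA ellipse of the focal set.

    The ellipse is the Mahalanobis ball (mean/covariance of the focal
    cells in the top PCs) of radius expansion * sqrt(chi2 quantile).
    """
    d = params.n_ellipse_dims
    pos = {c: i for i, c in enumerate(joint.cell_ids)}
    focal_idx = np.array([pos[c] for c in sorted(focal_cells)])
    other_idx = np.array([pos[c] for c in sorted(other_source_cells)])
    if len(focal_idx) < d + 1:
        raise ValueError("need at least n_ellipse_dims + 1 focal cells")
    x = joint.coords[focal_idx, :d]
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1).reshape(d, d)
    if not np.isfinite(np.linalg.cond(sigma)) or np.linalg.cond(sigma) > 1e12:
        raise ValueError(
            "singular focal covariance; use more dims or regularize"
        )
    inv = np.linalg.inv(sigma)
    radius = params.expansion * np.sqrt(chi2.ppf(params.quantile, df=d))
    out = []
    for i in other_idx:
        delta = joint.coords[i, :d] - mu
        dist = float(np.sqrt(delta @ inv @ delta))
        if dist <= radius:
            out.append(joint.cell_ids[i])
    return out
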