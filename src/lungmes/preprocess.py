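"""Cell QC, CPM normalization, Fano-factor feature selection, and embedding.

The workflow follows the standard Smart-seq2 recipe: discard cells with
fewer than 50,000 uniquely mapped reads or fewer than 400 detected genes,
normalize each cell to counts per million, select the 500 genes with a
high Fano factor (variance/mean) in most mice, log10-transform with a
pseudocount of 0.1, and project onto the top 25 principal components.
t-SNE is provided for visualization only and is never used for statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io_core import CountMatrix, NormalizedMatrix


@dataclasses.dataclass(frozen=True)
class QCParams:
    """Cell-level QC thresholds (cells *below* either threshold are discarded)."""

    min_reads: int = 50_000
    min_genes: int = 400

    def __post_init__(self) -> None:
        if self.min_reads <= 0 or self.min_genes <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclasses.dataclass(frozen=True)
class EmbeddingParams:
    n_features: int = 500
    pseudocount: float = 0.1
    n_pcs: int = 25
    mouse_majority_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < self.n_pcs:
            raise ValueError("n_features must be >= n_pcs")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not (0 < self.mouse_majority_fraction <= 1):
            raise ValueError("mouse_majority_fraction must be in (0, 1]")


@dataclasses.dataclass
class Embedding:
    """PC scores (cells x n_pcs) of the log-CPM feature matrix."""

    coords: np.ndarray
    cell_ids: list[str]
    feature_genes: list[str]
    params: EmbeddingParams


def filter_cells(cm: CountMatrix, params: QCParams = QCParams()) -> CountMatrix:
    """Keep cells with total counts >= min_reads AND detected genes >= min_genes.

    The thresholds are inclusive ("less than" is discarded), so a cell at
    exactly 50,000 counts / 400 genes is retained.  Idempotent; the gene
    axis is never touched.
    """
    totals = cm.counts.sum(axis=0)
    n_genes = (cm.counts > 0).sum(axis=0)
    keep = (totals >= params.min_reads) & (n_genes >= params.min_genes)
    return cm.subset_cells(np.asarray(keep, dtype=bool))


def normalize_cpm(cm: CountMatrix) -> NormalizedMatrix:
    """Counts-per-million: values[g, c] = counts[g, c] / total(c) * 1e6."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError(
            "zero-total cell present; run filter_cells before normalization"
        )
    values = cm.counts / totals[np.newaxis, :] * 1e6
    return NormalizedMatrix(
        values=values,
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        cell_meta=cm.cell_meta,
    )


def fano_factors(values: np.ndarray) -> np.ndarray:
    """Per-gene Fano factor (sample variance / mean); zero-mean genes get 0."""
    mean = values.mean(axis=1)
    if values.shape[1] >= 2:
        var = values.var(axis=1, ddof=1)
    else:
        var = np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, 0.0)
    return fano


def select_features(
    nm: NormalizedMatrix, params: EmbeddingParams = EmbeddingParams()
) -> list[str]:
    """Genes with a high Fano factor in most mice.

    Per mouse, a gene is "high" if its Fano factor ranks in that mouse's
    top ``n_features``.  Genes high in at least
    ``mouse_majority_fraction`` of mice are returned, ranked by the number
    of mice they are high in, then by median Fano factor across mice, with
    lexicographic gene order as the final tie-break; the list is truncated
    to ``n_features``.
    """
    mice = nm.cell_meta["mouse_id"].to_numpy()
    unique_mice = sorted(set(mice))
    n_top = min(params.n_features, nm.n_genes)
    fanos = np.zeros((len(unique_mice), nm.n_genes))
    high = np.zeros((len(unique_mice), nm.n_genes), dtype=bool)
    for mi, mouse in enumerate(unique_mice):
        cols = mice == mouse
        if cols.sum() < 2:
            raise ValueError(f"mouse {mouse!r} has < 2 cells; cannot estimate variance")
        f = fano_factors(nm.values[:, cols])
        fanos[mi] = f
        # top-n_top ranks; stable tie-break on gene symbol via lexsort
        order = np.lexsort((np.array(nm.gene_ids), -f))
        high[mi, order[:n_top]] = True
    n_mice_high = high.sum(axis=0)
    frac = n_mice_high / len(unique_mice)
    qualifies = frac >= params.mouse_majority_fraction - 1e-12
    if not qualifies.any():
        raise ValueError(
            "no gene is high-Fano in the required fraction of mice; "
            "lower mouse_majority_fraction"
        )
    median_fano = np.median(fanos, axis=0)
    idx = np.flatnonzero(qualifies)
    order = sorted(
        idx, key=lambda i: (-n_mice_high[i], -median_fano[i], nm.gene_ids[i])
    )
    return [nm.gene_ids[i] for i in order[: params.n_features]]


def log_transform(
    nm: NormalizedMatrix, features: list[str], pseudocount: float = 0.1
) -> np.ndarray:
    """log10(CPM + pseudocount) restricted to the feature genes; cells x genes."""
    gi = nm.gene_index(features)
    return np.log10(nm.values[gi, :].T + pseudocount)


def embed_pca(
    nm: NormalizedMatrix,
    features: list[str],
    params: EmbeddingParams = EmbeddingParams(),
) -> Embedding:
    """Project log10(CPM + pseudocount) of the feature genes onto the top PCs.

    Cells are samples, genes are centered; no unit-variance scaling.  The
    sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making the embedding deterministic.
    """
    if params.n_pcs >= min(len(features), nm.n_cells):
        raise ValueError("n_pcs must be < min(n_features, n_cells)")
    x = log_transform(nm, features, params.pseudocount)
    pca = PCA(
        n_components=params.n_pcs, svd_solver="full", random_state=params.seed
    )
    scores = pca.fit_transform(x)
    # deterministic sign convention
    for k in range(params.n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
            pca.components_[k] *= -1
    emb = Embedding(
        coords=scores,
        cell_ids=list(nm.cell_ids),
        feature_genes=list(features),
        params=params,
    )
    emb.explained_variance_ = pca.explained_variance_
    emb.explained_variance_ratio_ = pca.explained_variance_ratio_
    return emb


def embed_tsne(embedding: Embedding, seed: int = 0) -> np.ndarray:
    """2-D t-SNE of the PC coordinates; deterministic for a fixed seed.

    For plots only — downstream statistics always run on expression or PC
    space, never on the t-SNE plane.
    """
    n = embedding.coords.shape[0]
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        n_jobs=1,
    )
    return ts.fit_transform(embedding.coords)
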