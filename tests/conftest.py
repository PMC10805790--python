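"""Shared fixtures: tiny handcrafted matrices and one medium simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lungmes as lm


def make_count_matrix(counts, gene_ids=None, cell_ids=None, timepoints=None,
                      conditions=None, mouse_ids=None) -> lm.CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "mouse_id": mouse_ids or ["m1"] * n_cells,
            "timepoint": timepoints or ["P7"] * n_cells,
            "condition": conditions or ["normoxia"] * n_cells,
            "sex": ["F"] * n_cells,
        }
    )
    return lm.CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)


def make_normalized(values, **kw) -> lm.NormalizedMatrix:
    """Build a NormalizedMatrix from raw weights by rescaling columns to 1e6."""
    values = np.asarray(values, dtype=float)
    cm = make_count_matrix(np.ones_like(values, dtype=int), **kw)
    scaled = values / values.sum(axis=0, keepdims=True) * 1e6
    return lm.NormalizedMatrix(
        values=scaled, gene_ids=cm.gene_ids, cell_ids=cm.cell_ids, cell_meta=cm.cell_meta
    )


@pytest.fixture(scope="session")
def study():
    """One simulated study (seed 42) shared across read-only tests."""
    spec = lm.default_study_spec(42)
    cm, truth = lm.generate(spec)
    return spec, cm, truth


@pytest.fixture(scope="session")
def study_processed(study):
    """QC'd, normalized, embedded and clustered version of the shared study."""
    spec, cm, truth = study
    qcd = lm.filter_cells(cm)
    nm = lm.normalize_cpm(qcd)
    params = lm.EmbeddingParams(seed=42)
    features = lm.select_features(nm, params)
    emb = lm.embed_pca(nm, features, params)
    labels = lm.cluster_leiden(emb, seed=42)
    return nm, emb, labels, truth
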