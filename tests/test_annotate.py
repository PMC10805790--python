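"""Clustering, doublet exclusion, rule annotation, co-embedding, ellipse."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2
from sklearn.metrics import adjusted_rand_score

import lungmes as lm
from lungmes.annotate import cluster_positivity
from lungmes.rules import GROUP_ASM_MYOF, MarkerRule

from conftest import make_normalized


def toy_embedding(coords, seed=0):
    return lm.Embedding(
        coords=np.asarray(coords, dtype=float),
        cell_ids=[f"c{i}" for i in range(len(coords))],
        feature_genes=[],
        params=lm.EmbeddingParams(seed=seed),
    )


class TestClusterLeiden:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.5, size=(40, 3))
        b = rng.normal(20, 0.5, size=(40, 3))
        emb = toy_embedding(np.vstack([a, b]))
        labels = lm.cluster_leiden(emb, n_neighbors=10, resolution=0.1, seed=0)
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:40].tolist())) == 1
        assert len(set(labels[40:].tolist())) == 1

    def test_deterministic_for_fixed_seed(self, study_processed):
        _, emb, labels, _ = study_processed
        again = lm.cluster_leiden(emb, seed=42)
        assert np.array_equal(labels, again)

    def test_recovers_true_subtypes(self, study_processed):
        """Adjusted Rand index vs generator truth is high on study-like data."""
        nm, _, labels, truth = study_processed
        t = truth.cells.set_index("cell_id").loc[nm.cell_ids]
        keep = (~t["doublet"] & ~t["lowq"]).to_numpy()
        ari = adjusted_rand_score(t["subtype"].to_numpy()[keep], labels[keep])
        assert ari >= 0.8

    def test_n_neighbors_bound(self):
        emb = toy_embedding(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="n_neighbors"):
            lm.cluster_leiden(emb, n_neighbors=5)


class TestFlagDoublets:
    def test_coexpressing_cell_flagged(self):
        # three cells: fibroblast, mural, and a doublet coexpressing both
        # markers; a dominant background gene keeps off-marker CPM tiny
        nm = make_normalized(
            [[1000, 1, 500], [1, 1000, 500], [1e6, 1e6, 1e6]],
            gene_ids=["Adh1", "Pdgfrb", "other"],
        )
        labels = np.zeros(3, dtype=int)
        flags = lm.flag_doublets(
            nm, labels, [(frozenset(["Adh1"]), frozenset(["Pdgfrb"]))],
            min_cluster_size=1,
        )
        assert flags.tolist() == [False, False, True]

    def test_no_coexpression_no_flags(self):
        nm = make_normalized(np.ones((3, 20)))
        flags = lm.flag_doublets(
            nm, np.zeros(20, int), [(frozenset(["g0"]), frozenset(["missing"]))],
            min_cluster_size=5,
        )
        assert not flags.any()

    def test_small_clusters_flagged(self):
        nm = make_normalized(np.ones((2, 12)))
        labels = np.array([0] * 10 + [1] * 2)
        flags = lm.flag_doublets(nm, labels, [], min_cluster_size=5)
        assert flags.tolist() == [False] * 10 + [True] * 2

    def test_recovers_simulated_doublets(self, study_processed):
        """Recall and precision both >= 0.7 against generator truth."""
        nm, _, labels, truth = study_processed
        flags = lm.flag_doublets(nm, labels, lm.default_incompatible_pairs())
        t = truth.cells.set_index("cell_id").loc[nm.cell_ids]
        true_doublet = t["doublet"].to_numpy()
        recall = flags[true_doublet].mean()
        precision = true_doublet[flags].mean()
        assert recall >= 0.7
        assert precision >= 0.7


class TestAssignSubtypes:
    def _toy(self):
        # cluster 0: Tgfbi+Hhip (early ASM); cluster 1: Tgfbi+Hhip+Pdgfra
        # (precursor); the dominant filler keeps off-marker CPM near zero
        genes = ["Tgfbi", "Hhip", "Pdgfra", "Lum", "Mki67", "filler"]
        w = np.ones((6, 40))
        w[5] = 1e6
        w[0, :] = 5000.0
        w[1, :] = 5000.0
        w[2, 20:] = 5000.0
        nm = make_normalized(w, gene_ids=genes)
        labels = np.array([0] * 20 + [1] * 20)
        return nm, labels

    def test_early_asm_vs_precursor_rules(self):
        nm, labels = self._toy()
        ann = lm.assign_subtypes(nm, labels, lm.default_rules())
        by_cluster = ann.groupby("cluster_id")["subtype"].first()
        assert by_cluster[0] == "Early ASM"
        assert by_cluster[1] == "ASM/MyoF precursor"
        assert (ann["group"] == GROUP_ASM_MYOF).all()

    def test_pure_function_of_cluster_summaries(self):
        """Permuting cells within clusters never changes cluster subtypes."""
        nm, labels = self._toy()
        a = lm.assign_subtypes(nm, labels, lm.default_rules())
        rng = np.random.default_rng(0)
        perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
        b = lm.assign_subtypes(nm.subset_cells(perm), labels[perm], lm.default_rules())
        merged = a.merge(b, on="cell_id", suffixes=("_a", "_b"))
        assert (merged["subtype_a"] == merged["subtype_b"]).all()

    def test_empty_rules_rejected(self):
        nm, labels = self._toy()
        with pytest.raises(ValueError, match="rule"):
            lm.assign_subtypes(nm, labels, [])

    def test_recovers_true_subtypes_end_to_end(self, study_processed):
        """>=90% of clean cells get their true subtype; HA clusters are
        hyperoxia-restricted and nearly pure."""
        nm, _, labels, truth = study_processed
        flags = lm.flag_doublets(nm, labels, lm.default_incompatible_pairs())
        ann = lm.assign_subtypes(nm, labels, lm.default_rules(), doublet_flags=flags)
        merged = ann.merge(truth.cells, on="cell_id", suffixes=("", "_true"))
        clean = merged[~merged["doublet_true"] & ~merged["lowq"]]
        correct = (
            (clean["subtype"] == clean["subtype_true"])
            | (
                clean["subtype"].str.startswith("HA-novel")
                & clean["subtype_true"].isin(["HA1", "HA2"])
            )
        ) & ~clean["doublet"]
        assert correct.mean() >= 0.9

    def test_rule_gene_sets_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            MarkerRule(
                subtype="bad",
                group="mural",
                required_positive=frozenset(["A"]),
                required_negative=frozenset(["A"]),
            )


@pytest.fixture(scope="module")
def pair():
    """Query/atlas pair: two generator draws restricted to P21 cells."""
    q_cm, q_truth = lm.generate(lm.default_study_spec(7))
    a_cm, a_truth = lm.generate(lm.default_study_spec(8))
    sel_q = (q_cm.cell_meta["timepoint"] == "P21").to_numpy()
    sel_a = (a_cm.cell_meta["timepoint"] == "P21").to_numpy()
    return q_cm.subset_cells(sel_q), a_cm.subset_cells(sel_a), q_truth, a_truth


class TestHarmonizeEmbed:
    def test_source_tags_partition(self, pair):
        q, a, *_ = pair
        joint = lm.harmonize_embed(q, a, k=6)
        assert (joint.source == "query").sum() == q.n_cells
        assert (joint.source == "atlas").sum() == a.n_cells

    def test_k_zero_is_plain_joint_pca(self, pair):
        q, a, *_ = pair
        j0 = lm.harmonize_embed(q, a, k=0)
        j1 = lm.harmonize_embed(q, a, k=6)
        assert j0.coords.shape == j1.coords.shape
        assert not np.allclose(j0.coords, j1.coords)

    def test_same_type_cells_co_embed(self, pair):
        """After smoothing, inter-source distance within a true subtype is
        at most 1.5x the intra-source distance."""
        from scipy.spatial.distance import cdist

        q, a, qt, at = pair
        joint = lm.harmonize_embed(q, a, k=10)
        qt_ix = qt.cells.set_index("cell_id")
        at_ix = at.cells.set_index("cell_id")
        lab = np.array(
            [
                (qt_ix if s == "query" else at_ix).loc[c.split(":", 1)[1], "subtype"]
                for c, s in zip(joint.cell_ids, joint.source)
            ]
        )
        for subtype in ("Pericyte", "VSM"):
            sel = lab == subtype
            c, s = joint.coords[sel], joint.source[sel]
            intra = (
                cdist(c[s == "query"], c[s == "query"]).mean()
                + cdist(c[s == "atlas"], c[s == "atlas"]).mean()
            ) / 2
            inter = cdist(c[s == "query"], c[s == "atlas"]).mean()
            assert inter <= 1.5 * intra

    def test_empty_gene_intersection_rejected(self, pair):
        q, a, *_ = pair
        renamed = lm.CountMatrix(
            counts=a.counts,
            gene_ids=[f"x_{g}" for g in a.gene_ids],
            cell_ids=a.cell_ids,
            cell_meta=a.cell_meta,
        )
        with pytest.raises(ValueError, match="no genes"):
            lm.harmonize_embed(q, renamed)


class TestEllipse:
    def _joint(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(2 * n, 4))
        ids = [f"f{i}" for i in range(n)] + [f"o{i}" for i in range(n)]
        return lm.JointEmbedding(
            coords=coords,
            cell_ids=ids,
            source=np.array(["query"] * n + ["atlas"] * n),
            feature_genes=[],
            params=lm.EmbeddingParams(),
        )

    def test_cell_at_mean_inside(self):
        joint = self._joint()
        focal = {c for c in joint.cell_ids if c.startswith("f")}
        mu = joint.coords[:100, :2].mean(axis=0)
        joint.coords[100] = np.concatenate([mu, joint.coords[100, 2:]])
        inside = lm.ellipse_reannotate(joint, focal, {"o0"})
        assert inside == ["o0"]

    def test_infinite_expansion_includes_all(self):
        joint = self._joint()
        focal = {c for c in joint.cell_ids if c.startswith("f")}
        other = {c for c in joint.cell_ids if c.startswith("o")}
        inside = lm.ellipse_reannotate(
            joint, focal, other, lm.EllipseParams(expansion=1e9)
        )
        assert set(inside) == other

    def test_matches_explicit_mahalanobis(self):
        """Membership equals a direct per-point computation with an explicit
        matrix inverse."""
        joint = self._joint(n=100, seed=3)
        focal = {c for c in joint.cell_ids if c.startswith("f")}
        other = {c for c in joint.cell_ids if c.startswith("o")}
        params = lm.EllipseParams(n_ellipse_dims=2, expansion=1.5, quantile=0.95)
        got = set(lm.ellipse_reannotate(joint, focal, other, params))

        x = joint.coords[:100, :2]
        mu = x.mean(axis=0)
        inv = np.linalg.inv(np.cov(x, rowvar=False, ddof=1))
        r = 1.5 * np.sqrt(chi2.ppf(0.95, 2))
        expected = set()
        for i in range(100, 200):
            d = joint.coords[i, :2] - mu
            if np.sqrt(d @ inv @ d) <= r:
                expected.add(joint.cell_ids[i])
        assert got == expected

    def test_membership_monotone_in_expansion(self):
        joint = self._joint(seed=5)
        focal = {c for c in joint.cell_ids if c.startswith("f")}
        other = {c for c in joint.cell_ids if c.startswith("o")}
        prev: set = set()
        for exp in (1.0, 1.5, 2.5, 4.0):
            cur = set(
                lm.ellipse_reannotate(joint, focal, other, lm.EllipseParams(expansion=exp))
            )
            assert prev <= cur
            prev = cur

    def test_too_few_focal_cells_rejected(self):
        joint = self._joint()
        with pytest.raises(ValueError, match="focal"):
            lm.ellipse_reannotate(joint, {"f0", "f1"}, {"o0"})
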