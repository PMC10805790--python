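"""Hyperoxia developmental-arrest statistics.

Two complementary analyses quantify the arrest phenotype:

1. A bootstrap compositional test.  Cell-subtype composition vectors are
   built for the hyperoxic stratum and for two healthy reference strata
   (early = P1, late = P7).  Over B bootstrap replicates, an equal number
   of cells (the smallest stratum size, "balanced") is resampled with
   replacement from each stratum and the difference
   d(focal, late) - d(focal, early) is recorded, with d the total
   variation distance (half L1) between composition vectors.  A positive
   difference means the hyperoxic composition is closer to the younger
   reference; the empirical P is the fraction of replicates at or below
   zero (ties count against the arrest hypothesis).

2. A progression-gene analysis.  Within one cell type, genes that rise
   from P1 to P7 in normoxia (signed KS > 0 with KS >= ks_min) are the
   progression genes; each is then compared between hyperoxia-P7 and
   normoxia-P7, and the fraction with a negative signed KS — progression
   lost under hyperoxia — is the arrest fraction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diffexp import RankingParams, ks_de


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Half the L1 distance between two composition vectors; in [0, 1]."""
    return float(0.5 * np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


def euclidean(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


_DISTANCES = {"total_variation": total_variation, "euclidean": euclidean}


def _stratum_digest(stratum: tuple[str, str]) -> int:
    """Stable small integer identifying a (timepoint, condition) stratum."""
    import hashlib

    h = hashlib.sha256(f"{stratum[0]}|{stratum[1]}".encode()).digest()
    return int.from_bytes(h[:4], "big")


@dataclasses.dataclass
class CompositionProfile:
    proportions: np.ndarray
    subtypes: list[str]
    n_cells: int
    stratum: tuple[str, str]


def _stratum_subtypes(ann: pd.DataFrame, stratum: tuple[str, str]) -> np.ndarray:
    tp, cond = stratum
    sel = ann[
        (ann["timepoint"] == tp) & (ann["condition"] == cond) & (~ann["doublet"])
    ]
    return sel["subtype"].to_numpy()


def composition(
    ann: pd.DataFrame, stratum: tuple[str, str], subtypes: list[str] | None = None
) -> CompositionProfile:
    """Subtype proportions among non-doublet cells of one (timepoint, condition)."""
    labels = _stratum_subtypes(ann, stratum)
    if len(labels) == 0:
        raise ValueError(f"no non-doublet cells in stratum {stratum}")
    if subtypes is None:
        subtypes = sorted(set(labels))
    counts = pd.Series(labels).value_counts()
    props = np.array([counts.get(s, 0) for s in subtypes], dtype=float)
    props /= len(labels)
    return CompositionProfile(
        proportions=props, subtypes=list(subtypes), n_cells=len(labels), stratum=stratum
    )


@dataclasses.dataclass
class ArrestBootstrapResult:
    diffs: np.ndarray
    empirical_p: float
    B: int
    seed: int
    distance_name: str


def bootstrap_arrest(
    ann: pd.DataFrame,
    focal: tuple[str, str],
    ref_early: tuple[str, str],
    ref_late: tuple[str, str],
    B: int = 1000,
    seed: int = 0,
    distance: str = "total_variation",
) -> ArrestBootstrapResult:
    """Bootstrap d(focal, late) - d(focal, early) over balanced cell resamples.

    empirical_p = #{diff <= 0} / B: the fraction of replicates in which
    the focal (hyperoxic) composition is at least as close to the late
    reference as to the early one.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    dist = _DISTANCES[distance]
    strata_labels = [
        _stratum_subtypes(ann, s) for s in (focal, ref_early, ref_late)
    ]
    for s, lab in zip((focal, ref_early, ref_late), strata_labels):
        if len(lab) == 0:
            raise ValueError(f"empty stratum {s}")
    subtypes = sorted(set(np.concatenate(strata_labels)))
    sub_idx = {s: i for i, s in enumerate(subtypes)}
    coded = [np.array([sub_idx[s] for s in lab]) for lab in strata_labels]
    n = min(len(lab) for lab in strata_labels)  # balanced at each time point
    k = len(subtypes)
    # one independent stream per stratum identity, so each stratum's
    # resamples do not depend on which argument slot it occupies
    # (swapping the references exactly negates every diff)
    streams = [
        np.random.default_rng([seed, _stratum_digest(s)])
        for s in (focal, ref_early, ref_late)
    ]
    props = np.empty((3, B, k))
    for j, (codes, rng) in enumerate(zip(coded, streams)):
        samp = codes[rng.integers(0, len(codes), size=(B, n))]
        for b in range(B):
            props[j, b] = np.bincount(samp[b], minlength=k) / n
    diffs = np.array(
        [dist(props[0, b], props[2, b]) - dist(props[0, b], props[1, b]) for b in range(B)]
    )
    empirical_p = float((diffs <= 0).sum() / B)
    return ArrestBootstrapResult(
        diffs=diffs, empirical_p=empirical_p, B=B, seed=seed, distance_name=distance
    )


@dataclasses.dataclass
class ProgressionArrestResult:
    cell_type: str
    table: pd.DataFrame  # gene_id, normoxia_progress_ks, hyperoxia_effect_ks
    arrest_fraction: float | None  # None when no progression genes pass


def _cells_of(ann: pd.DataFrame, cell_type: str, tp: str, cond: str) -> list[str]:
    sel = ann[
        (ann["subtype"] == cell_type)
        & (ann["timepoint"] == tp)
        & (ann["condition"] == cond)
        & (~ann["doublet"])
    ]
    return sel["cell_id"].tolist()


def progression_arrest(
    nm,
    ann: pd.DataFrame,
    cell_type: str,
    ranking: RankingParams = RankingParams(),
) -> ProgressionArrestResult:
    """Progression genes (up P1->P7 in normoxia) and their hyperoxia response.

    arrest_fraction = fraction of progression genes whose signed KS for
    hyperoxia-P7 vs normoxia-P7 is negative; None when no gene passes
    the ks_min selection.
    """
    strata = {
        "normoxia P1": _cells_of(ann, cell_type, "P1", "normoxia"),
        "normoxia P7": _cells_of(ann, cell_type, "P7", "normoxia"),
        "hyperoxia P7": _cells_of(ann, cell_type, "P7", "hyperoxia"),
    }
    for name, cells in strata.items():
        if len(cells) < 2:
            raise ValueError(f"cell type {cell_type!r} missing from stratum {name}")
    de_prog = ks_de(nm, strata["normoxia P7"], strata["normoxia P1"])
    prog = de_prog[(de_prog["signed_ks"] > 0) & (de_prog["ks_stat"] >= ranking.ks_min)]
    if prog.empty:
        return ProgressionArrestResult(
            cell_type=cell_type,
            table=pd.DataFrame(
                columns=["gene_id", "normoxia_progress_ks", "hyperoxia_effect_ks"]
            ),
            arrest_fraction=None,
        )
    de_hyper = ks_de(
        nm, strata["hyperoxia P7"], strata["normoxia P7"], genes=prog["gene_id"].tolist()
    )
    table = prog[["gene_id", "signed_ks"]].rename(
        columns={"signed_ks": "normoxia_progress_ks"}
    ).merge(
        de_hyper[["gene_id", "signed_ks"]].rename(
            columns={"signed_ks": "hyperoxia_effect_ks"}
        ),
        on="gene_id",
    )
    arrest_fraction = float((table["hyperoxia_effect_ks"] < 0).mean())
    return ProgressionArrestResult(
        cell_type=cell_type, table=table, arrest_fraction=arrest_fraction
    )
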