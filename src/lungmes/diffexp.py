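"""Kolmogorov-Smirnov differential expression and the TF quadrant fingerprint.

Single-cell expression rarely fits a parametric family, so differential
expression between two cell populations is assessed per gene with the
nonparametric two-sample KS test on CPM values, Bonferroni-corrected over
the genes actually tested.  A signed variant of the KS statistic (sign =
direction of the mean difference) makes the statistic directional, which
the transcription-factor quadrant fingerprint relies on: each TF is
scored against two reference populations at once, and the quadrant of
the (signed KS, signed KS) pair classifies it as specifically up,
specifically down, or mixed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

LOG2FC_PSEUDOCOUNT = 0.1

#: with both samples at or below this size the exact two-sample KS
#: p-value is used; above it, the asymptotic Kolmogorov distribution.
EXACT_P_MAX_N = 25


def _ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    mode = "exact" if max(len(a), len(b)) <= EXACT_P_MAX_N else "asymp"
    try:
        res = stats.ks_2samp(a, b, method=mode)
    except (ValueError, RuntimeWarning):
        res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(1.0, res.pvalue))


def signed_ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(ks_stat, signed_ks, p_value) for two samples; sign = mean(a) - mean(b)."""
    stat, p = _ks_two_sample(a, b)
    sign = 1.0 if a.mean() >= b.mean() else -1.0
    return stat, sign * stat, p


def _resolve_cells(nm, cells) -> np.ndarray:
    pos = {c: i for i, c in enumerate(nm.cell_ids)}
    return np.array(sorted(pos[str(c)] for c in cells), dtype=int)


def ks_de(nm, cells_a, cells_b, genes=None) -> pd.DataFrame:
    """Per-gene KS differential expression between two disjoint cell sets.

    Returns the DEResult table with columns gene_id, ks_stat, signed_ks,
    p_value, p_adj (Bonferroni over the tested genes), log2fc (A over B,
    pseudocount 0.1 on the means).
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if set_a & set_b:
        raise ValueError("cell sets overlap")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each cell set needs at least 2 cells")
    ia = _resolve_cells(nm, set_a)
    ib = _resolve_cells(nm, set_b)
    if genes is None:
        gene_list = list(nm.gene_ids)
    else:
        gene_list = [g for g in genes if g in set(nm.gene_ids)]
    if not gene_list:
        return pd.DataFrame(
            columns=["gene_id", "ks_stat", "signed_ks", "p_value", "p_adj", "log2fc"]
        )
    gi = nm.gene_index(gene_list)
    m = len(gene_list)
    rows = []
    for g, row in zip(gene_list, gi):
        va = nm.values[row, ia]
        vb = nm.values[row, ib]
        stat, signed, p = signed_ks(va, vb)
        log2fc = float(
            np.log2(
                (va.mean() + LOG2FC_PSEUDOCOUNT) / (vb.mean() + LOG2FC_PSEUDOCOUNT)
            )
        )
        rows.append(
            {
                "gene_id": g,
                "ks_stat": stat,
                "signed_ks": signed,
                "p_value": p,
                "p_adj": min(1.0, m * p),
                "log2fc": log2fc,
            }
        )
    return pd.DataFrame.from_records(rows)


@dataclasses.dataclass(frozen=True)
class RankingParams:
    """Gene selection after DE: either top |KS|, or top |log2FC| above a KS floor."""

    ks_min: float = 0.3
    top_n: int = 100
    mode: str = "by_fc_above_ks"  # or "by_stat"

    def __post_init__(self) -> None:
        if not (0 <= self.ks_min <= 1):
            raise ValueError("ks_min must be in [0, 1]")
        if self.mode not in ("by_stat", "by_fc_above_ks"):
            raise ValueError("mode must be by_stat or by_fc_above_ks")


def rank_genes(de: pd.DataFrame, params: RankingParams) -> list[str]:
    """Ordered gene list per the ranking mode; ties broken lexicographically."""
    if de.empty:
        raise ValueError("empty DEResult")
    df = de.copy()
    if params.mode == "by_stat":
        df["_key"] = df["ks_stat"].abs()
    else:
        df = df[df["ks_stat"] >= params.ks_min]
        df = df.copy()
        df["_key"] = df["log2fc"].abs()
    df = df.sort_values(["_key", "gene_id"], ascending=[False, True], kind="mergesort")
    return df["gene_id"].head(params.top_n).tolist()


def tf_quadrant(
    nm, focal_cells, ref1_cells, ref2_cells, tf_genes
) -> pd.DataFrame:
    """Signed-KS enrichment of each TF in the focal set vs two references.

    Quadrants: (+,+) -> specific_up, (-,-) -> specific_down, otherwise
    mixed_x / mixed_y by which axis is positive.  Only TFs expressed
    (nonzero in at least one focal or reference cell) are scored; TFs
    absent from the matrix are skipped.
    """
    sets = [set(focal_cells), set(ref1_cells), set(ref2_cells)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("cell sets must be disjoint")
        if len(sets[i]) < 2:
            raise ValueError("each cell set needs at least 2 cells")
    idx = [_resolve_cells(nm, s) for s in sets]
    present = set(nm.gene_ids)
    rows = []
    for g in tf_genes:
        if g not in present:
            continue
        row = nm.gene_index([g])[0]
        vf, v1, v2 = (nm.values[row, i] for i in idx)
        if vf.max() == 0 and v1.max() == 0 and v2.max() == 0:
            continue
        _, ex, _ = signed_ks(vf, v1)
        _, ey, _ = signed_ks(vf, v2)
        if ex > 0 and ey > 0:
            quad = "specific_up"
        elif ex < 0 and ey < 0:
            quad = "specific_down"
        elif ex > 0:
            quad = "mixed_x"
        else:
            quad = "mixed_y"
        rows.append({"gene_id": g, "enrich_x": ex, "enrich_y": ey, "quadrant": quad})
    return pd.DataFrame.from_records(
        rows, columns=["gene_id", "enrich_x", "enrich_y", "quadrant"]
    )
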