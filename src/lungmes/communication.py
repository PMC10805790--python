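"""Ligand-receptor interaction counting and strength scoring.

An interaction is "detected" between a source and target population when
at least 20% of source cells express the ligand and at least 20% of
target cells express the receptor ("expresses" = CPM above a floor,
0 by default, appropriate for deep Smart-seq2 libraries).  Interaction
strength is the symmetric product
    [mean ligand CPM in source x source-type proportion] x
    [mean receptor CPM in target x target-type proportion],
with proportions taken over non-doublet cells of the stratum; a variant
using only the source-side abundance is available behind a flag.
"""

from __future__ import annotations

import pandas as pd

from .io_core import LRDatabase, NormalizedMatrix

DEFAULT_THRESHOLD = 0.20
EXPRESSION_FLOOR_CPM = 0.0

INTERACTION_COLUMNS = [
    "pair_id",
    "ligand_gene",
    "receptor_gene",
    "source_type",
    "target_type",
    "timepoint",
    "condition",
    "frac_ligand",
    "frac_receptor",
    "detected",
    "strength",
]


def _population(
    ann: pd.DataFrame, cell_type: str, stratum: tuple[str, str]
) -> pd.DataFrame:
    tp, cond = stratum
    sel = ann[(ann["timepoint"] == tp) & (ann["condition"] == cond) & (~ann["doublet"])]
    return sel[(sel["subtype"] == cell_type) | (sel["group"] == cell_type)]


def _expressing_fraction(
    nm: NormalizedMatrix, gene: str, cells: list[str], floor: float
) -> float:
    if gene not in set(nm.gene_ids):
        return 0.0
    gi = nm.gene_index([gene])[0]
    pos = {c: i for i, c in enumerate(nm.cell_ids)}
    idx = [pos[c] for c in cells]
    return float((nm.values[gi, idx] > floor).mean())


def _mean_cpm(nm: NormalizedMatrix, gene: str, cells: list[str]) -> float:
    if gene not in set(nm.gene_ids):
        return 0.0
    gi = nm.gene_index([gene])[0]
    pos = {c: i for i, c in enumerate(nm.cell_ids)}
    idx = [pos[c] for c in cells]
    return float(nm.values[gi, idx].mean())


def _proportion(ann: pd.DataFrame, cell_type: str, stratum: tuple[str, str]) -> float:
    tp, cond = stratum
    all_cells = ann[
        (ann["timepoint"] == tp) & (ann["condition"] == cond) & (~ann["doublet"])
    ]
    if len(all_cells) == 0:
        raise ValueError(f"no non-doublet cells in stratum {stratum}")
    return len(_population(ann, cell_type, stratum)) / len(all_cells)


def detect_interactions(
    nm: NormalizedMatrix,
    ann: pd.DataFrame,
    db: LRDatabase,
    source_type: str,
    target_type: str,
    stratum: tuple[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    expression_floor: float = EXPRESSION_FLOOR_CPM,
    source_abundance_only: bool = False,
) -> pd.DataFrame:
    """One record per LR pair: expressing fractions, detected flag, strength.

    ``detected`` is inclusive at the threshold ("at least 20%").  Genes
    absent from the matrix count as 0% expressing.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    src = _population(ann, source_type, stratum)
    tgt = _population(ann, target_type, stratum)
    if len(src) == 0:
        raise ValueError(f"source population {source_type!r} empty in {stratum}")
    if len(tgt) == 0:
        raise ValueError(f"target population {target_type!r} empty in {stratum}")
    src_cells = src["cell_id"].tolist()
    tgt_cells = tgt["cell_id"].tolist()
    p_src = _proportion(ann, source_type, stratum)
    p_tgt = _proportion(ann, target_type, stratum)
    rows = []
    for _, pair in db.pairs.iterrows():
        lig, rec = pair["ligand_gene"], pair["receptor_gene"]
        frac_l = _expressing_fraction(nm, lig, src_cells, expression_floor)
        frac_r = _expressing_fraction(nm, rec, tgt_cells, expression_floor)
        strength = _mean_cpm(nm, lig, src_cells) * p_src * _mean_cpm(nm, rec, tgt_cells)
        if not source_abundance_only:
            strength *= p_tgt
        rows.append(
            {
                "pair_id": pair["pair_id"],
                "ligand_gene": lig,
                "receptor_gene": rec,
                "source_type": source_type,
                "target_type": target_type,
                "timepoint": stratum[0],
                "condition": stratum[1],
                "frac_ligand": frac_l,
                "frac_receptor": frac_r,
                "detected": bool(frac_l >= threshold and frac_r >= threshold),
                "strength": strength,
            }
        )
    return pd.DataFrame.from_records(rows, columns=INTERACTION_COLUMNS)


def interaction_strength(
    nm: NormalizedMatrix,
    ann: pd.DataFrame,
    pair: tuple[str, str, str],
    source_type: str,
    target_type: str,
    stratum: tuple[str, str],
    source_abundance_only: bool = False,
) -> float:
    """Strength of one (pair_id, ligand, receptor) interaction; see module docs."""
    pair_id, lig, rec = pair
    db = LRDatabase(
        pairs=pd.DataFrame(
            {"pair_id": [pair_id], "ligand_gene": [lig], "receptor_gene": [rec]}
        )
    )
    table = detect_interactions(
        nm,
        ann,
        db,
        source_type,
        target_type,
        stratum,
        source_abundance_only=source_abundance_only,
    )
    return float(table["strength"].iloc[0])


def count_interactions(
    table: pd.DataFrame, group_by: list[str] | None = None
) -> pd.DataFrame:
    """Number of detected records per group (default: target type x stratum)."""
    if group_by is None:
        group_by = ["target_type", "timepoint", "condition"]
    if table.empty:
        return pd.DataFrame(columns=group_by + ["n_detected"])
    detected = table[table["detected"]]
    counts = (
        detected.groupby(group_by, as_index=False, sort=True)
        .size()
        .rename(columns={"size": "n_detected"})
    )
    return counts
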