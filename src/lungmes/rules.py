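"""Marker-gene rule table for mesenchymal subtype annotation.

Three broad groups are keyed by one marker each: fibroblasts (Adh1),
ASM/MyoF (Tgfbi), mural cells (Pdgfrb).  Within groups, subtypes split on
Hhip vs Pdgfra (early ASM vs myofibroblast, coexpression = precursor),
Col13a1 vs Col14a1 (alveolar vs adventitial fibroblast, coexpression =
precursor), Tagln/Acta2 + Pdgfrb (vascular smooth muscle) vs Cox4i2
(pericyte), with Mki67 marking the proliferating variants.

Rules are matched first-wins, with more specific rules (more required
genes) ahead of their generic siblings.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

GROUP_FIBROBLAST = "fibroblast"
GROUP_ASM_MYOF = "ASM/MyoF"
GROUP_MURAL = "mural"
GROUP_NOVEL = "novel"
GROUP_DOUBLET = "doublet"

#: marker panel of the emergent hyperoxia-associated Acta1+ populations
HA_PANEL = ("Acta1", "Tubb3", "Lgals3", "Aqp3")


@dataclasses.dataclass(frozen=True)
class MarkerRule:
    subtype: str
    group: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.required_positive & self.required_negative:
            raise ValueError(
                f"rule {self.subtype}: positive and negative gene sets overlap"
            )


def _rule(subtype: str, group: str, pos: str, neg: str = "") -> MarkerRule:
    return MarkerRule(
        subtype=subtype,
        group=group,
        required_positive=frozenset(g for g in pos.split(";") if g),
        required_negative=frozenset(g for g in neg.split(";") if g),
    )


def default_rules() -> list[MarkerRule]:
    """The shipped rule table, in first-match order."""
    return [
        _rule("ASM/MyoF precursor", GROUP_ASM_MYOF, "Tgfbi;Hhip;Pdgfra"),
        _rule("Proliferating myofibroblast", GROUP_ASM_MYOF, "Tgfbi;Pdgfra;Mki67", "Hhip"),
        _rule("ASM", GROUP_ASM_MYOF, "Tgfbi;Hhip;Lum", "Pdgfra"),
        _rule("Early ASM", GROUP_ASM_MYOF, "Tgfbi;Hhip", "Pdgfra;Lum"),
        _rule("Myofibroblast", GROUP_ASM_MYOF, "Tgfbi;Pdgfra", "Hhip;Mki67"),
        _rule("VSM", GROUP_MURAL, "Pdgfrb;Tagln;Acta2", "Tgfbi"),
        _rule("Proliferating pericyte", GROUP_MURAL, "Pdgfrb;Cox4i2;Mki67", "Tagln"),
        _rule("Pericyte", GROUP_MURAL, "Pdgfrb;Cox4i2", "Tagln;Mki67"),
        _rule("Fibroblast precursor", GROUP_FIBROBLAST, "Adh1;Col13a1;Col14a1"),
        _rule("Proliferating fibroblast", GROUP_FIBROBLAST, "Adh1;Col13a1;Mki67", "Col14a1"),
        _rule("Alveolar fibroblast", GROUP_FIBROBLAST, "Adh1;Col13a1;Spon1", "Col14a1;Mki67"),
        _rule("Early alveolar fibroblast", GROUP_FIBROBLAST, "Adh1;Col13a1", "Col14a1;Spon1;Mki67"),
        _rule("Adventitial fibroblast", GROUP_FIBROBLAST, "Adh1;Col14a1;Podn", "Col13a1"),
        _rule("Early adventitial fibroblast", GROUP_FIBROBLAST, "Adh1;Col14a1", "Col13a1;Podn"),
    ]


def default_incompatible_pairs() -> list[tuple[frozenset[str], frozenset[str]]]:
    """Marker pairs never coexpressed by a single mesenchymal cell type.

    A single cell positive for one gene from each side of any pair is a
    doublet candidate.  Pairs cross the three broad groups and, within
    groups, lineages that only ever coexpress in a precursor are avoided
    (e.g. Hhip/Pdgfra is NOT listed because ASM/MyoF precursors coexpress
    both).
    """
    pairs = [
        ("Adh1", "Tgfbi"),
        ("Adh1", "Pdgfrb"),
        ("Tgfbi", "Pdgfrb"),
        ("Wnt2", "Mfap5"),
        ("Hsd11b1", "Wnt2"),
        ("Hsd11b1", "Mfap5"),
        ("Hhip", "Stc1"),
        ("Crh", "Aspn"),
        ("Tagln", "Cox4i2"),
        ("Tubb3", "Adh1"),
        ("Tubb3", "Tgfbi"),
        ("Tubb3", "Pdgfrb"),
    ]
    return [(frozenset([a]), frozenset([b])) for a, b in pairs]


def write_rules(rules: list[MarkerRule], path) -> None:
    df = pd.DataFrame(
        {
            "subtype": [r.subtype for r in rules],
            "group": [r.group for r in rules],
            "positive_genes": [";".join(sorted(r.required_positive)) for r in rules],
            "negative_genes": [";".join(sorted(r.required_negative)) for r in rules],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_rules(path) -> list[MarkerRule]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        _rule(row["subtype"], row["group"], row["positive_genes"], row["negative_genes"])
        for _, row in df.iterrows()
    ]
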