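"""Seeded synthetic scRNA-seq generator for the perinatal lung mesenchyme.

Counts are drawn from a negative binomial (gamma-Poisson) law, the standard
overdispersed model for scRNA-seq, with a single global shape parameter.
Each cell subtype is defined by a set of lineage marker genes whose
relative expression weight is multiplied up in that subtype and set
near-silent elsewhere, so markers behave like real on/off lineage genes.
The generator reproduces the structural features the analysis assumes:

* ~14 mesenchymal subtypes in three groups (fibroblast / ASM-MyoF / mural)
  with time-point-dependent composition over E18.5, P1, P7, P21;
* a hyperoxia arm at P7 whose composition mirrors P1 (developmental
  arrest) plus emergent Acta1+ populations (HA1/HA2) restricted to
  hyperoxia;
* "progression genes" whose mean rises from P1 to P7 in normoxia but is
  frozen at the P1 level in hyperoxia for arrested subtypes;
* spiked doublets (additive mixtures of two same-stratum cells) and
  low-quality cells that fall below the QC thresholds (total counts
  < 50,000 or expressed genes < 400).

Every draw flows through one ``numpy.random.Generator``, so an identical
spec + seed yields a bit-identical matrix and truth table.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import CONDITIONS, TIMEPOINTS, CountMatrix

#: relative weight of a lineage marker gene in subtypes where it is "off",
#: as a fraction of a background gene's weight.  Near-silent, as real
#: lineage markers are.
OFF_WEIGHT_FRACTION = 0.002

QC_MIN_READS = 50_000
QC_MIN_GENES = 400


class SpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SubtypeSpec:
    """One cell subtype: a name, its marker genes, and expression levels.

    ``multiplier`` scales marker genes relative to ``baseline_mean``, the
    relative expression weight of a background gene (depth_mean fixes the
    absolute counts).  ``proliferating`` adds Mki67 to the marker set.
    """

    name: str
    marker_genes: tuple[str, ...]
    multiplier: float = 30.0
    proliferating: bool = False
    baseline_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplier <= 1:
            raise SpecError(f"{self.name}: marker multiplier must be > 1")
        if self.baseline_mean <= 0:
            raise SpecError(f"{self.name}: baseline_mean must be > 0")

    @property
    def all_markers(self) -> tuple[str, ...]:
        if self.proliferating and "Mki67" not in self.marker_genes:
            return self.marker_genes + ("Mki67",)
        return self.marker_genes


@dataclasses.dataclass
class GeneratorSpec:
    """Full description of a synthetic study.

    composition / n_cells are keyed by (timepoint, condition) strata;
    each composition vector is over ``subtypes`` in order and must sum
    to 1.  ``progression_genes`` maps a subtype name to genes whose mean
    is multiplied by ``progression_multiplier`` at P7/P21 in normoxia;
    for subtypes in ``arrested_subtypes`` the hyperoxia arm keeps the P1
    level (the arrest signal), otherwise hyperoxia progresses too.
    """

    subtypes: list[SubtypeSpec]
    composition: dict[tuple[str, str], np.ndarray]
    n_cells: dict[tuple[str, str], int]
    n_genes: int = 800
    nb_dispersion: float = 2.0
    depth_mean: float = 150_000.0
    depth_sd: float = 0.25  # sigma of log depth
    progression_genes: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    progression_multiplier: float = 4.0
    arrested_subtypes: frozenset[str] | None = None
    doublet_rate: float = 0.0
    lowq_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.name for s in self.subtypes]
        if len(set(names)) != len(names):
            raise SpecError("subtype names must be unique")
        for stratum, p in self.composition.items():
            tp, cond = stratum
            if tp not in TIMEPOINTS or cond not in CONDITIONS:
                raise SpecError(f"invalid stratum {stratum}")
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.subtypes),) or (p < 0).any():
                raise SpecError(f"composition for {stratum} must be a probability vector")
            if abs(p.sum() - 1.0) > 1e-9:
                raise SpecError(f"composition for {stratum} sums to {p.sum()}, not 1")
            self.composition[stratum] = p
        if set(self.n_cells) != set(self.composition):
            raise SpecError("n_cells and composition must cover the same strata")
        if not (0 <= self.doublet_rate < 0.5):
            raise SpecError("doublet_rate must be in [0, 0.5)")
        if not (0 <= self.lowq_rate < 1):
            raise SpecError("lowq_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise SpecError("nb_dispersion must be > 0")
        named = self.named_genes()
        if self.n_genes < len(named):
            raise SpecError(
                f"n_genes={self.n_genes} smaller than the {len(named)} named genes"
            )
        if self.arrested_subtypes is None:
            self.arrested_subtypes = frozenset(self.progression_genes)

    def named_genes(self) -> list[str]:
        """Marker + progression genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for st in self.subtypes:
            for g in st.all_markers:
                seen.setdefault(g)
        for genes in self.progression_genes.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def gene_ids(self) -> list[str]:
        named = self.named_genes()
        n_fill = self.n_genes - len(named)
        return named + [f"G{i:04d}" for i in range(n_fill)]

    def strata(self) -> list[tuple[str, str]]:
        order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
        cord = {c: i for i, c in enumerate(CONDITIONS)}
        return sorted(self.composition, key=lambda s: (order[s[0]], cord[s[1]]))


@dataclasses.dataclass
class TruthTable:
    """Ground truth for every generated cell and gene."""

    cells: pd.DataFrame  # cell_id, subtype, doublet, lowq, timepoint, condition, mouse_id
    genes: pd.DataFrame  # gene_id, marker_of, progression_of


def _expression_weights(
    spec: GeneratorSpec, subtype: SubtypeSpec, stratum: tuple[str, str]
) -> np.ndarray:
    """Relative expression weight per gene for one subtype in one stratum."""
    genes = spec.gene_ids()
    base = subtype.baseline_mean
    markers = set(subtype.all_markers)
    w = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in markers:
            w[i] = base * subtype.multiplier
        elif _is_lineage_marker(spec, g):
            w[i] = base * OFF_WEIGHT_FRACTION
        else:
            w[i] = base
    tp, cond = stratum
    prog = spec.progression_genes.get(subtype.name, ())
    if prog and tp in ("P7", "P21"):
        progressed = cond == "normoxia" or subtype.name not in spec.arrested_subtypes
        if progressed:
            idx = {g: i for i, g in enumerate(genes)}
            for g in prog:
                w[idx[g]] *= spec.progression_multiplier
    return w


def _is_lineage_marker(spec: GeneratorSpec, gene: str) -> bool:
    for st in spec.subtypes:
        if gene in st.all_markers:
            return True
    return False


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with the given mean matrix."""
    lam = rng.gamma(shape, np.asarray(mean) / shape)
    return rng.poisson(lam).astype(np.int64)


def _single_cell_counts(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    weights: np.ndarray,
    depth: float,
    restrict: np.ndarray | None = None,
) -> np.ndarray:
    w = weights.copy()
    if restrict is not None:
        mask = np.zeros(len(w), dtype=bool)
        mask[restrict] = True
        w[~mask] = 0.0
    mean = depth * w / w.sum()
    return _nb_draw(rng, mean, spec.nb_dispersion)


def generate(spec: GeneratorSpec) -> tuple[CountMatrix, TruthTable]:
    """Draw a CountMatrix + TruthTable from a GeneratorSpec.

    Deterministic: identical spec + seed give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    subtype_names = [s.name for s in spec.subtypes]

    columns: list[np.ndarray] = []
    records: list[dict] = []
    cell_counter = 0

    for stratum in spec.strata():
        tp, cond = stratum
        n = spec.n_cells[stratum]
        comp = spec.composition[stratum]
        n_doublet = int(round(n * spec.doublet_rate))
        n_lowq = int(round(n * spec.lowq_rate))
        n_singlet = n - n_doublet - n_lowq
        if n_singlet < 0:
            raise SpecError(f"doublet+lowq rates exceed stratum size for {stratum}")

        # cache per-subtype weights for this stratum
        wcache = {
            s.name: _expression_weights(spec, s, stratum) for s in spec.subtypes
        }
        mice = [f"{tp}_{cond[0].upper()}_{i}" for i in (1, 2)]
        sexes = {mice[0]: "F", mice[1]: "M"}

        def new_cell(counts, subtype, doublet, lowq):
            nonlocal cell_counter
            mouse = mice[int(rng.integers(2))]
            records.append(
                {
                    "cell_id": f"cell_{cell_counter:05d}",
                    "subtype": subtype,
                    "doublet": doublet,
                    "lowq": lowq,
                    "timepoint": tp,
                    "condition": cond,
                    "mouse_id": mouse,
                    "sex": sexes[mouse],
                }
            )
            columns.append(counts)
            cell_counter += 1

        # ordinary singlets; depths floored safely above the QC threshold so
        # that only the dedicated low-quality cells can fail QC
        labels = rng.choice(len(spec.subtypes), size=n_singlet, p=comp)
        depths = np.maximum(
            rng.lognormal(np.log(spec.depth_mean), spec.depth_sd, size=n_singlet),
            1.3 * QC_MIN_READS,
        )
        for lab, depth in zip(labels, depths):
            name = subtype_names[lab]
            counts = _single_cell_counts(rng, spec, wcache[name], depth)
            new_cell(counts, name, False, False)

        # doublets: additive mixtures of two same-stratum draws
        for _ in range(n_doublet):
            a, b = rng.choice(len(spec.subtypes), size=2, p=comp)
            da, db = rng.lognormal(np.log(spec.depth_mean), spec.depth_sd, size=2)
            counts = _single_cell_counts(
                rng, spec, wcache[subtype_names[a]], da
            ) + _single_cell_counts(rng, spec, wcache[subtype_names[b]], db)
            new_cell(counts, f"{subtype_names[a]}+{subtype_names[b]}", True, False)

        # low-quality cells: alternate low depth / few expressed genes
        lowq_labels = rng.choice(len(spec.subtypes), size=n_lowq, p=comp)
        for j, lab in enumerate(lowq_labels):
            name = subtype_names[lab]
            if j % 2 == 0:
                depth = float(
                    np.clip(rng.lognormal(np.log(15_000), 0.4), 1_000, 0.8 * QC_MIN_READS)
                )
                counts = _single_cell_counts(rng, spec, wcache[name], depth)
            else:
                depth = rng.lognormal(np.log(spec.depth_mean), spec.depth_sd)
                keep = rng.choice(
                    spec.n_genes, size=min(300, QC_MIN_GENES - 100), replace=False
                )
                counts = _single_cell_counts(rng, spec, wcache[name], depth, restrict=keep)
            new_cell(counts, name, False, True)

    cells = pd.DataFrame.from_records(records)
    counts = np.column_stack(columns) if columns else np.zeros((len(genes), 0), dtype=np.int64)
    cm = CountMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells["cell_id"].tolist(),
        cell_meta=cells[["mouse_id", "timepoint", "condition", "sex"]],
    )

    marker_of: dict[str, list[str]] = {g: [] for g in genes}
    for st in spec.subtypes:
        for g in st.all_markers:
            marker_of[g].append(st.name)
    prog_of: dict[str, list[str]] = {g: [] for g in genes}
    for name, gs in spec.progression_genes.items():
        for g in gs:
            prog_of[g].append(name)
    gene_df = pd.DataFrame(
        {
            "gene_id": genes,
            "marker_of": [";".join(marker_of[g]) for g in genes],
            "progression_of": [";".join(prog_of[g]) for g in genes],
        }
    )
    truth = TruthTable(
        cells=cells[
            ["cell_id", "subtype", "doublet", "lowq", "timepoint", "condition", "mouse_id"]
        ],
        genes=gene_df,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# default study-like spec


#: fraction of the hyperoxia arm taken by the emergent Acta1+ populations
HA_FRACTION = 0.08

_SUBTYPE_TABLE: list[tuple[str, tuple[str, ...], bool]] = [
    ("Fibroblast precursor", ("Adh1", "Col13a1", "Col14a1", "Hsd11b1", "Hif3a"), False),
    ("Early alveolar fibroblast", ("Adh1", "Col13a1", "Wnt2", "Mest"), False),
    ("Alveolar fibroblast", ("Adh1", "Col13a1", "Wnt2", "Spon1"), False),
    ("Early adventitial fibroblast", ("Adh1", "Col14a1", "Mfap5", "Dcn", "Meg3"), False),
    ("Adventitial fibroblast", ("Adh1", "Col14a1", "Mfap5", "Dcn", "Podn"), False),
    ("Proliferating fibroblast", ("Adh1", "Col13a1", "Wnt2"), True),
    ("ASM/MyoF precursor", ("Tgfbi", "Hhip", "Pdgfra", "Crh"), False),
    ("Early ASM", ("Tgfbi", "Hhip", "Aspn"), False),
    ("ASM", ("Tgfbi", "Hhip", "Lum"), False),
    ("Myofibroblast", ("Tgfbi", "Pdgfra", "Stc1"), False),
    ("Proliferating myofibroblast", ("Tgfbi", "Pdgfra", "Stc1"), True),
    ("VSM", ("Pdgfrb", "Tagln", "Acta2", "Eln", "Prrx1", "Osr1", "Id4"), False),
    ("Pericyte", ("Pdgfrb", "Cox4i2", "Mcam", "Postn", "Tbx4"), False),
    ("Proliferating pericyte", ("Pdgfrb", "Cox4i2", "Mcam", "Tbx4"), True),
    ("HA1", ("Acta1", "Tubb3", "Lgals3", "Aqp3", "Actc1"), False),
    ("HA2", ("Acta1", "Tubb3", "Lgals3", "Aqp3", "Wnt2", "Col13a1"), False),
]

# composition over the 14 normal subtypes (HA1/HA2 appended as zeros for
# normoxia).  Proportions are free choices shaped to the study design:
# fibroblast precursors dominate E18.5 and vanish postnatally, ASM/MyoF
# peaks at P7, mural abundance rises steadily, P21 holds mature types only.
_COMPOSITION_14 = {
    "E18.5": [0.40, 0.05, 0.00, 0.05, 0.00, 0.08, 0.25, 0.02, 0.00, 0.02, 0.00, 0.04, 0.08, 0.01],
    "P1":    [0.02, 0.30, 0.00, 0.15, 0.00, 0.08, 0.05, 0.12, 0.00, 0.12, 0.02, 0.04, 0.08, 0.02],
    "P7":    [0.00, 0.18, 0.02, 0.08, 0.02, 0.06, 0.00, 0.15, 0.01, 0.18, 0.08, 0.06, 0.12, 0.04],
    "P21":   [0.00, 0.00, 0.30, 0.00, 0.18, 0.00, 0.00, 0.00, 0.12, 0.00, 0.00, 0.12, 0.26, 0.02],
}

_N_CELLS = {
    ("E18.5", "normoxia"): 500,
    ("P1", "normoxia"): 600,
    ("P7", "normoxia"): 700,
    ("P21", "normoxia"): 500,
    ("P7", "hyperoxia"): 700,
}

_PROGRESSION = {
    "Pericyte": ("Enpp2", "Cxcl14") + tuple(f"Prg_Peri_{i}" for i in range(6)),
    "Myofibroblast": tuple(f"Prg_MyoF_{i}" for i in range(8)),
    "Early ASM": tuple(f"Prg_EASM_{i}" for i in range(8)),
    "Early alveolar fibroblast": tuple(f"Prg_EAlvF_{i}" for i in range(8)),
    # VSM keeps progressing under hyperoxia: the built-in non-arrested control
    "VSM": tuple(f"Prg_VSM_{i}" for i in range(8)),
}

_ARRESTED = frozenset(
    ["Pericyte", "Myofibroblast", "Early ASM", "Early alveolar fibroblast"]
)


def default_study_spec(
    seed: int,
    n_cells: Mapping[tuple[str, str], int] | None = None,
    doublet_rate: float = 0.03,
    lowq_rate: float = 0.05,
) -> GeneratorSpec:
    """Spec emulating the study design: 4 time points in normoxia, a
    hyperoxia arm at P7 whose composition mirrors P1 (encoding the arrest
    finding) plus HA1/HA2 Acta1+ populations restricted to hyperoxia.
    """
    # Each subtype carries, beyond its canonical markers, a private
    # three-gene signature standing in for the dozens of subtype-specific
    # genes real cell types express.
    subtypes = [
        SubtypeSpec(
            name=n,
            marker_genes=m + tuple(f"Sig{i:02d}_{j}" for j in range(3)),
            proliferating=p,
        )
        for i, (n, m, p) in enumerate(_SUBTYPE_TABLE)
    ]
    composition: dict[tuple[str, str], np.ndarray] = {}
    for tp, p14 in _COMPOSITION_14.items():
        composition[(tp, "normoxia")] = np.array(p14 + [0.0, 0.0])
    p1 = np.array(_COMPOSITION_14["P1"])
    hyper = np.concatenate(
        [(1.0 - HA_FRACTION) * p1, [HA_FRACTION / 2, HA_FRACTION / 2]]
    )
    composition[("P7", "hyperoxia")] = hyper
    return GeneratorSpec(
        subtypes=subtypes,
        composition=composition,
        n_cells=dict(n_cells) if n_cells is not None else dict(_N_CELLS),
        progression_genes=dict(_PROGRESSION),
        arrested_subtypes=_ARRESTED,
        doublet_rate=doublet_rate,
        lowq_rate=lowq_rate,
        seed=seed,
    )
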