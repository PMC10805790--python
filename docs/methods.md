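# Methods

`lungmes` re-implements, as a tested library and CLI, a single-cell
analysis of the perinatal mouse lung mesenchyme: plate-based (Smart-seq2
style) scRNA-seq of mesenchymal cells at E18.5, P1, P7 and P21, plus a
hyperoxia (80% O₂, birth→P7) arm modeling bronchopulmonary dysplasia.
This note records the models, the parameter choices, and what the
synthetic data can and cannot establish.

## Pipeline

**QC.** Cells with fewer than 50,000 total counts or fewer than 400
detected genes are discarded; both thresholds are inclusive on the
keep side (a cell at exactly 50,000 / 400 survives). Totals are taken
from the count-matrix column sums, standing in for uniquely mapped
reads.

**Normalization.** Counts per million (CPM): each retained cell's
column is scaled to sum to 10⁶. Zero-total cells are a hard error by
construction — QC must run first.

**Feature selection.** Per mouse, each gene's Fano factor (sample
variance / mean of CPM; genes with zero mean score 0) is ranked; a gene
is "high" in a mouse if it sits in that mouse's top *n* = 500. Genes
high in at least half the mice (the `mouse_majority_fraction = 0.5`
knob) are kept, ranked by vote count, then median Fano, then gene
symbol. The majority vote deliberately favors reproducible
overdispersion; its known cost is that genes expressed only in a
condition- or age-restricted subset of mice (e.g. genes private to the
hyperoxia arm or to P21) cannot be selected.

**Embedding.** log10(CPM + 0.1) of the selected genes, gene-centered
PCA (no unit-variance scaling), top 25 components. Each component's
sign is fixed so its largest-magnitude loading is positive, making the
embedding fully deterministic. Log base is a free choice: any fixed
base rescales all inputs uniformly and leaves clustering invariant.
t-SNE (seeded, perplexity ≤ 30) is provided for figures only; no
statistic is ever computed in t-SNE coordinates.

**Clustering.** Leiden community detection (RBConfiguration quality,
`leidenalg`) on the unweighted symmetric kNN graph in PC space.
Defaults: `n_neighbors = 10`, `resolution = 2.0`, chosen once on a
development seed so that the expected ~16 populations of the default
simulation separate; over-clustering is harmless downstream (rule
annotation maps sub-clusters to the same subtype), under-clustering is
not, so the default leans fine. Labels are renumbered by decreasing
cluster size.

**Doublet exclusion.** A cell is flagged when (a) its cluster has fewer
than 10 cells, or (b) it co-expresses (CPM > 100) at least one gene
from each side of an incompatible marker pair. The shipped pair list
crosses the three mesenchymal groups (Adh1/Tgfbi/Pdgfrb) and, within
groups, lineages that never co-occur in a single cell type — pairs that
a legitimate precursor co-expresses (Hhip + Pdgfra, Col13a1 + Col14a1)
are deliberately excluded. Doublets formed from two cells of the same
lineage are not detectable by this rule; on simulated data this caps
recall around 0.8.

**Subtype annotation.** Per cluster, a gene is *positive* when its mean
CPM exceeds 50 **and** more than 25% of the cluster's cells express it
above a 10 CPM floor. The floor keeps stray single-molecule counts of
silent genes from qualifying; without it a handful of unflagged
doublets can push a silent marker's cluster mean over threshold. The
cluster receives the first rule (in table order, more specific rules
first) whose required-positive genes are all positive and whose
required-negative genes are all non-positive: fibroblasts (Adh1) split
by Col13a1 vs Col14a1 (both = precursor) and maturity markers
(Spon1, Podn); ASM/MyoF (Tgfbi) split by Hhip vs Pdgfra (both =
precursor) and Lum (mature ASM); mural cells split into VSM
(Tagln/Acta2 + Pdgfrb, Tgfbi-negative) and pericytes (Cox4i2); Mki67
positivity sets the proliferating flag and selects the proliferating
rule variants. Clusters matching no rule but positive for the full
Acta1 panel (Acta1, Tubb3, Lgals3, Aqp3) are reported as `HA-novel-k`
— the emergent hyperoxia-associated populations; anything else is
`unassigned`.

**Atlas co-embedding and ellipse reannotation.** Query and reference
count matrices are intersected on genes, jointly CPM-normalized,
feature-selected and PCA-embedded; each cell's coordinates are then
averaged with its ⌈k/2⌉ nearest neighbors from *each* source (k = 10
total). This batch-balanced neighbor averaging is intentionally
minimal: the contract is "same-type cells from the two sources land
together", which the tests assert by a distance-ratio criterion, not
fidelity to any particular published harmonization tool. Reannotation
fits the mean and covariance of a focal cell set in the top 2 joint
PCs and returns other-source cells within a rigidly expanded
Mahalanobis ellipse of radius `expansion × sqrt(χ²₀.₉₅(2))`, defaults
expansion 1.5 and quantile 0.95 (free choices; only "rigidly expanded"
is inherited).

## Statistics

**Differential expression.** Per gene, the two-sample
Kolmogorov–Smirnov statistic on CPM values between two disjoint cell
sets; exact p-values when both groups have ≤ 25 cells, the asymptotic
Kolmogorov distribution otherwise; Bonferroni correction over the genes
actually tested. A *signed* KS (sign of the mean difference, magnitude
= KS statistic) makes the statistic directional; log₂ fold changes use
pseudocount 0.1 on group means, mirroring the embedding pseudocount.
Gene ranking offers two modes: top |KS|, or — the fold-change mode —
genes with KS ≥ 0.3 ordered by |log₂FC|.

**TF quadrant fingerprint.** Each transcription factor is scored by
signed KS of a focal population against two references (e.g. VSM vs
pericytes on x, VSM vs ASM on y); the sign pair assigns the quadrant
(specific-up, specific-down, mixed). The choice of signed KS as the
"enrichment" axis is this package's own; only expressed TFs are scored.

**Compositional arrest bootstrap.** Subtype composition vectors are
built from non-doublet cells of the hyperoxic stratum and of two
healthy references (P1, P7). Per replicate, n = (smallest stratum
size) cells are resampled with replacement from each stratum
("balanced"), and d(focal, P7) − d(focal, P1) recorded with d = total
variation distance (½ L1) — the canonical compositional metric;
Euclidean is available behind a flag and the distance name is recorded
in every result. The empirical P is the fraction of B = 1000
replicates with difference ≤ 0, ties counting against the arrest
hypothesis (conservative). Each stratum draws from its own
seed-derived random stream, so swapping the two references exactly
negates every replicate. Composition is over fine subtypes by default;
group-level vectors are an option.

**Progression-gene arrest.** Within one cell type, progression genes
are those with signed KS > 0 and KS ≥ 0.3 comparing normoxia P7 vs P1.
Each is then compared hyperoxia-P7 vs normoxia-P7; the arrest fraction
is the share with negative signed KS. Caveat: when the two P7 strata
truly have identical expression, each gene's sign is a fair coin, so
the null arrest fraction is a Binomial(m, ½) proportion around 0.5 —
and with small strata, selection noise (winner's curse on the P1→P7
comparison) biases it above 0.5. Interpret arrest fractions against
that baseline, not against 0.

**Ligand–receptor analysis.** For a user-supplied pair table (the
schema matches an export from any LR resource; none is bundled), an
interaction is *detected* in a (source type, target type, stratum)
triple when at least 20% of source cells express the ligand and at
least 20% of target cells the receptor — inclusive at the threshold,
with "express" = CPM > 0 (appropriate for deep plate-based libraries;
the floor is a knob). Interaction strength is the symmetric product
(mean ligand CPM × source proportion) × (mean receptor CPM × target
proportion), proportions over non-doublet stratum cells; a variant
using only the source-side abundance is available behind
`source_abundance_only`.

## The synthetic study

The generator draws counts from a negative binomial (gamma-Poisson)
with one global shape parameter r = 2.0 — overdispersed (CV² ≈ 0.5 at
high expression) yet tight enough that log-CPM of an "on" marker has
spread ≈ 0.35 dex, in the range of deep plate-based data. Each cell
has a log-normal target depth (median 150,000 counts, σ_log = 0.25,
floored safely above the QC threshold) over 800 genes: ~700 background
genes, canonical markers, and per-subtype three-gene private
signatures standing in for the dozens of genes real subtypes
differentially express. Markers multiply a subtype's baseline weight
by 30; in all other subtypes a lineage marker sits at 0.002× baseline
(near-silent), so positivity and doublet thresholds behave as they do
for real on/off lineage genes.

The default study: 16 subtypes (14 normal + HA1/HA2), five strata
(E18.5/P1/P7/P21 normoxia of 500/600/700/500 cells, P7 hyperoxia of
700), compositions shaped to the study design — precursors dominate
prenatally and vanish after birth, ASM/MyoF and proliferation peak at
P7, mural abundance rises steadily, P21 keeps only mature types. The
hyperoxia arm re-uses the P1 composition scaled by 0.92, with the
remaining 8% split between HA1 and HA2 (which never appear in
normoxia) — encoding both the compositional arrest and the emergent
Acta1+ populations. Proportions are free choices: the source study
reports compositions only graphically. Progression genes (8 per
affected type, including Enpp2/Cxcl14 for pericytes) gain a 4× mean at
P7/P21 in normoxia; for arrested subtypes (pericytes, myofibroblasts,
early ASM, early alveolar fibroblasts) the hyperoxia arm stays at the
P1 level, while VSM keeps progressing under hyperoxia and serves as
the built-in non-arrested control. Doublets (3%) are additive mixtures
of two same-stratum cells; low-quality cells (5%) get either a
sub-threshold depth or expression restricted to 300 genes.

What passing tests show — and what they do not. The simulation has
independent genes given the subtype, a single dispersion, no ambient
RNA, no batch effects beyond the mouse label, and no empirical
library-size distribution; recovery results (≈ 99% subtype accuracy,
doublet recall ≈ 0.8 at precision ≈ 1) therefore certify the
*logic* of the pipeline under its stated assumptions, not performance
on real data. One known, deliberate limitation: HA2 shares Wnt2 and
Col13a1 with alveolar fibroblasts, and since hyperoxia-private genes
cannot pass the most-mice feature vote, HA2 often co-clusters with
alveolar fibroblasts while HA1 is always recovered as a pure
hyperoxia-only novel cluster — a realistic failure mode the annotation
accuracy already accounts for.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; every stochastic stage takes a seed.
* PCA uses the full SVD solver; the sign convention (largest loading
  positive) removes solver sign ambiguity.
* KS p-values are clipped to (0, 1]; Bonferroni m is the number of
  genes actually tested after any subset restriction.
* Empty QC results, empty LR tables, and empty gene subsets are legal
  and return empty outputs; zero-total cells, overlapping DE cell sets,
  singular ellipse covariances, and compositions that do not sum to 1
  are hard errors with actionable messages.
* Result tables are TSV with ≥ 10 significant digits and a provenance
  header (config hash, seed, stage); `summary.json` is key-sorted so
  identical runs are byte-identical.
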