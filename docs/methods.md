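# Methods

## Scope and model

`amcpipe` converts heterogeneous quantifications of brain proteins and
metabolites into one table of molar concentrations (µM) with full
provenance (study, species, brain region, cell type, subcellular
location, condition, age). The pipeline has five stages: ingest,
nomenclature alignment, per-study concentration estimation, housekeeping
normalization, and statistical validation. Metabolites follow a parallel
path: unit standardization, PubChem CID alignment, and tissue-level
prediction by compartment mixing.

## Nomenclature alignment

Gene names are vertices of an undirected graph; every pair of names
co-listed on one data entry or one synonym-table row is an edge.
Connected components are synonym groups. The canonical name of a
component is its most frequent member, counted over data-entry
occurrences only (synonym-table rows contribute edges, not counts).
Ties prefer names present in the mouse synonym table, then the
lexicographically smallest uppercase name — a deterministic,
reproducible stand-in for manual curation. Comparison is
case-insensitive and canonical output is uppercase so mouse-style
(`Stxbp1`) and human-style (`STXBP1`) symbols unify; the cost is that
isoform-level distinctions are deliberately merged under gene symbols.
Components containing two names with non-empty, disjoint accession sets
are reported as conflicts and flagged, never auto-split: a co-listing
can erroneously bridge two real proteins, and splitting automatically
would hide the problem instead of surfacing it. Live database queries
are replaced by a required offline synonym table
(accession ↔ pipe-separated gene names ↔ species) for reproducibility.

## Digestion and detectability

MS intensity scales with how many peptides a protein yields, so
LFQ/TMT/SILAC signals are divided by the count of theoretical peptides:
the sequence is cut immediately after every K/R (trypsin) or K (lysC),
zero missed cleavages, no proline exception, and fragments of 6–29
residues inclusive are counted. iBAQ is already peptide-normalized and
takes a factor of 1; a protein with zero countable peptides cannot carry
a peptide-scaled signal and is excluded with a warning. Molecular
weights are average (not monoisotopic) masses — residue masses plus one
water — because the estimation needs bulk mass, and weights supplied by
the source data are passed through unchanged. UniProt wildcard `X` is
assigned the mean residue mass; `B/J/O/U/Z` are rejected rather than
guessed. The initiator methionine is kept.

## Concentration estimation

The total-protein-mass approach assumes a fixed total cellular protein
concentration (200 g/L) and protein mass per cell (200 pg). These bulk
constants are commonly used but not cell-type specific; both are exposed
in the configuration for substitution. Detectability-corrected signals
are converted to copy numbers by their share of the per-cell protein
mass, and to molar concentrations by the implied cell volume. Two exact
identities follow and are enforced as tests: cell volume =
200 pg / 200 g/L = 1e-12 L regardless of inputs, and the mass-weighted
concentration sum recovers 200 g/L. Concentrations are scale-invariant
under global multiplication of a study's signals, which is what makes
arbitrary-unit intensities usable at all. Entries with zero or missing
signal are dropped before the sums (they carry no quantification);
replicate columns are treated as separate cellular proteomes and
estimated independently. Values already reported in molar units are
metrically rescaled; mol per g protein crosses to molar via the 200 g/L
bridge.

The method needs proteome-scale coverage: with few proteins the fixed
protein mass concentrates into too few species and absolute values
inflate (visible in the README's three-protein example). This matches
the known limitation of the approach for low-coverage studies.

## Housekeeping normalization

Each study is multiplied by `reference_median / study_housekeeping_median`
on the linear µM scale, which equalizes housekeeping medians across
studies exactly and is idempotent. The reference median is computed from
housekeeping entries of healthy, young-to-middle-aged mouse data
(including mouse cell lines). Organelle-only studies are normalized with
the reference but excluded from computing it, since their concentration
scale is not cellular; they are identified by an explicit study-id list
in the configuration, not inferred from metadata. Housekeeping
membership is by canonical gene symbol after nomenclature alignment,
because housekeeping lists are transcript-derived.

## Metabolites

Unit conversions use brain density 1.04 g/mL and 80% water content.
The dry↔wet bridge reads 1 mg dry = 5 mg wet, the only consistent
reading of those constants, so 1 nmol/mg dry = 208 µM. Conversions are
linear in the value and exactly invertible (round-trip identity to
1e-9 relative, property-tested). MRS and MS values are tagged but not
cross-corrected (the method mainly affects variance, not location);
species differences are flagged, not corrected. Tissue prediction is the
convex combination of compartment concentrations with volume fractions
extracellular 0.19, vasculature 0.03, neuronal somas 0.10, neurites
0.60, glia 0.08. Neuronal concentration supplies both soma and neurite
fractions; the glia term uses the astrocytic concentration, imputed from
the neuronal one when absent. Records missing a blood or extracellular
value are excluded rather than imputed — no defensible imputation source
exists for those compartments. Organelle-scale entries are stored but
never mixed.

## Statistical validation

- **Variability score** = |sample SD / mean| / n on linear values.
  "Scaled to the number of measurements" is read as division by n: it
  yields a dimensionless, coverage-penalized score and preserves the
  defining zero case (score 0 iff CV 0). Undefined for n < 2 or zero
  mean; such entries are skipped.
- **Specificity index** = mean ln concentration in the target location
  minus the complement; antisymmetric under target/complement swap.
- **Top-percentile selection** takes the q-quantile (linear
  interpolation) over all concentrations and selects strictly greater
  entries per location.
- **Correlation tables** compute pairwise Pearson r on ln
  concentrations of the proteins common to each pair only (per-gene
  means within groups), because coverage differs too much across studies
  to fix one common protein set; pairs with < 3 common proteins are
  undefined.
- **Median equality** uses Kruskal–Wallis; on rejection at α = 0.05, a
  hand-implemented Conover–Iman post-hoc (t statistics on tie-corrected
  rank sums, df = N−k) with Holm adjustment over all pairs.
- **Two-group battery**: DBM/OVS (|median difference| over the span of
  both groups' 1.5×IQR boxplot whiskers — "overall visible spread" in
  boxplot vocabulary; NaN when the spread is zero), two-sided
  Mann–Whitney U and Kolmogorov–Smirnov, Brown–Forsythe
  (median-centered Levene) and Fligner–Killeen variance tests.
- **Permutation procedure**: 1000 repetitions of drawing N=100 per
  group (without replacement where possible, with replacement as the
  documented fallback), recording rejection rates at α = 0.05. Control
  mode draws both samples jointly without replacement from the pooled
  data — an exact exchangeability null. On ln-scale data all four tests
  calibrate near 0.05; the two-sided KS test is slightly conservative at
  N=100 (discrete exact distribution), so its control rate sits at the
  low end of the band.
- **Differential concentration**: fold change = mean(A)/mean(B) on
  linear values, p from Welch's t on ln concentrations — the minimal
  standard choice for lognormal abundances, isolated in one function so
  it can be substituted. Linear thresholds 1.15 / 0.87; log2 thresholds
  ±2; α = 0.05. Genes with < 2 replicates on a side are skipped.
- **RNA-to-protein**: one ratio per gene (protein µM / expression,
  replicates averaged first), zero-expression genes excluded and
  reported; prediction is gene-wise linear and exactly self-consistent
  on the reference. No smoothing, no cell-type correction —
  cross-cell-type degradation is an expected, reported property.

## Synthetic data

The generator emulates multi-study integration conditions: lognormal
true copy numbers (median 1e4 copies/cell, ln-SD 2.3, i.e. ~4 orders of
magnitude — typical of deep MS proteomes), sequences with lognormal
lengths (median 400 residues, ln-SD 0.45) and ~11% K/R so > 90% of
proteins yield detectable tryptic peptides, per-study batch scale
factors, unit-mean lognormal measurement noise, iid per-entry synonym
corruption through a registered invertible registry, and dropout guarded
so housekeeping genes never vanish entirely. The designated housekeeping
subset (~5% of genes) is drawn from mid-to-high abundance so study
medians over it are stable. Everything is reproducible bit-for-bit from
the seed.

What it does not emulate: peptide-level identification, shared peptides,
missingness correlated with abundance, inter-replicate structure, or
real synonym ambiguity (each gene has exactly one registered synonym).
Passing recovery tests therefore shows the pipeline inverts the nuisances
it models — batch scale, detectability, unit heterogeneity, label
corruption — not that it removes every bias in real data.

Under iid 20% corruption across five studies, a minority of genes end up
observed more often under the synonym than the official symbol, in which
case the frequency rule canonicalizes to the synonym. This is correct
behavior ("most frequent name"), and restoration is accordingly defined
as assigning a corrupted entry the same canonical name as its gene's
other entries — which the graph achieves completely; ground truth joins
through the same canonical map.

## Numerical choices and degenerate inputs

Concentrations are stored in µM and serialized with 12 significant
digits (round trips well beyond 1e-9 relative). Quantile and whisker
computations use linear interpolation of the empirical distribution.
Degenerate cases raise informative errors: all-zero studies, empty
reference pools, studies without housekeeping genes, volume fractions
not summing to 1 (±1e-9), conflicting CID tables, fewer than 3 common
compounds/proteins for correlations. Zero-variance differential groups
get p decided by exact mean equality rather than NaN propagation.
Processing is order-deterministic: study files are read sorted and
records sorted by (study, gene) before estimation.

## Problem sizes

The test and acceptance workloads use 5 studies × 2000 genes for
recovery (per-study ln-scale Pearson r with truth ≈ 0.996 at 20% noise),
1000 random sequences for the digestion oracle, and 1000 permutation
repetitions at N=100 for calibration — sizes at which every stochastic
check is stable while the whole suite runs in seconds.
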