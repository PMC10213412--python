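# Methods

This note records the models, conventions and numerical choices behind
`soilfoodweb`, and what the synthetic-data tests do and do not establish
about real data.

## Faunal analysis

Genera map to trophic guilds and c-p values through a curated reference
table shipped with the package (`data/trait_reference.csv`, 36 common
genera with body masses in µg fresh weight); users can supply their own.
The omnivore–predator guild is stored split into omnivores (Om) and
predators (Ca) because their structural components differ (Om3–Om5 vs
Ca2–Ca5); a coarse `OP` label defaults to `Om`.

Component weights follow the standard faunal-analysis scheme consistent
with the channel-index formula (3.2 for Ba1, 0.8 for Fu2):
e = 3.2·Ba1 + 0.8·Fu2, b = 0.8·(Ba2+Fu2), s weights 0.8/1.8/3.2/5.0 for
cp 2/3/4/5 over Ba3–5, Fu3–5, Om3–5 and Ca2–5. The maturity index uses
all free-living taxa (Ba ∪ Fu ∪ Om ∪ Ca) including cp-1 opportunists; the
formula carries no cp-range restriction. Indices whose denominator is
zero are missing values (NaN), propagated through downstream statistics —
an empty enrichment channel is not the same as CI = 0.

**FDis.** Mixed trait types (guild categorical, c-p ordinal-as-numeric,
log body mass numeric, each range-scaled) require a Gower dissimilarity,
which we embed by principal coordinates before taking the
abundance-weighted distance to the weighted centroid. Negative PCoA
eigenvalues (Gower matrices need not be Euclidean) use the standard
corrected squared distance (positive-axis minus negative-axis terms),
clipped at zero. Which traits enter FDis is a genuine free choice; the
three shipped traits are the ones the reference table provides, and the
trait set is easy to change by passing a reduced reference.

**Predation pressure.** Counts arrive per 100 g dry soil and 16S copies
per g; both are converted to a per-gram basis before division (the
`counts_basis_g` argument records the convention). The absolute scale is
therefore ~10⁻⁸–10⁻⁶ nematodes per copy; only relative comparisons are
meaningful.

**Metabolic footprints** use the standard production + respiration
composite F = Σ N(0.1·W/cp + 0.273·W^0.75). They are optional: they need
body masses, and the footprint of a sample is skipped with a warning when
masses are incomplete.

## ¹⁸O physiology and mineralization

The constants are fixed by the method definitions: 31.21 % oxygen mass
fraction of DNA, 22.4 L mol⁻¹ molar gas volume (STP — no temperature
correction is applied to the 15 °C incubation; the bias is a constant
factor ≈ 288/273 on respiration and cancels in all ratios of respiration
measurements), 12.01 g mol⁻¹ carbon. Blank correction subtracts the
soil-free vial's ΔCO₂ and floors at zero. CM uses the CO₂ equivalent
mass 22 (two HCl per carbonate) over the jar's soil mass in kg; an
`as_carbon` flag converts CO₂ to CO₂-C (×12.01/44.01). Validation is
strict at record construction: atom% excess must not exceed the label,
titration volume must not exceed the blank.

## Community metrics

Rarefaction is multivariate-hypergeometric (without replacement), the
urn model of QIIME-style subsampling; samples below the target depth are
dropped with a warning, never up-sampled. Bray–Curtis comes from scipy's
`pdist`; zero-total samples yield NaN rows rather than an arbitrary 0 or
1. Ordination (NMDS/PCoA) is delegated to established implementations
(scikit-learn MDS, eigendecomposition) and treated as an opaque stage;
only the distance matrix feeding it is computed and tested here.

## Statistics

*Tukey letters.* Pairwise p-values from the studentized-range
distribution (scipy `tukey_hsd`, Tukey–Kramer for unequal n); the compact
letter display is built by insert-and-absorb, so two groups share a
letter exactly when their difference is not significant. Letters are
assigned in order of first appearance of the groups.

*Variance partitioning.* Redundancy R² = SS(fitted)/SS(total) from least
squares of the column-centred response table on each predictor set, with
Ezekiel adjustment 1−(1−R²)(n−1)/(n−m−1) where m is the *rank* of the
centred predictor matrix. Rank-based degrees of freedom make perfect
between-set redundancy legal (X1 = X2 puts everything into the shared
fraction b, as in vegan); only within-set collinearity is an error,
reported with the offending columns. Negative adjusted fractions are
reported as-is. The interface takes two predictor tables; a third set
can be partitioned by composing calls on residuals, which we deliberately
did not wrap because the two-set design covers the intended analyses.

*envfit.* r² is the squared multiple correlation of the variable on the
axis scores; significance permutes the variable's rows with
p = (1+count)/(n_perm+1), the exact-test convention that keeps p ≥
1/(n_perm+1) and avoids zero p-values.

*Spearman.* Pairwise-complete observations, average ranks for ties,
two-sided p from the t approximation on n−2 df (approximate below
n ≈ 10; exact enumeration is not offered). Matrix p-values are reported
raw; `bh_adjust` provides an optional Benjamini–Hochberg column because
no particular correction is canonical for these descriptive matrices.

## Synthetic studies

The generator emulates a five-treatment trial (CK, N, NS, NSM, NB — 
unfertilized, mineral, +straw, +straw & manure, +straw biochar), three
replicates each. Baseline guild shares are Ba 47.6 %, Fu 25.7 %,
Pp 13.3 %, OP 13.4 %; default treatment multipliers encode the
qualitative ordering typical of such amendments (straw+manure highest in
total nematodes, bacterivores, 16S copies and growth; mineral-only lowest
among fertilized; a relatively fungal channel under CK/N) without
asserting any field study's numbers. Dispersion and variance defaults
(Dirichlet concentration 200, copy-number CV 10 %, rate CV 8 %, chemistry
SDs of a few percent of the means) are free parameters chosen as
plausible plot-scale variability, not estimates of any dataset.

Counts are Dirichlet-multinomial: expected taxon proportions =
(base guild share × treatment multiplier, renormalized) × fixed
within-guild weights; a per-sample composition ~ Dirichlet(dispersion ×
expectation); counts ~ multinomial at Poisson-drawn depth (default 300
nematodes, 30 000 reads). `dispersion = inf` removes compositional noise;
`noise_free=True` additionally zeroes all measurement noise and replaces
count draws by exact expected counts (then real-valued — the price of
making recovery tests exact identities rather than statistical checks).

Incubation and titration records are constructed by *algebraic inversion*
of the physiology formulas from drawn true rates (fixed assay constants:
20 µg O, 20 atom% label, 1 g, 24 h, 50 mL headspace, 8 µg preculture DNA
per g, 0.4 M HCl, 50 mL blank): atom% excess, ΔCO₂ and V₁ are set so the
analysis formulas return the truth exactly. Inversions that would demand
unphysical records (excess above the label, negative titration volume)
raise instead of silently clipping. The truth table is serialized with
the data so recovery tests never reach into generator internals.

What the generator does **not** emulate: sequence-level reads (no FASTQ;
generation starts at the OTU table), spatial structure, time series,
taxon-specific measurement bias, or realistic phylogenetic correlation
among OTUs. Passing recovery tests therefore demonstrates correctness of
the computational chain, not robustness to real-world measurement error.

## Problem sizes and determinism

Default problem sizes (15 samples, 150 OTUs at depth 30 000, 200-instance
statistical oracle batches, 500-replicate permutation calibration at
n_perm = 199) were chosen so the full verification chain runs in well
under a minute on one core while keeping Monte-Carlo standard errors far
below the asserted tolerances. All randomness flows from explicit integer
seeds through `numpy.random.Generator`; no global RNG state is touched,
and rerunning any stage with the same config is byte-identical.
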