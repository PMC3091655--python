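# Methods

## Coordinate conventions

Chromatin regions are stored with a 1-based start and an exclusive end, so a
region's size is `end − start`. This is the only convention consistent with
the published boundary table, where every printed size equals the end
coordinate minus the start coordinate; it is verified row by row in the test
suite. BED output maps to 0-based half-open coordinates as
`(start − 1, end − 1)`, preserving spans exactly and round-tripping through
the reader.

A transition zone is the gap between the outermost mapped markers of two
adjacent regions on an arm (`left.end` to `right.start`). Zones are
attributed to the boundary irrespective of which side is heterochromatic,
and zero-size zones (abutting regions) are retained because they mark
directly adjacent mapped regions. Genes inside transition zones are treated
as euchromatic: the enrichment module expects the caller to assign them to
the background set, never to the heterochromatic study set.

Heterochromatin aggregates sum the PH, IHc and IHd classes; euchromatin
sums EU and PEU. PEU is nevertheless reported separately throughout because
the count model treats it as a chromatin type in its own right. Report
rounding follows the conventions of the source material: Mb to one decimal,
kb to the nearest integer, percentages to one decimal.

## Repeat and duplication filters

Tandem repeats are accepted only with percent match ≥ 80 and copy number
≥ 2, tightened to ≥ 8 copies for microsatellite periods; accepted records
are binned by period into microsatellites (2–6 bp), minisatellites
(7–99 bp) and satellites (≥ 100 bp). Period-1 homopolymer runs are
rejected. Copy numbers are compared on the raw (possibly fractional) value.
Putative segmental duplications are kept only for alignments ≥ 2,500 bp
with identity strictly above 90%. Genes and MARs carry no thresholds.
External annotation tools are never re-implemented; only their output
formats are read and these stated post-filters applied.

## Windows and tabulation

Windows tile each region exactly: euchromatic regions split into
`ceil(size / 5 Mb)` near-equal windows and heterochromatic regions into
`ceil(size / 1 Mb)`, which keeps heterochromatin windows under 1 Mb
whenever the region is not an exact multiple and at most 1 Mb always. No
window crosses a region boundary, so the chromatin class is constant within
a window.

An interval is *counted* in the window containing its start position — each
interval contributes exactly one count genome-wide, conserving totals —
while *coverage* clips the interval to every window it overlaps, merging
same-class intervals first so overlapping copies are not double-counted.
Coverage is checked against a per-bp marking oracle in the tests. Intervals
on arms with no windows are skipped with a logged warning.

## The Poisson partition model

Window counts follow `C_i ~ Poisson(λ_i)` with
`log λ_i = μ_g + β_g log L_i + ζ_g log(K_i + 1)`, where `g` is the
parameter group of the window's chromatin type under a candidate tying
configuration. The `+1` offset keeps the linear predictor finite for
uncovered windows (K = 0) while preserving their ordering; the offset is
configurable. Natural logarithms are used throughout.

Within a configuration the MLE is found by Newton iteration with step
halving (the log-likelihood is concave), converging to a gradient norm
below `1e−9` relative to the log-likelihood; non-convergence raises with
diagnostics rather than returning a dubious fit. Exactly collinear design
columns — e.g. a group whose windows share a single length, making its β
column a multiple of its intercept column — are detected by pivoted QR and
dropped; the reduced fit is flagged and the parameter count p reflects only
identified columns. Standard errors come from the inverse observed Fisher
information at the MLE. The fitter is cross-checked in the tests against an
independent IRLS implementation (statsmodels GLM) to 1e−6 in
log-likelihood; statsmodels is never used in the fitting path itself.

Configurations are scored by `bic_score = 2·loglik − p·log N` (higher is
better). The published account of this criterion writes a minus sign on the
left of the defining equation yet reports per-model values that equal the
right-hand side; this package therefore stores the right-hand side
directly, labels it the BIC score, and takes ΔBIC as the absolute score
difference — the only reading consistent with the worked retroelement
comparisons (ΔBIC = 3.77 and 1.52), which the tests reproduce. The Bayes
factor of the favored model over the other is approximated by
`exp(½·ΔBIC)`. Verbal support labels follow the usage of those worked
examples: ΔBIC < 1.5 mild, 1.5–3 moderate, 3–10 strong, > 10 decisive.

The default model space is *joint*: one set partition of the five chromatin
types shared by (μ, β, ζ), giving Bell(5) = 52 configurations — chosen
because the hypotheses of interest merge whole chromatin types (e.g.
"PEU = EU"). An *independent* mode (separate partitions per parameter,
Bell(5)³ configurations) is provided for exploration; enumeration refuses
more than eight class labels. The search is exhaustive by default; the
simulated-annealing alternative (proposal: move one class to another or a
new group; Metropolis acceptance on the BIC score; geometric cooling
T₀ = 5, factor 0.999; parameters refit exactly at each visited
configuration, with memoization) requires an explicit seed and is verified
in the tests to reach the exhaustive optimum. Ties are broken toward fewer
parameters, then the canonical configuration label.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested; its defaults are fixed, not tuned per test.

* **Chromatin map.** The layout template reproduces the packaged boundary
  map — the class sequence and size proportions of the five arms, including
  transition-zone gaps — optionally rescaled.
* **Feature intervals.** Per-class interval densities (count/Mb) and union
  coverage fractions default to values qualitatively mirroring the
  published medians: gene density ~5× lower in heterochromatin;
  retroelement coverage peaking in PH; SD coverage peaking in intercalary
  heterochromatin; tandem-repeat coverage highest in PH; MARs concentrated
  in PEU and PH. Counts per region are Poisson(density × size). Interval
  lengths are log-normal (σ = 0.6) with the mean set to
  `−S·ln(1 − f)/ν` (S region size, f target coverage fraction, ν expected
  count); under circular uniform placement this makes the expected union
  coverage exactly `f`, which the tests verify to Monte-Carlo precision.
  Wrap-around spills are emitted as a second clipped row. Attribute values
  (period, copies, match; SD length and identity) are drawn inside the
  acceptance regions of the corresponding filters.
* **Window counts.** Forward simulation of the log-link model under a
  planted tying. The default planted configuration merges EU with PEU and
  keeps the heterochromatin types distinct, with intercept gaps of at least
  1 on the log scale (μ = −6, −6, −5, −7, −4 for EU, PEU, PH, IHc, IHd;
  β = 0.3, ζ = 0.5 shared). Per-window coverage fractions are jittered
  log-normally (σ = 0.6), giving the coverage covariate within-class
  variation.
* **Analysis windows for simulation studies.** Real maps yield window
  lengths that vary across regions because region sizes are not multiples
  of the target; that within-class length variation is what identifies β
  separately from μ. `gen_analysis_windows` reproduces it directly,
  jittering window lengths around the target (never exceeding it) while
  still tiling each region exactly. Without such variation, classes whose
  windows sit at different length scales can be merged freely by tilting β
  — a genuine non-identifiability, not a software artifact.
* **GO annotations.** Term frequencies follow a flat Dirichlet draw; the
  study set is sampled so each planted term's study frequency is the
  enrichment factor times its background frequency in expectation. Factors
  below 1 are refused.
* **Seeding.** A single master seed streams independent per-component
  substreams, so each artifact regenerates independently; all stochastic
  entry points require a seed.

Simulation-study problem sizes were chosen to keep the default suite fast:
partition recovery uses 50 replicates of ≈ 1,600 windows (250-kb/50-kb
windows — the same 5:1 euchromatin:heterochromatin ratio as the full-scale
scheme), Wald coverage uses 200 replicates of ≈ 2,000 windows, and the
annealing/exhaustive equivalence uses 30 replicates of ≈ 200 windows.
Under these conditions the planted partition is recovered in ≈ 95% of
replicates and 95% Wald intervals for μ cover at ≈ 95%.

What passing these simulations does *not* show: the generator draws
independent windows with exactly Poisson counts, no overdispersion, no
spatial autocorrelation along arms, no TE family structure, and no
annotation bias — all present in real genomes. Recovery rates here are
therefore an upper bound on what identically sized real data would give,
and per-feature MAX models on real annotations (which depend on the genome
assembly and annotation versions) are not reproduced by this package.

## GO enrichment

The test statistic is the one-sided hypergeometric upper tail
`P(X ≥ k)` for `k` of `n` study genes carrying a term against `K` of `N`
background genes — the standard test of GO term-finder tools, which the
published pipeline used (the tool is named there; the test form is its
documented default). It is checked against exhaustive draw enumeration for
small backgrounds. The Bonferroni multiplier counts the terms annotated to
at least one study gene (the term-finder convention; configurable to all
background terms), and a term is significant when the corrected p-value is
below α = 0.05. No GO-graph ancestor propagation is performed by default.

## Known limitations

* The per-feature MAX models and absolute BIC values reported for the real
  genome require the original feature annotations and are out of reach of
  the packaged data; the package instead validates its machinery by oracle
  equivalence, planted-partition recovery and interval-coverage
  calibration.
* Counts are strictly Poisson; overdispersed or zero-inflated alternatives
  are not provided.
* Arm identity enters only through window membership: the likelihood
  factorizes over windows, and no arm-level random effect is fitted.
* Divergence-island overlap percentages and window-median gene-density
  ratios quoted in the source material depend on external data not packaged
  here and are not recomputed.
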