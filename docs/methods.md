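# Methods

This note documents the models, the numerical choices, and the design
decisions behind `seascape`, in the order the pipeline runs them. It
also states precisely what the synthetic seascape does and does not
emulate, and therefore what a passing test suite does and does not show
about real data.

## The toy ocean

The velocity field is derived from a streamfunction ψ on a flat
Cartesian grid (default 64×128 cells of 18 km, a one-cell land frame, a
meridional barrier with a gap): ψ = sin(2πx̃)·sin(πỹ) gives two
counter-rotating gyres that meet at the barrier, plus a localized jet
term pumping water eastward through the gap. Velocities are central
differences of ψ (u = −∂ψ/∂y, v = ∂ψ/∂x), so the discrete divergence is
exactly zero on every ocean cell whose four neighbours are ocean; land
cells have zero velocity. Monthly fields are ψ scaled by
1 + A·cos(2πm/12) (seasonal amplitude A = 0.4 by default). The
streamfunction is normalized so the peak speed is 0.15 m/s — slow
enough that within-gyre travel times spread over the 0–1.5-year window
where the turnover statistics operate, fast enough that each gyre mixes
internally within a few years. The calendar is idealized: 12 months of
30 days (86 400 s each), so a year is 360 days; `month_length` is
configurable. No bathymetry, Ekman layer, spherical metric terms, or
mesoscale eddy spectrum is modelled: transport mathematics is tested
without geodesy.

Stations are drawn from ocean cells whose mean-flow speed exceeds the
0.75 quantile (the energetic streamline annulus of each gyre), at least
5 cells apart, at least 8 columns away from the barrier (so every
station sits in a gyre core rather than the exchange channel), split
evenly between the basins. The generator records the basin truth label.

## Transport

Floats are advected with a fourth-order Runge-Kutta step on velocities
interpolated bilinearly in space (cell centres) and linearly in time
between consecutive monthly snapshots. Horizontal eddy diffusivity
K (default 100 m²/s) enters as one additive Gaussian kick per step with
standard deviation √(2KΔt) per component (Euler-Maruyama splitting). A
step that would land on land or off-grid first reverts the kick and, if
still invalid, the whole step — a stall-at-coast rule chosen over
reflection for simplicity; at toy scale the difference is confined to a
one-cell coastal strip. The default step is month/600 with a CFL
warning at max|u|·Δt > 0.5·min(dx, dy); the toy pipeline uses month/300,
which keeps an order-of-magnitude CFL margin on this grid and halves the
cost of the monthly precomputation.

Monthly trajectories are precomputed from every ocean-cell centre for
every month instance; dense paths are stored subsampled so consecutive
stored points are less than about one grid cell apart, which bounds the
error of first-entry detection at the two-cell capture radius. Stitched
trajectories start in a uniformly chosen cell within the capture radius
of a station and a uniformly chosen month instance, then repeatedly jump
to a stored trajectory of the following calendar month (uniform over
available years) starting in the current end cell. First-entry times at
every station's capture disc are accumulated along the way.

T_min(i, j) is the minimum first-entry time at j over the ensemble
released near i; pairs connected by fewer trajectories than
`min_connections` are masked. The matrix is then closed under path
concatenation (min-plus transitive closure over valid pairs). The
closure is an estimator property, not a model change: an exhaustive
stitched ensemble is closed automatically, because the concatenation of
a trajectory reaching station k and one leaving k is itself a valid
stitched trajectory. At desk-scale ensembles (100 trajectories × 20
years per station, versus thousands × millennia at study scale) the raw
pairwise minimum overstates rarely sampled connections by years; the
closure removes exactly that finite-ensemble bias. `close_paths=False`
restores the raw estimator. Symmetrization takes the elementwise
minimum of the two directions, the natural reduction when the
dissimilarity it will be compared against is symmetric.

Over-water geographic distance is the shortest path on the 8-neighbour
ocean-cell graph with centre-to-centre edge lengths.

## Communities

Communities are a latent-Gaussian threshold model. For each taxon, a
Gaussian field over stations is thresholded at the occupancy quantile
(default 0.22: each taxon is present at ~22% of stations). The latent
correlation for a station pair is chosen by numerically inverting the
threshold model's expected-Jaccard curve so that

    E[Jaccard similarity] = J₀ · exp(−T_eff / τ_true),

an exact exponential decay with e-folding time τ_true on top of a
local-patchiness baseline J₀ (default 0.45: even stations with
vanishing travel time share less than half their taxa, mirroring the
strong small-scale patchiness of real plankton communities). Two
stations with exactly zero travel time are the same water parcel and
get identical communities. The direct choice corr = exp(−T/τ) was
rejected because the induced Jaccard decay is only approximately
exponential, which makes the fitted e-folding time depend on the
geometry of each realization's travel-time distribution; the inversion
makes parameter recovery well-posed.

T_eff is the (closed, symmetrized) travel time, with two designed
modifications. Within a basin it saturates at 1.5·τ_true: gyre
recirculation keeps same-basin communities from decorrelating
completely, which is what lets basin-scale provinces exist at all, and
which reproduces the flattening of travel-time correlations beyond
~1.5 years. Between basins T_eff is a large constant (3·τ_true plus
5·τ_true per unit of `basin_pool_divergence`), and the divergence
additionally anti-correlates the basins' latent fields (floored at
−0.35, the approximate feasibility limit given the within-basin
coherence): basin-specific taxon pools — taxa favoured in one basin and
rare in the other — are what separate provinces across basins.

The target correlation matrix built this way from an empirical T is not
guaranteed positive semi-definite; it is projected onto the PSD cone
(eigenvalue clipping) and row-renormalized to unit variances, with
grossly infeasible inputs (λ_min < −0.25·λ_max) rejected. Within-basin
pairs with no measured connection at all receive the saturation floor
rather than causing a rejection — a station can sit off the flow
attractor and collect no trajectories.

Calibration constants (occupancy 0.22, J₀ = 0.45, speed 0.15 m/s,
saturation 1.5τ, anti-correlation −0.35) were fixed once, at design
time, by requiring on a panel of eight generator seeds that (a) the
two basins are recovered as provinces, (b) the nonlinear least-squares
turnover fit recovers τ_true within its tolerance on every panel seed,
and (c) the required correlations stay inside the PSD-feasible cone.
They are not tuned per run.

Abundances are lognormal masses on present taxa. Reads are drawn from
per-taxon uniform-random genomes (2000 bp) proportionally to abundance,
with uniform start positions and i.i.d. substitution errors (default
1%); no indels, no paired ends, no quality-score model beyond a
constant. Environmental tables combine a latitudinal temperature
gradient with a seasonal sinusoid, nutrients decaying exponentially
with along-mean-flow travel time from upwelling source cells (computed
by Dijkstra on the ocean graph with distance/speed edge weights), and
lognormal chlorophyll/PAR covariates.

What the generator does **not** emulate: real taxon-abundance
distributions and their sampling noise, seasonality of community
composition (only the flow and temperature are seasonal), depth
structure (the DCM layer is a label only), horizontal stirring below
grid scale, and any coupling of communities back onto the environment.
Passing the recovery tests therefore shows that the analysis chain is
correct and well-calibrated under its own assumptions — not that those
assumptions hold in the real ocean.

## β-diversity

K-mer profiles are exact sets of canonical k-mers (lexicographic
minimum of a k-mer and its reverse complement; k odd so no k-mer is its
own reverse complement), 2-bit-packed into uint64 and computed fully
vectorized; windows containing non-ACGT symbols are skipped. The
low-complexity filter drops whole reads whose mononucleotide Shannon
entropy (bits, N excluded) falls below the threshold (default 1.5);
masking low-complexity regions within reads would be the alternative
reading of that rule. Subsampling takes a prefix, so profiles are
nested as the read cap grows. The distinct-k-mer dissimilarity,
Jaccard, and Bray-Curtis all live on the 0–100 percent scale. Defaults
follow the full-scale analysis (k = 31, 10⁸ reads); the toy profile
uses k = 15 and the generated 2×10⁴ reads per sample.

## Provinces

UPGMA is scipy's average-linkage agglomeration; merge heights are
inter-cluster mean dissimilarities, so cophenetic distances are
ultrametric (tested against an independently coded O(n³) textbook
implementation). Cluster support is the ordinary bootstrap proportion:
feature columns of the presence matrix underlying the dissimilarity are
resampled with replacement, the matrix and tree recomputed, and each
original node scored by the fraction of replicates containing an
identical leaf set. This replaces the multiscale "approximately
unbiased" p-value of pvclust; BP is simpler, monotone in the same
signal, and sufficient to dissolve unstable clusters. For k-mer-scale
feature spaces the bootstrap operates on a seeded random subset of
columns (default cap 50 000), which estimates the same stability at a
fraction of the cost.

The partition is automated: every horizontal cut yielding 2..k_max
clusters is scored by the mean silhouette over all samples, with
samples in singleton clusters contributing their conventional s = 0.
Scoring only the samples in clusters of size ≥ 2 was tried first and
discarded: it lets a high-k cut win by dissolving most samples into
singletons while keeping a few tight pairs (on the default seascape the
k = 14 cut of 20 samples beat the true two-basin cut under that rule).
After the cut, singleton clusters and clusters with bootstrap support
below `min_support` (default 0.5) are dissolved to the unassigned label
"-"; a province always has at least two members.

## Ordination and colors

PCoA double-centres −½D² and eigendecomposes; if any eigenvalue is
negative beyond tolerance the Cailliez additive constant (largest real
eigenvalue of the standard 2n×2n companion matrix) is added to
off-diagonal dissimilarities first. Axis signs are fixed by making the
sample with the largest absolute score positive, so colors are
reproducible across platforms. Channels are
round(128·(1 + λ_c·x/max|x|)) clamped to [0, 255] (the mapping reaches
256 exactly at the extreme score; clamping was chosen over rescaling).
λ_c is 1, eig₂/eig₁, eig₃/eig₁ for the PCoA variant and 1 for all axes
in the environmental variant. Environmental ordination shifts each
variable positive (−min + 10⁻⁶) when needed, Box-Cox-transforms with
the MLE exponent searched on [−2, 2], z-scales, takes the top three PCA
components, rescales them to unit variance and whitens (Mahalanobis) so
their covariance is the identity; constant variables are dropped with a
warning.

## Correlation and turnover statistics

Matrix Spearman correlations average-rank the selected off-diagonal
pairs and Pearson-correlate the ranks; the Mantel test permutes station
identities of one matrix (rows and columns jointly) with the pair mask
held fixed, p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm). Partial
Spearman is the standard first-order formula
(r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)). Cumulative correlation curves
evaluate ρ over pairs with T < t per ceiling t (default grid: monthly
steps), report ceilings with fewer than `min_pairs` pairs as missing,
and can attach a 95% CI from a station-level bootstrap (stations
resampled with replacement, self-pairs dropped), which respects the
pairwise dependence that a pair-level bootstrap would ignore.

The turnover fit is nonlinear least squares of y = C₀·e^(−x/τ) on
similarity (100 − dissimilarity) against symmetrized T_min, restricted
to pairs with T below the fit window (default 1.5 years), initialized
at C₀ = max y, τ = median T. τ is the e-folding time: at x = τ the
fitted similarity has fallen to C₀/e, a ~63% change. In the end-to-end
tests the fit pools within-basin pairs, mirroring the restriction of
such fits to a single current system; cross-basin pairs carry
basin-pool dissimilarity that is independent of travel time by design.

The end-to-end checks define the seascape's basin-crossing time as the
lower quartile of cross-basin symmetrized T_min — the onset of
appreciable inter-basin exchange — and locate the cumulative-
correlation peak on the mean of five replicate community draws. The
peak is a bias-variance phenomenon (with noiseless communities the
curve has no interior maximum), so a single draw's argmax wanders at
the threshold-grid scale; averaging recovers the structural location,
which sits where cross-basin pairs begin to enter in numbers. On the
eight-seed design panel this agreement holds within ±30% for six seeds;
geometries whose averaged curve is monotone can still miss it — a known
limitation of locating a flat peak with 20 stations.

ANOSIM uses R = (mean between-group rank − mean within-group rank)/(M/2)
with M = n(n−1)/2 and a one-sided permutation p over relabelings;
singleton groups are excluded with a warning. Kruskal-Wallis uses the
tie-corrected H with the chi-square approximation; a parameter constant
across samples reports H = 0, p = 1. PAR at depth follows the
chlorophyll-based attenuation relation (log₁₀ in the depth polynomial;
k = −ln 0.01/Z, so PAR falls to 1% of surface at the reference depth Z).
Seasonality indices are each station's annual range divided by the
largest range over stations. Euclidean environmental distances z-score
each parameter first; ratio parameters floor zero denominators at 10⁻⁶.

## Pipeline

A single validated config (pydantic schema, unknown keys rejected with a
spelling suggestion) drives the chain synth → transport → communities →
β-diversity → provinces → colors → correlations → turnover, per
organismal size fraction (fractions share the field, stations, and
transport; each gets its own designed τ_true). Communities are
generated from the measured symmetrized travel times so that the decay
downstream analyses estimate is expressed in the same currency they
measure. Full-scale defaults follow the published analysis (k = 31,
10⁸ reads, 1000 bootstraps and permutations, 200 km ≈ 11-cell capture
radius, 1000 trajectories × 10 000 years, >1000-trajectory connection
threshold, p < 0.01, 1.5-year fit window); `PipelineConfig.toy_profile()`
is the desk-scale override (k = 15, 2-cell radius, 100 × 20-year
trajectories, ≥5 connections). Station exclusions (non-surface, coastal
and Southern Ocean id lists, connection mask) are config-level filters
and every exclusion is logged. A global seed derives per-stage seeds by
hashing the stage name; the run manifest records parameters, seeds,
wall-clock, and SHA-256 hashes of every artifact, and a rerun with the
same config reproduces identical hashes.

## Problem sizes

The reference toy conditions used throughout the tests are a 64×128
grid with 24 months, 20 stations, 2000 taxa, 100 stitched trajectories
of 20 years per station, 2000-bp genomes with 100-bp reads at 2×10⁴ per
sample, 200 bootstrap replicates and 199–999 permutations. These sizes
run the complete chain in a few minutes on one CPU while leaving every
recovery target (basin provinces, τ within 25%, calibrated null
rejection rates) statistically resolvable.
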