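# Methods

## Eco-evolutionary chemostat model

The ecological layer is a MacArthur/Tilman consumer–resource model for a
well-mixed chemostat with two substitutable sugars (resource 1 =
fructose, resource 2 = galactose), dilution rate D (h⁻¹) and supply
concentrations S₁, S₂ (g/L):

    dR_j/dt = D (S_j − R_j) − Σ_i N_i u_ij φ_j(R_j)
    dN_i/dt = N_i (ε Σ_j u_ij φ_j(R_j) − D)

φ_j is either Monod, φ_j(R) = v_j R/(K_j + R), or linear, φ_j(R) = a_j R
(selectable; Monod is the default).  N_i are biomass densities in
OD-equivalent units, u_ij ∈ [0, 1] utilization allocations, and ε a
single shared yield (biomass per g/L of sugar consumed).  Whether yield
differences between the sugars (2 vs 3 ATP per molecule in the organism
that motivated the model) belong inside the trade-off is unresolved; we
keep a single ε and fold all asymmetry into the supply and, optionally,
per-resource v_j.

Phenotypes live on the trade-off boundary u₂ = u_max(1 − (u₁/u_max)^p)^{1/p}:
interior points are strictly dominated, so the evolving trait is the
scalar u₁.  p sweeps both regimes — p < 1 strong (inward-bulging),
p = 1 linear, p > 1 weak (outward-bulging).

### Default parameters and why

| parameter | default | units | rationale |
|---|---|---|---|
| v₁ = v₂ | 6.0 | g sugar · (OD·h)⁻¹ | with ε = 0.4 gives ancestral-scale growth rates ~1 h⁻¹ at supply, comfortably above the preset dilution rates |
| K₁ = K₂ | 0.5 | g/L | half-saturation well below supply: equilibria operate on the sensitive part of the uptake curve |
| ε | 0.4 | OD per g/L | sets equilibrium biomass ≈ ε·S (0.75–4 OD across treatments) and, critically, the strength of the resource feedback (below) |
| D presets | 0.3 / 0.2 / 0.3 | h⁻¹ | fructose / galactose / mix initial dilution rates of the experimental protocol |
| supply presets | (5,0) / (0,10) / (2.5,5) | g/L | 0.5% w/v fructose, 1% w/v galactose, and the half-strength mix |

The feedback point deserves emphasis.  For linear uptake one can show
that the interior singular strategy u₁* is convergence-stable iff the
consumption pressure n = N*a/D satisfies 2n/(1 + n·u₁*) > g''(u₁*),
where g is the trade-off boundary.  Low-yield parameterizations make
every strong-trade-off singular point an evolutionary *repeller*: the
population runs to one specialist corner and the second specialist can
never establish through small mutational steps.  The defaults above put
the model in the empirically relevant regime where p ≈ 0.4–0.7 yields a
convergence-stable *branching point* (both under symmetric supply and
under the mix preset for p ≳ 0.5) and p ≥ 1 a convergent ESS.  Under the
mix preset at p = 0.4 the interior attractor disappears entirely
(mid-curve phenotypes are partly unviable at D = 0.3) and evolution runs
to a boundary specialist; the bifurcation-consistency checks therefore
use symmetric supply where the attractor structure is clean across the
whole p grid.

### Equilibrium, invasion analysis, numerics

`ecological_equilibrium` integrates the ODEs (LSODA, rtol 1e-8,
atol 1e-12) in 500-h chunks until scaled derivatives fall below 1e-9
(cap 6000 h), prunes densities below the 1e-8 extinction threshold and
polishes the surviving subset with a Newton solve, so that every
survivor's per-capita growth equals D to ~1e-12.  Washout (no type
viable) returns N* = 0, R* = S with a flag.

Invasion fitness of a rare mutant is its per-capita growth at the
resident equilibrium, s = ε Σ_j u_j^mut φ_j(R_j*) − D.  The selection
gradient is a central finite difference in the mutant trait (h = 1e-5);
singular strategies are bracketed on a 41-point grid and refined by
Brent's method.  Grid points where the monomorphic resident itself
washes out (possible mid-curve under strong trade-offs) are excluded
from bracketing.  Classification uses the numeric second derivative of
s in the mutant direction (h = 1e-4): positive → branching point,
otherwise ESS; singular points within h of the trait boundary are
boundary specialists.  For p = 1 the curvature is exactly zero and the
label degenerates to ESS by convention.

`evolve` is an oligomorphic adaptive-dynamics loop: relax to
equilibrium, draw a parent proportional to density, add a mutant with
u₁ perturbed by a truncated Normal(0, mutation_sd = 0.05), at seed
density 1e-4, prune and merge traits closer than 1e-3.  One RNG seeded
per run controls parent choice and mutation draws; everything else is
deterministic.  Epoch bookkeeping assigns 500 h of ecological time per
mutation epoch, so generation counts follow D·t/ln 2 exactly.

`run_treatment` runs the chemostat in real time (24-h integrations).
Once per day the controller multiplies D by 1.15 if total OD (biomass ×
od_per_density, default 0.3) exceeds 1.0 and divides by 1.15 below 0.5,
clipped to [0.01, 1.5] h⁻¹ — "adjusted daily" with an unspecified step
size in the protocol; multiplicative steps guarantee positivity.  Because
chemostat biomass is nearly growth-rate-independent (N* ≈ ε(S − R*)),
the band acts mostly one-sidedly per treatment: a treatment below the
band rides D down, one above rides it up to the cap.  Mutants (default
one per day, relative density ~5e-4) supply standing variation; a
population that washes out is re-seeded at trace density for up to three
days before the run is flagged.  Simulated day counts (250–400) are
chosen for the mutation-limited dynamics of the model and are not
calibrated to the wet experiment's 38–58 days; the model compresses the
population's enormous real mutation supply into a few lineages per day.

## Growth-rate estimation

OD600 curves are background-corrected (configured scalar blank, default
the minimum of the first three readings; non-positive values masked),
restricted to points with corrected OD > 0.16, and every run of five
points consecutive in the sampling grid gets an OLS fit of ln(OD)
against time; mu_max is the largest slope, converted minutes → hours.
Windows spanning gaps in the retained sequence are skipped; ties go to
the earliest window.  Fewer than five consecutive eligible points yields
an `insufficient_points` status rather than a number.  Replicates are
averaged arithmetically over estimates with `ok` status.

The window protocol is exact on exponentials but inherits a downward
bias of roughly mu·(OD_window/K) when the curve saturates at plateau K
near the threshold: at K = 1.2 the bias reaches ~0.15 h⁻¹ for
mu = 0.82 h⁻¹.  Recovery tests therefore use deep-exponential synthetic
curves (K = 6, inoculum 0.005, cuvette-equivalent OD units) where the
measured median error is ~0.01–0.02 h⁻¹; users applying the protocol to
shallow plate-reader curves should expect the documented bias, which
affects absolute but not comparative rate estimates.

## Phenotype clustering

Points are (G_max, F_max) pairs in h⁻¹.  The mixture family is EVV:
equal component volumes (equal covariance determinants), varying shapes
and orientations.  The constrained M-step has a closed form — with W_k
the responsibility-weighted scatter of component k,

    Σ_k = λ · W_k / det(W_k)^{1/d},   λ = (1/n) Σ_k det(W_k)^{1/d}

— so each EM iteration is a true maximization and the log-likelihood is
provably non-decreasing (asserted on every fit).  Initialization is
k-means++ with 10 seeded restarts, best final likelihood kept;
convergence at Δloglik < 1e-6 (cap 300 iterations); singular scatters
get a 1e-6 diagonal ridge and a flag.  Model selection maximizes
BIC = 2·loglik − m·ln n over k = 1..3, with m = 5k free parameters in
2-D (k−1 weights, 2k means, 1 shared volume, k shapes, k orientations);
fewer than 6 points restricts to k = 1.  Cluster means are labeled by
quadrant against F = 0.703 and G = 0.545 h⁻¹ (the midpoints of the
observed group-average rate intervals), with ≥ on the strategy's own
axis; the low-both quadrant gets its own label rather than being folded
into "generalist".  Lineages across timepoints are linked by greedy
nearest-centroid matching (Euclidean in (g, f)); unmatched clusters open
or close lineages, and cluster frequencies are responsibility-weighted
point shares.

## Variant filtering and CNV calling

Variant records are presence/absence entries (strain, locus, 1-based
position, class ∈ {SNP, indel, CNV_dup, CNV_del}, annotation flag).
Ancestral subtraction removes evolved records matching an ancestral
(position, class) pair — allele detail is deliberately ignored, since
the comparison is per-locus presence/absence.  Candidate loci for
phenotype P require (1) carriers exclusively from P's single-sugar
treatment plus, by default, mix-treatment strains labeled P (a strict
single-treatment mode is a flag: the protocol's wording admits both
readings); (2) full annotation; (3) ≥5 carrier strains with SNP/indels
or ≥5 distinct variants of any class.

CNV calling is a transparent threshold-run segmentation, not a
reimplementation of read-level CNV software: per-bin depth (100-bp bins)
is divided by the genome-wide median, runs of ≥3 bins at ratio ≥1.5
(or ≤0.5) become duplication (deletion) calls, runs separated by a
single discordant bin merge, and the call's copy ratio is the median bin
ratio.  Calls are invariant to global depth scaling.  Coordinates are
1-based inclusive internally; BED-like output converts to 0-based
half-open at the boundary.

## Synthetic data and what it does not emulate

Generators mirror the study design — 3 treatments × 4 replicates ×
3 timepoints, 6 colonies per plate (mix plated on both sugars → the
288-strain library), sequencing subsample of 3 strains × 2 replicates
per treatment-timepoint, one metagenomic sample per replicate-timepoint
(36) — and return machine-readable truth beside every dataset.  Growth
curves are lagged-logistic with multiplicative Gaussian noise on a
10-min grid; phenotype clouds are Gaussian mixtures at FS/GS-like means;
variant tables plant phenotype-exclusive loci among Poisson background
noise and shared ancestral variants; coverage is Poisson depth (mean
300×) scaled by planted fold changes, with presets for the observed 2-,
3- and 6-fold duplication motifs.  The printed figure of 48 sequenced
single strains does not equal the 3×2×3×3 = 54 of the stated
sub-sampling; the generator exposes the counts as parameters and its
default layout yields 54.

Passing tests on these generators demonstrates correctness of the
estimators under their stated noise models, not robustness to what real
data adds: reader drift and well effects, non-Gaussian phenotype
dispersion, linked variants and shared genealogy (carriers are drawn
independently), mappability- and GC-dependent coverage, and repeats,
whose copy-ratio variance grows with copy number.  Estimated copy ratios
of high-fold amplifications are accordingly more trustworthy in the
synthetic setting than they would be on real repetitive sequence.

## Known limitations

- The consumer–resource instantiation is a minimal stand-in for richer
  metabolic detail; only qualitative agreement with the motivating
  experiments (specialist fixation on single sugars, diversification on
  the mix under strong trade-offs) is claimed, and no genotype-level
  mechanism is simulated.
- The OD↔biomass mapping and the controller gains are conventions; the
  experiment's "dilution rises as the culture adapts" feedback needs
  growth-rate-dependent biomass, which the minimal chemostat lacks.
- The EVV family is the only mixture family implemented; no comparison
  across mclust-style families is offered.
- CNV segmentation has no statistical significance model; thresholds are
  user-set and logged.
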