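# Methods

## Model overview

Movement is a biased correlated random walk on a 25 m raster landscape,
discretized into 4 h steps. At each iteration an animal draws `n_candidates`
(21) candidate steps — step length and turning angle resampled independently,
with replacement, from pooled empirical winter distributions — scores each
candidate with a step selection function w(x) = exp(β·x), and selects one
under a configurable rule. It then moves, feeds at the end cell, and updates
three pieces of internal state: a FIFO ledger of the last 18 per-step net
energies (the 72 h balance ΔE), a bounded list of remembered location
clusters, and its heading.

The SSF is estimated by conditional logistic regression on strata of one
observed step plus 20 random steps sharing its start point. The covariates
that depend on internal state cannot be observed, so tracks are *replayed*:
the recorded path is stepped through the same energetics/memory submodels the
simulator uses, and covariates are recorded for observed and random steps
alike, with only the observed step mutating state. Because simulator and
replay engine share one covariate implementation, a simulated track replayed
through the estimator reproduces the simulator's logged covariates exactly —
the round-trip the test suite checks, and the property that makes forward
modelling (fit the trait directly, simulate once) possible.

## Covariates

Per candidate step: cos(θ_mem) (cosine of the minimum angle between the step
bearing and the directions to remembered cluster centroids; 0 with empty
memory), G/L (Michaelis–Menten energy gain at the end cell over expenditure
for the step), canopy Cover (%) and its 3×3 gradient Edge (%/cell, a
Sobel-type operator: [1,2,1]/4 transverse smoothing + central differences,
one-sided at borders), Altitude (m), three disturbance terms
cos(θ_kind)·f(D_kind), and two interactions (G/L)·ΔE and Cover·ΔE. The
interactions express ΔE in MJ rather than kJ — a pure unit choice that keeps
the design matrix O(1)–O(100) and the Newton solver well-conditioned. ΔE is
taken at decision time (before the step's feeding), so it is constant within
a stratum.

Nested candidate models: *memory* {cos θ_mem}; *energetic* {cos θ_mem, G/L,
(G/L)·ΔE}; *environment* (all ten terms).

## Parameters and provenance

All constants live in `ssfwalk/data/defaults.yaml` with a provenance tag per
value. Established values: intake asymptote a = 61.3 g/day/kg, half-saturation
b = 40 g/m², energy content 7.79 kJ/g, 1600 m in-patch radius, disturbance
zero-crossings 1500/1600/1300 m, 20 random steps per stratum, 21 candidates,
winter window Dec 28–Apr 15 (108 days × 6 steps/day = 648 iterations,
computed from the dates, not stored). Placeholders that must be transcribed
from primary sources for real use (tagged `PAPER-APPENDIX`): the locomotion
coefficients (defaults: 1540 kJ basal per 4 h step, 0.26 kJ/m travelled,
2.5 kJ/m climbed, for a 100 kg animal — allometric/locomotion-literature
orders of magnitude) and the per-class lichen biomass table (synthetic values
spanning 0–60 g/m² with lichen-rich open conifer richest). Documented
decisions: body mass 100 kg; daily intake scaled by 4/24 per step; descent
costs nothing (max(0, Δalt)); memory capacity K = 15 clusters; a new cluster
forms when 2 consecutive off-patch locations fall within 1600 m of each
other; centroids update as running means over all member locations.

## Estimation and inference

The conditional log-likelihood is maximized by Newton–Raphson with
step-halving (|Δℓ| < 1e-8, ≤ 100 iterations); diverging coefficient norms are
reported as monotone likelihood (separation) rather than returned. Naive
covariance is the inverse observed information A⁻¹. Because consecutive
strata of one animal are autocorrelated, inference uses the cluster-robust
sandwich A⁻¹BA⁻¹ with B the sum of clustered score outer products; clusters
are contiguous blocks of 24 strata per individual (4 days; the block length
is a package choice — only the separation rule is established), with the 2
strata after each block dropped so blocks are ≥ 8 h apart, and blocks of
different individuals merged when simultaneous strata start < 100 m apart.
Model selection uses QIC = −2ℓ + 2·tr(A·V_robust), which reduces to AIC under
independence. Coefficients are reported unscaled; covariate standardization
is off by default.

Cross-validation implements the case-control rank-bin design: each of 100
repetitions refits on a random 80% of strata, ranks each withheld observed
step among its 21 rows (midranks on ties, rounded to a bin), tallies ranks
into 21 bins, and correlates bin index with frequency (Spearman). The "5-fold"
is realized as repeated random 80/20 splits, the protocol's literal
description. Note the tie-handled ceiling: a perfect scorer concentrates all
mass in bin 21, and the Spearman of (1..21) against (0,…,0,N) with midranks
is ≈ 0.369, not 1 — real data spread mass across bins, which is why strong
models report r_s near 0.9.

## Simulation and selection rules

Agents act in series in id order, so forage depletion is order-dependent but
fully determined by the seed. Rules: *best* (argmax; ties broken by a seeded
shuffle), *best90* (argmax with probability 0.9, else uniform over all 21),
*roulette* (probability ∝ w/(1+w), the logistic of the score, normalized over
the candidate set — normalization is a package choice; an
acceptance-probability reading was the alternative), *crw* (uniform null),
plus *proportional* (probability ∝ w), an addition beyond the four standard
rules: it is the exact generative counterpart of the conditional-logit
likelihood and is what the parameter-recovery and coupling tests simulate
from. Candidates whose end point leaves the grid are redrawn (≤ 100
attempts); optional confinement polygons redraw candidates until inside
(cap 1000, then the shortest candidate is kept). Initial heading is uniform,
the ledger starts empty (ΔE over fewer than 18 steps is the partial sum), and
memory starts empty.

## Synthetic data

The landscape generator produces spatially autocorrelated class patches
(Voronoi cells of seeded points, ~200 cells mean patch size), linear roads,
square cutblocks with ages, and a smoothed-noise DEM (300–700 m). The step
pool is log-normal lengths (median 250 m, σ = 0.8) with wrapped-normal
turning angles (σ = 1.3 rad) — the shapes routinely reported for 4 h
large-herbivore fixes. Synthetic studies simulate tracks from a fixed
reference coefficient vector (`TRUE_BETA`) under proportional selection.
What this emulates: patchy forage, disturbance gradients, memory-driven
revisitation, depletion feedback. What it does not: GPS error, irregular fix
intervals, inter-individual interaction, seasonal vegetation dynamics, snow
— so passing tests demonstrate the estimator/simulator machinery is correct
and internally consistent, not that the fitted coefficients describe any
real herd.

Test and example problem sizes (120–150 cell grids, 3–5 individuals, 100–150
steps, 50-replicate batches) are the package's chosen defaults for its
self-checks; all scale linearly if enlarged.

## Numerical choices and degenerate inputs

Linear predictors are clipped at ±500 before exponentiation (the logistic
saturates there). Absent feature kinds give D = +∞ and a zero disturbance
term, consistent with f → 0. A centroid coincident with a step's start has
no defined direction and is skipped in cos(θ_mem). Feeding is capped by the
cell's remaining lichen mass, so grid mass removed always equals grams
ingested. A 1×1 grid has zero edge everywhere. 95% MCPs drop
floor(0.05·n) points farthest from the centroid; collinear/duplicate sets
are flagged degenerate with zero area. RSFs flag separated classes
(|β| > 15 or SE > 50) as non-finite and exclude them from correlations;
β-vector correlations require ≥ 3 shared finite coefficients.

## Known limitations

Mixed-effects RSF estimation (random effects for individual and year) is out
of scope; per-individual fixed-effects logistic RSFs with rank tests stand in
for the cross-method significance machinery. Raster I/O is ESRI ASCII grid
only. Replay treats individuals independently, so in multi-animal
simulations the depletion other animals cause is not visible to the
estimator — a small bias at realistic densities, zero in single-animal
round-trips. SL and TA are resampled independently (their empirical joint
dependence is ignored), and random steps use end-cell covariates only (no
path integration along the step).
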