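# Methods

This note records the models behind `ovitrace`, the parameter conventions
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where more than one defensible
option existed.

## Input model and site handling

The unit of analysis is a multiple alignment of mtDNA control-region
sequences (all rows equal length; the conventional segment is 628 aligned
positions) with per-sequence metadata (breed, region, optional
haplogroup). Two missing-data policies are offered: *complete deletion*
(drop any column containing a gap or `N`; the default for diversity and
neutrality statistics, matching common control-region practice) and
*partial deletion* (keep columns with ≥95% real bases by default, the
convention used when building trees). The two policies can give different
retained-site counts, so π and k are always reported together with the
site count they were computed on.

## Diversity and neutrality statistics

Site classes follow the desktop-software convention: S counts polymorphic
columns; Sg counts strictly biallelic columns whose minor allele occurs in
one sequence; P counts columns with at least two alleles each carried by
two or more sequences. A triallelic column with allele counts (1, 1, n−2)
is therefore segregating but neither Sg nor P, which keeps Sg + P ≤ S.

H<sub>d</sub> is Nei's unbiased haplotype diversity; π is mean pairwise
difference per retained site; k its per-pair count. Tajima's D uses the
standard a₁…e₂ constants. Fu & Li's D\* and F\* (the outgroup-free
variants) are computed from total mutations η = Σ(alleles − 1) per column
and singleton mutations η<sub>s</sub>, with the corrected starred variance
constants in general use since Simonsen et al. (1995); the n = 4
single-singleton configuration gives D\* = −0.612372 and F\* = −0.234001
by exact hand evaluation, reproduced to 1e-6 by the implementation. Fu's
F<sub>s</sub> = ln(S′/(1−S′)) with S′ = P(K ≥ K_obs | θ = k) under the
Ewens sampling distribution; P(K = j) is evaluated by the sequential
(Chinese-restaurant) Poisson-binomial recursion, which is numerically
stable at any n, and is checked in the tests against the Stirling-number
form. Boundary conventions: all four tests are undefined (NaN, flagged)
when S = 0; F<sub>s</sub> is +∞ at the K_obs = 1 boundary.

Significance, when requested, comes from a seeded coalescent-simulated
null (θ matched to the observed k) rather than transcribed critical-value
tables: one mechanism serves all four tests and the simulated-null route
is validated directly by the type-I-error checks below. Fu's
F<sub>s</sub> follows the conventional stricter threshold (p < 0.02,
implemented as the two-sided 4% envelope).

Between-population divergence: D<sub>xy</sub> is the mean per-site
difference over all cross-population pairs; D<sub>a</sub> subtracts the
mean within-population diversity computed in the frequency-weighted (Nei)
convention — over all ordered pairs including self-pairs — so that
identical samples give exactly D<sub>a</sub> = 0.

## Haplogroup assignment, AMOVA, composition

Haplogroups are assigned by nearest reference (Hamming distance on the
usable sites) against the five lineage references A–E; exact ties are
flagged ambiguous rather than broken arbitrarily. AMOVA follows the
Excoffier–Smouse–Quattro decomposition on pairwise nucleotide-difference
counts (treated as squared distances, the mtDNA convention; no model
correction), with Φ_CT/Φ_SC/Φ_ST and permutation p-values (default 1,000
permutations, seeded; individuals among breeds for Φ_ST, individuals
within groups for Φ_SC, whole breeds among groups for Φ_CT). Breeds of
size 1 are excluded with a warning. Reported composition percentages are
rounded half away from zero, which is what reproduces counts such as
119/193 → 62% exactly.

## Median-joining networks

The network starts from the minimum spanning network (union of all MSTs,
built per distance class) over observed haplotypes and repeatedly adds
majority-consensus median vectors of triplets that share at least two MSN
links, keeping per round every candidate within ε of the best connection
cost (ε = 0 default). Closure is followed by MP-style pruning: median
vectors not on any shortest network connection between observed
haplotypes are removed, and remaining medians of degree ≤ 2 are spliced
out (they add no branching information). Tie-breaks are lexicographic on
sequence throughout, and haplotypes are canonically ordered before
construction, so the ε = 0 network is deterministic. Note that the MSN,
being the union of all MSTs, can have *total* edge weight above a single
MST when distance ties are common; the parsimony property that holds (and
is tested) is that a spanning tree routed through the median vectors is
never longer than the observed-only MST.

Star contraction is the greedy hub-first simplification: the haplotype
with the most neighbours within the radius (ties: higher multiplicity,
then lexicographic) absorbs them, provided it centres at least two rays;
repeat until no star remains. Network groups are the connected components
after cutting edges longer than a user-chosen cutoff; the cutoff is a
free parameter by design — the sensible value sits between the
within-cluster and between-cluster distance scales (12 steps for the
synthetic two-wave design, whose scales are ~9.5 and ~30).

## Terminal-branch (level-1) tree affinity

For a leaf x, the level-1 neighbours are the other leaves of the smallest
clade containing x with ≥ 2 leaves — the sister leaf of a cherry, all
co-members of a terminal polytomy, and, under a ladder, the relation is
asymmetric (a deep leaf can have a shallow leaf as neighbour but not vice
versa). The affinity count matrix sums, over the focal breed's leaves,
the breed memberships of their neighbours; rows are normalised to
percentages (one decimal reported), and self-breed connections are
counted by default (they are informative) with an option to exclude them.
The rule is isolated in one function (`level1_neighbors`) so alternative
readings (e.g. sister-clade-only) can be swapped without touching the
bookkeeping. Region aggregation sums partner-breed columns into regions
before normalising; on raw counts, aggregation and normalisation commute.

Concordance between two connection matrices (e.g. tree-derived vs
network-derived percentages) is the Pearson correlation over the paired
cells with the two-sided t-transform p-value; it is computed on
percentages, not raw counts.

A caveat established with the simulator: on star-like genealogies
(post-expansion data) reconstructed by neighbour joining, trees become
caterpillar-shaped and level-1 neighbour sets of deep leaves balloon, so
the affinity share is then a noisy, biased estimate of founder fractions.
Under hierarchical (constant-size coalescent) within-population
genealogies with balanced clade sizes, the share tracks planted founder
fractions to within a few percentage points (the regime the recovery
tests exercise).

The neighbour-joining builder included as plumbing delegates the
agglomeration to scikit-bio and canonicalises taxon order, making its
topology deterministic.

## Mismatch distributions and expansion dating

The sudden-expansion expectation is Rogers & Harpending's
F_i(τ, θ₀, θ₁) = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} (τ^j/j!)
[F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)], with equilibrium
F̂_i(θ) = θ^i/(1+θ)^{i+1}. In the θ₀ → 0, θ₁ → ∞ limit this is
Poisson(τ), so τ̂ approaches the mismatch mean — used as an analytic
check. Fitting minimises the SSD between observed relative frequencies
and the expectation over bins 0..max: a coarse grid over (θ₀, τ) with θ₁
profiled at the conventional cap 99,999, then Nelder-Mead refinement of
all three parameters under 0 ≤ θ₀ ≤ θ₁ ≤ cap, τ ≥ 0; if refinement does
not improve on the grid the grid optimum is kept and the fit flagged.
The SSD goodness-of-fit p-value is a parametric bootstrap: simulate
coalescent samples under the fitted expansion, refit each with the same
optimiser, report the fraction with SSD ≥ observed (default 1,000
replicates, seeded; ≥ 100 enforced).

Per-branch mutation counts for rate calibration use unit-cost small
parsimony (Sankoff) per column. When several equally parsimonious
reconstructions exist, mutations are attributed fractionally — the
expected count per branch under a uniform distribution over all optimal
assignments, computed by an up-down counting pass — so branch totals
always sum to the parsimony score; a deterministic first-found mode is
available. Gaps and `N` are treated as missing (any state).

Dating method 1: τ = 2μt with μ the segment-wide per-year rate, estimated
as the mean over tips below an age-calibrated node of (root-to-tip
mutation count)/age. The calibration ages in the intended application are
the 1.26 Myr and 1.72 Myr ancestor nodes; because the literature reports
dates in years with yearly rates, t is returned in years with an optional
generation-time factor (default 1). Dating method 2: a least-squares line
through (τ, years B.P.) anchor pairs — exact with the two archaeological
anchors — evaluated at query τ values; τ credible intervals are
propagated through the line endpoint-wise (reordered if the slope is
negative). How the original interval propagation was done is not
documented anywhere; endpoint mapping is the minimal monotone choice.

## Climate module

Q₃ = 3.43R/(M−m) (undefined at M = m). Per-breed climate summaries are
arithmetic means over localities, with Q₃ computed from the mean R, M, m.
Before correlation, the stated transforms are applied: √ for altitude,
log₁₀ for T<sub>max</sub>, M and π (log base 10 assumed — the base is not
documented in the source convention); test statistics and the Shannon
index pass through untransformed. Correlations are Pearson on the
transformed columns with two-sided p-values; alongside the raw α = 0.05
flags a Benjamini–Hochberg flag is reported because the analysis runs
many pairs.

## Synthetic data

`simulate_coalescent` wraps msprime (Kingman coalescent, haploid, no
recombination) with a finite-sites Jukes–Cantor mutation model over the
628-position locus. Parameterisation is purely in (θ, τ): internally an
arbitrary per-locus rate U is fixed and Ne = θ/(2U), with a sudden size
change placed τ/(2U) generations back, so E[k] = θ at equilibrium and the
post-expansion mismatch mean ≈ τ. Genealogies export to Newick with
branch lengths in expected-mutation units.

`simulate_scenario` builds multi-breed surveys: founder pools diverge
from a shared root by a fixed number of private substitutions (default
15, disjoint positions per pool, giving ≥ 30 steps between pools), each
pool's internal variation is a coalescent sample under its own
demography, and each breed draws individuals from pools according to its
admixture fractions. Truth tables (per-individual source, founder
sequences, planted fractions) are returned for recovery tests. The
study-like default is six focal breeds of 29–37 animals plus foreign
pools, with focal admixture 79/21 between a western and an eastern
lineage and pool expansion ages τ = 5.1 and 6.6 — the design of the
survey this package is modelled on.

What the generator does *not* emulate: transition/transversion bias and
rate heterogeneity across sites, within-breed geographic substructure,
sequencing error, and alignment gaps. Passing recovery tests therefore
demonstrate correctness of the inference chain under its own model
assumptions, not robustness to those real-data features.

## Problem sizes and determinism

Simulation-based checks use: 500 test + 1,500 null replicates (n = 30,
θ = 5) for neutrality-test calibration; 100 replicates (n = 50, τ = 5)
for expansion recovery; 50 replicate trees (~98 sequences) for
planted-admixture recovery; 500 replicates for the E[k] and E[S]
expectations — sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances. Every random stage takes an explicit seed (msprime
seeds derived via `numpy.random.SeedSequence`), and reruns with the same
seed are bit-identical.

## Known limitations

- The expansion fit treats mismatch bins as independent (the SSD
  criterion); standard practice, but the bins are correlated, which the
  parametric bootstrap accounts for only under the fitted model.
- AMOVA assumes difference counts are squared-Euclidean-compatible; with
  mtDNA difference counts this is the convention, not a theorem.
- Level-1 affinity shares are topology-noisy on expansion-shaped trees
  (see above); interpret them on hierarchical trees or as
  replicate-averaged quantities.
- The haplogroup classifier is nearest-reference only; it does not model
  within-haplogroup paraphyly.
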