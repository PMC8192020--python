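# Methods

`admixcoal` tests whether a mitochondrial haplotype shared between two
reproductively isolated species is better explained by introgression
(gene flow after divergence) or by incomplete lineage sorting (retained
ancestral polymorphism), using genome-wide SNP data.  The package was
built around a two-species ricefish system — a large-lake endemic
(population 1, the recipient) and a small-fountain endemic (population 2,
the donor) — but every component is generic.

## Demographic model family

All models are backward-in-time coalescent models over unlinked short
loci.  Time is measured in generations before sampling; sizes are diploid
individuals; growth between epoch boundaries is exponential, never
linear.

Two-population core (ALD, "allopatric divergence"): each population is
constant at its current size (NPOP1, NPOP2) back to a change-onset time
(TCHG1, TCHG2), then changes exponentially to its size at the divergence
time (NDIV11, NDIV12), and the two lineages join into an ancestor of
constant size NANC1 at TDIV1.  Within a change epoch,

    N(t) = Nstart * (Nend / Nstart) ** ((t - t0) / (t1 - t0)).

Variants:

* **DGF** — ALD plus continuous migration between 0 and TDIV1. MIG12 and
  MIG21 are backward per-lineage migration probabilities per generation.
* **ADM1** — ALD plus one admixture pulse: backward in time, at TAD each
  population-1 lineage relocates to population 2 with probability ADMIX.
  Under ADM1 a fraction ADMIX of the recipient's genome derives from the
  donor at TAD.
* **ADM2** — the pulse source is an unsampled ("ghost") population that
  split from the donor's lineage at TDIV2 (TAD < TDIV2 < TDIV1).  The
  ghost parameterization is a design choice, since only the parameter
  count (15) is externally constrained: the ghost is constant at NPOP3
  back to TCHG3, exponential to NDIV13 at TDIV2, joins the donor lineage
  there; the merged (donor + ghost) lineage is constant at NANC2 on
  (TDIV2, TDIV1]; the donor's exponential change runs from TCHG2 to its
  first divergence, TDIV2.

Free-parameter counts: ALD 8, DGF 10, ADM1 10, ADM2 15.

Five one-population size-change models support per-species screening:
CONST (NPOP), RECENT_GROWTH / RECENT_DECLINE (NPOP, NANC, TCHG; change
reaching the present), PASTGROWTH (NPOP, NANC, TCHG1 < TCHG2; change
confined to the past) and BOTTLENECK (NPOP, NBOT, TCHG1 < TCHG2; a size
excursion inside a window).  Only the past-growth topology is externally
fixed; the rest of the set is a documented reconstruction.

## Coalescent simulator

The simulator (`coalsim`, numba kernels in `_kernel`) is exact in
continuous time.  A model compiles to epoch tables: piecewise-exponential
sizes N0·exp(β(t−t_e)) per population per epoch, per-epoch migration
matrices, and discrete boundary events (pulses, joins).  Within an epoch,
the waiting time to the next coalescence among k lineages inverts the
cumulative hazard of the rate k(k−1)/2 / (2N(t)) through the exponential
size function; when the population grows backward in time the hazard can
saturate, in which case no event occurs before the epoch ends.  Migration
is a competing constant-rate exponential clock.  No generations are
discretised.

Mutations follow the infinite-sites model: each branch receives
Poisson(branch length × μ × locus length) mutations, each a new biallelic
SNP carried by all sampled lineages below the branch.  Loci are unlinked
and internally non-recombining, the standard assumption for ~51-bp RAD
loci.  Haploids are paired at random into diploids, so Hardy–Weinberg
proportions hold by construction.  There is no sequencing-error,
allele-dropout or missing-data model: the emulated data were filtered to
complete genotypes, and passing tests on this generator says nothing
about robustness to genotyping artefacts.

REF/ALT nucleotides are drawn with a configurable transition fraction
(default 887/1552 ≈ 0.57, the transition fraction of the emulated SNP
panel), so the transition/transversion classifier sees realistic input.

Default study conditions (`SimulationConfig`): two populations × 10
diploids, 4,703 loci × 51 bp, μ = 3.5×10⁻⁹ per site per generation.  The
canonical generating parameters (`models.ADM1_STUDY_SCALE`) use the
reported point estimates TDIV1 = 85,000 generations, TAD = 7,700,
ADMIX = 0.023, with the remaining sizes and change times fixed once
inside the published 95% intervals — geometric midpoints where the
intervals are narrow, lower-half values for the very wide size intervals
so that simulated datasets carry a segregating-site count of the same
order as the emulated panel (~2,600 vs 1,552 observed; the spectrum-shape
likelihood conditions on polymorphism, so this total affects power, not
correctness).

Reproducibility: one master seed; per-locus streams derive from it via
`numpy.random.SeedSequence`, so datasets are bit-identical across runs
and machines for a fixed seed.

## Spectra

Folded (minor-allele) 1D and 2D joint SFS are built from ALT-allele
counts (folding makes the REF/ALT orientation irrelevant).  A cell whose
pooled count exceeds half the pooled sample size folds into its
complement; an exact-half cell keeps the orientation with the smaller
population-1 count — a deterministic, order-independent tie rule chosen
here because the emulated pipeline does not document its own.  Spectra
round-trip through a fastsimcoal2-style observed-SFS text dialect
(`1 observations` header, `d0_i` column labels, `d1_j` row labels).

## Composite likelihood and its Monte-Carlo estimator

The observed spectrum is treated as multinomial over polymorphic cells:

    lnL = Σ_cells m_cell · ln max(p_cell, 10⁻⁸),

with expected cell probabilities p estimated by simulating locus
genealogies and accumulating *branch length* into each cell rather than
sampling mutations: under infinite sites the probability that a
segregating site falls in cell (i, j) is proportional to the expected
branch length subtending i + j carriers, so branch weighting is the
Rao-Blackwellised estimator of the same quantity and removes all Poisson
mutation noise.  The 10⁻⁸ floor guards cells left empty by a finite
replicate count.

**Scale identifiability.**  SFS proportions are *exactly* invariant under
multiplying all sizes and times by a common factor c (the per-locus
genealogy scales linearly; cell assignment is unchanged — the test suite
checks this to machine precision).  A SNP-only likelihood therefore
cannot identify absolute sizes or times.  The monomorphic site class
restores the scale: with S segregating among N total sequenced sites and
q(θ) = μ · E[tree length], the full likelihood adds
S ln q + (N − S) ln(1 − q).  Because q is the only scale-dependent term,
the scale can be profiled out in closed form: the optimal factor sets
q = S/N exactly.  `fit_model` therefore searches the SNP-only likelihood
with the ancestral size anchored at a reference value (removing both the
flat ridge and the scale dimension), then rescales all sizes and times by
ĉ = S / (N · μ · L̂(shape)) — migration rates by 1/ĉ — and reports the
profiled likelihood.  The profiled monomorphic term is a
model-independent constant, so AIC differences equal SNP-only likelihood
differences.  This profiling is the package's resolution of an
under-documented step in the emulated protocol (which reports absolute
parameter scales from SNP data without stating how the scale was tied
down); it is numerically crucial, because estimating q by simulation
instead multiplies the relative tree-length error by S and that noise
(±20–30 ln-units at desk-scale replicate counts) would drown the
admixture signal itself (~20–50 ln-units).

## Optimization

Search runs in transformed space: log10 for sizes, times and migration
rates, logit for ADMIX.  Points violating ordering constraints
(e.g. TAD ≥ TDIV1) are projected back onto the constraint surface rather
than penalised.  The default strategy per run is bounded differential
evolution (Sobol initialisation, `popsize`·dim candidates, `maxiter`
generations) followed by a local Powell polish at 4× the search replicate
count; multi-start Nelder–Mead is retained as an option but measurably
stalls on this 10-dimensional surface (it remained ~70 ln-units short of
the truth objective in calibration runs and produced nesting violations
between ALD and ADM1).  Within a run, every objective evaluation re-uses
the same per-locus seeds (common random numbers), making the stochastic
objective quasi-deterministic; every run's optimum is finally re-evaluated
on a larger seed set derived only from the master seed — hence shared by
all models fitted under that seed — and the winner is selected on that
common footing, since per-run seed sets carry offsets of several ln-units
that would otherwise distort the choice.

`fit_competing_models` adds symmetric cross-refinement for model
comparisons: after independent searches, each model is repeatedly refined
from every competitor's fitted parameters, translated across parameter
sets with the extra parameters at their null boundary (ADMIX at the lower
bound, migration at the lower bound), so a nested pair cannot be ranked
apart by optimizer luck alone.  Rounds repeat (up to 3) until no model
improves by more than 0.5 ln-units.

Model support: AIC = 2k − 2 lnL after converting log10-likelihoods to
natural logs; the support table also reports the *relative likelihood*
10^(log10L − log10L_best) — the likelihood ratio to the best model, not an
Akaike weight, matching the convention of the emulated analysis.

Confidence intervals are parametric bootstrap: simulate datasets under
the fitted model, refit each (warm-started from the point estimate plus
one global run), report 2.5%/97.5% quantiles.  The protocol being
emulated is self-contradictory on this point (its table footnote says
nonparametric, its methods parametric); the parametric version is
implemented.

## SNP pipeline

Filter order is completeness → HWE → (optional) first-SNP-per-locus,
each idempotent, each dropping whole loci.  The HWE test is the two-sided
exact test on heterozygote counts conditional on allele counts
(Wigginton-style; no mid-p), applied per population at α = 0.05 with no
multiple-testing correction; a locus deviating in any one population is
removed.  Transitions are {A,G} and {C,T}; a SNP is *diagnostic* when the
two populations are fixed for different alleles.

## Mitochondrial distances and dating

p-distances use pairwise deletion (positions with a gap or ambiguity in
either sequence are excluded per pair); group means are unweighted over
all cross pairs.  Dating applies a percent-per-My substitution rate to
the pairwise distance directly, T = p/r, because that convention
reproduces the emulated study's published dates; the per-lineage
alternative T = p/2r sits behind a flag.  Default rate range
2.5–3.1%/My; generations convert to years with a 2-year generation time.
Haplogroup assignment minimises the mean p-distance to reference groups
and flags exact ties instead of breaking them.

## Numerical and testing notes

* Problem sizes in the test suite are chosen for a single-CPU desk run:
  statistical checks use 2×10³–2×10⁴ Monte-Carlo replicates with 3-SE
  tolerances; the simulator is additionally cross-checked against
  msprime's branch-mode allele-frequency spectrum on the same translated
  demography, with the comparison threshold calibrated to ~1.5× the
  measured self-noise of the estimators.
* The admixture-recovery study fits ALD and ADM1 to data generated at the
  canonical study scale with a reduced search budget (1 DE run per model,
  1,500-replicate search evaluations, 30,000-replicate final
  evaluations) and with search ranges spanning ten-fold around the
  canonical scale (`models.study_search_bounds`): the fully broad default
  ranges cover four orders of magnitude per parameter and single desk-
  scale DE runs scatter by ~±20 ln-units across repeats on them, which
  is the same order as the admixture signal itself.  The full 100-run,
  broad-range protocol of the emulated study is available through the
  `paper` profile but is cluster-scale.
* Degenerate inputs: zero-probability pulses are legal (and equal the
  pulse-free model in distribution, not per-stream, because the pulse
  consumes RNG draws); zero-length epochs collapse; a monomorphic
  spectrum refuses normalisation with a clear error.
* Known limitations: no recombination within loci, no more than two
  sampled populations, no missing-data or error model, no analytic
  (diffusion) expected SFS — the Monte-Carlo expectation is the only
  backend, with common random numbers standing in for smoothness.
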