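# Methods

## The inference problem

Three parapatric genetic clusters — Northern, Central, Southern — are
observed at two loci: a concatenated mitochondrial fragment (COI+COII,
~1.5 kb, maternally inherited, effectively Ne/2 gene copies per Ne diploid
individuals) and a phased nuclear intron (EB14G, ~0.5 kb, 2Ne gene
copies). The competing explanations are encoded as thirteen rooted
three-population histories, each with exactly two divergence events:

* **R1–R6** (single refugium): one population is the source of both
  founding events, e.g. R3 = `N-S;N-C` (Northern founded Southern at the
  older time T_old, then Northern founded Central at T_recent).
* **DS1–DS6** (distributional shift / stepping stone): the population
  founded first is itself the source of the second event,
  e.g. DS1 = `S-N;N-C`.
* **V** (vicariance): an ancestral population of its own size split into
  Northern and Southern at T_old; Northern then founded Central.

Every founding event carries a founder bottleneck: forward in time the
derived population originates at `bot_Ne` individuals for
`bot_duration` generations, then switches to its stationary size. In the
vicariance scenario both daughters are bottlenecked (symmetric treatment;
the alternative of bottlenecking only one daughter has no principled
basis). Time is counted in generations with a one-year generation time, so
generations/1,000 = kya. There is no migration after divergence, no
recombination within a locus, and free recombination between loci.

## Coalescent engine

Backward in time, lineages within a population coalesce at rate
C(k,2)/G(t), where G(t) is the piecewise-constant number of gene copies
(locus scaling applied to the diploid Ne, bottleneck epochs included); at
a divergence event all lineages of the derived population(s) move into
the source. Sequences are produced by finite-sites simulation: the number
of substitutions is Poisson(total branch length × μ × L), events are
placed uniformly over branch length and sites and resolved oldest-first
from a random root sequence. Single substitution events are drawn from
the locus model (default HKY with κ = 2 and equal base frequencies; K2P
and JC69 available — JC69 is used wherever an analytic cross-check is
wanted). Per-site mutation rates are per generation; the default priors
take the mitochondrial rate in [5×10⁻⁹, 5×10⁻⁷] and the nuclear rate in
[5×10⁻¹⁰, 2.5×10⁻⁸] (an order of magnitude slower in the mean).

The engine is validated against closed forms (E[pairwise TMRCA] = G;
E[π] = Ne·μ for mtDNA and 4Ne·μ for nuclear loci) and against msprime
configured with the identical demography (two-sample KS on S and K,
α = 0.01); msprime is used only as an independent oracle, never as the
implementation.

## Summary statistics and site filtering

All statistics use complete deletion by default: columns containing N or
a gap anywhere in the analysis set are excluded and L_effective is the
retained count (pairwise deletion is available for the pair-difference
family). The ABC summary vector is fixed-order, per locus: for each
population (lexicographic label order) S, private S, mean and variance of
pairwise differences, mean and variance of the rarest-nucleotide count at
segregating sites, and Tajima's D; then for each population pair the
pooled S, K_xy and Hudson's F_ST — 30 entries per locus for three
populations, 60 for the two-locus design. For the vector, complete
deletion is applied jointly across all populations of the dataset (a
single retained-column set), which is what makes the entries mutually
consistent; the standalone two-population functions filter on their own
pair only, so on data with missing residues the pooled-S entries can
differ slightly from a pair-only computation. Undefined entries (e.g.
Tajima's D when S = 0 or n < 4) are stored as 0 with an explicit mask;
masked columns are dropped jointly from all distance computations.
Variance estimators divide by N (population convention) throughout.

Haplotypes are compared literally: 'N' never wildcard-matches, so
counting is deterministic at the cost of occasionally splitting a
haplotype that differs only by a masked base. A related caveat when
comparing against tables produced by common desktop popgen workflows:
their arithmetic sometimes implies statistics computed on
haplotype-collapsed alignments with θ_W based on total mutations η rather
than S. This package computes on all sequences with θ_W = S/a_n;
`diversity_table` can be fed a collapsed alignment if the other
convention is wanted.

## Neutrality and size-change tests

R² follows its published definition: sqrt(mean over sequences of
(U_i − K/2)²)/S with U_i the singleton mutations (folded) carried by
sequence i. Null p-values come from constant-size neutral coalescent
simulations without recombination, conditioned on θ_W from the observed
data by default (conditioning on the observed S is available), with the
continuity-corrected estimate (b+1)/(m+1); replicates on which the
statistic is undefined are excluded from m. Fay & Wu's H uses only
biallelic sites where the outgroup carries one of the two observed states.
The compound DH test calibrates a shared marginal quantile γ on the
simulated joint null so that P(D ≤ q_D(γ) and H ≤ q_H(γ)) equals the
nominal level, and reports the smallest level at which the observed pair
rejects. Mismatch-distribution modality is reported descriptively (local
maxima after a small moving average, ignoring peaks below 5% of the
tallest); no formal modality test is attempted.

## ABC machinery

Reference tables interleave rows across scenarios; statistics are
standardized by median and 1.4826×MAD (SD fallback where the MAD is
zero). Rejection keeps the ceil(tolerance × rows) closest rows under the
Euclidean distance on standardized, jointly-defined statistics, ties
broken by row index. Posterior model probabilities come from a
ridge-stabilized (λ = 10⁻⁶) polychotomous logistic regression of scenario
identity on the standardized statistics over the accepted rows, evaluated
at the observed vector, with delta-method 95% intervals from the inverse
penalized information; when acceptance is single-scenario or the fit
fails, rejection frequencies with Clopper–Pearson intervals are reported
instead. A practical note from our calibration experiments: at desk-scale
tables (≲10³ rows per scenario) the 13-way logistic fit is noisier than
plain rejection frequencies, so the scenario-recovery analyses in the
test suite classify by the modal accepted scenario; the logistic route is
the default for posterior probabilities in the tournament, where each
comparison involves at most six scenarios.

The tournament compares each tier-1 group on its own freshly simulated
table; group winners (ties toward the earlier scenario in the group) plus
declared extras (the vicariance scenario) meet in tier 2, again on a fresh
table. Type I error is the fraction of pseudo-observed datasets simulated
under alternatives that are classified as the focal scenario; type II the
fraction of focal-scenario datasets classified otherwise.

Parameter posteriors are the accepted rows' draws, optionally adjusted by
weighted (Epanechnikov) local-linear regression of each log-parameter on
the standardized statistics, with a slope ridge of 10⁻²·n_accepted —
all parameters here are strictly positive, hence the log scale. The
adjustment is skipped with a warning when the accepted rows do not exceed
the predictor count, since an (under)determined regression would collapse
the posterior. Calibration experiments (50 stepping-stone pseudo-datasets,
tables up to 10⁴ rows) showed the adjusted sample sharpens the point
estimate (relative median absolute error ~0.06–0.08 for T_old) but its
equal-tailed quantile intervals undercover (~76–88%), whereas the
unadjusted accepted-sample intervals are calibrated (~92%): interval
statements at these table sizes should therefore use `adjust="none"`,
and that is what the coverage checks do. PCA model checking projects the
standardized simulations and the observed vector on two components and
flags whether the observation falls within the simulated score ranges.

## SDM post-processing

Probability rasters (one per period: present, Mid-Holocene ~6 kya, Last
Glacial Maximum ~22 kya, Last Interglacial ~120–140 kya) are binarized at
a single scalar threshold, suitable iff p > t (strict). The threshold is
chosen from per-pseudo-absence-replicate TSS curves on a 0.01 grid: either
the median of per-replicate argmaxes, or the smallest threshold at which
the median curve's forward difference drops below 0.02 per step (the
"lowest before the steep slope" rationale). Shift maps are the cell-wise
2·recent − older with categories colonization (2), stability (1), absence
(0), extinction (−1); stability across periods is the cell-wise product.
Grids must match exactly — no resampling — and I/O is single-band ESRI
ASCII with a declared no-data value; points belong to cells under
half-open [edge, edge+Δ) intervals.

## Synthetic data

The default sequence fixture simulates the study design — 16 Southern,
24 Northern, 82 Central individuals (122 mtDNA sequences; two phased
nuclear sequences per individual) — under the stepping-stone history with
T_old = 64,800 and T_recent = 8,630 generations (the study's point
estimates), μ_mt = 1.2×10⁻⁷ and μ_nuc = 6×10⁻⁹ per site per generation,
and stationary sizes (130k, 85k, 25k) chosen so θ = Ne·μ reproduces the
observed per-site diversities (≈0.016/0.010/0.003). Generation retries a
bounded number of times until the realized data show the qualitative
signature (π_S > π_N > π_C, Tajima's D < 0 in Central) and records the
outcome rather than looping. Raster fixtures are smooth random fields plus
a Gaussian latitudinal ridge pushed through a steep logistic, with the
ridge drifting northward (or widening, or static) across periods;
presences are sampled proportionally to cell probability, pseudo-absences
uniformly (91 presences, 20 replicates of 100 pseudo-absences by default).
What the fixtures do not emulate: real bioclimatic spatial structure,
within-colony relatedness, sequencing error beyond rare Ns, recombination
in the nuclear intron, or selection — so passing tests demonstrate correct
inference under the model, not robustness to those violations.

The `separated_priors` configuration used for recovery experiments fixes
mutation rates at their point estimates and narrows Ne to
log-uniform(1.2×10⁵, 2×10⁵) with strong founder bottlenecks (Ne 10–50 for
80–100 generations) and tight, non-overlapping time bands (T_old 55–75 k,
T_recent 7–11 k generations). The Ne band is a structural choice, not a
tuning detail: scenario identity is only identifiable when at least one
locus retains coalescent memory across the divergence times. With Ne far
below the times, a founded population re-equilibrates and mirror-image
scenarios become likelihood-equivalent; with Ne far above, the recent
event leaves no within-population signal. Setting the mitochondrial
timescale (Ne/2) at the divergence times and the nuclear (2Ne) well above
them lets the shallow locus record the direction of the recent founding
and the deep locus preserve the older founder signature.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the pipeline at
workstation scale, chosen as this package's own reference conditions:
reference tables of 300–2,000 rows per scenario (tournaments at 300),
scenario recovery over all 13 scenarios × 25 replicates against a
1,200-row/scenario table, credible-interval coverage over 50 replicates
against a 2,000-row table, neutrality calibration over 400 neutral
replicates × 150 null simulations, and oracle equivalence over 1,000
random alignments. Production-scale analyses (10⁵–10⁶ rows per scenario)
use the same code paths; only the row counts change. Every random stage
takes an explicit seed and is bit-reproducible given it. Degenerate inputs
are handled by sentinel-and-mask (undefined statistics), bounded retries
(prior ordering constraints), or explicit errors (empty tables,
misaligned rasters); p-values never return exactly zero by construction.

## Known limitations

* Scenario discrimination among all 13 histories is intrinsically hard at
  small sample sizes; several mirror-image pairs approach
  likelihood-equivalence outside the prior regime described above, and the
  second-tier error rates can be large — conclusions should always be
  read together with the reported type I/II error rates.
* Delta-method intervals for logistic posterior probabilities are
  asymptotic and can be wide or degenerate near 0/1 at small accepted
  counts; the rejection-frequency fallback bounds them.
* The finite-sites mutation scheme applies a uniform per-site total rate
  (model-specific only in the replacement step), which differs from a full
  rate-matrix HKY at high divergence; at the diversities simulated here
  (π ≤ 0.04/site) the bias is negligible, as the msprime cross-validation
  confirms.
* Compound-test variants other than DH (e.g. HEW) are not implemented.
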