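# Methods

`ddpop` analyses haploid multi-locus re-sequencing panels of the social
amoeba *Dictyostelium discoideum*: many short gene fragments (~400–600 bp)
sequenced in a couple dozen wild strains, with one chromosome sampled
densely to resolve linkage disequilibrium and recombination. This note
records the models, estimators, numerical conventions, and the design
choices made where the design was genuinely open.

## Data model and conventions

* Coordinates are 1-based, inclusive, on six declared chromosomes.
* `N` and `-` are both missing data. A site is biallelic with respect to
  non-missing calls only; sites with three or more alleles are excluded and
  counted. Singletons are retained at calling time; the 10% minor-allele
  frequency filter is applied once, globally, before all LD and
  composite-likelihood analyses (frequencies computed over callable calls).
* Missing-data policy: pairwise deletion for π, pairwise differences, Fst
  and two-locus haplotype counts; for θ_W, S counts sites biallelic among
  non-missing calls while L is the full surveyed length. Tajima's D uses
  constants computed from the panel n, not per-site n — a deliberate
  simplification whose error is negligible at the ~2% missingness these
  panels show.

## Diversity statistics

θ_W = S/(a₁L) with a₁ the harmonic number of n−1. π is the mean over
strain pairs of (differences / jointly callable assayed sites), rescaled to
the surveyed length. Tajima's D follows the 1989 constants (a₁, a₂, b₁,
b₂, c₁, c₂, e₁, e₂) with the per-site unbiased heterozygosity sum
Σ 2k(m−k)/(m(m−1)) as the π term; it is undefined (returned as `None`) for
invariant data. Hudson's Fst is 1 − H_w/H_b with H_w the average of the two
within-group mean pairwise diversities. The genome summaries are L/S (mean
inter-SNP spacing) and π × genome size (expected genome-wide pairwise
differences; genome size defaults to 34 Mb).

Pooled (Table-style) values use totals over fragments; per-fragment
breakdowns recompute each statistic inside the fragment.

## Linkage disequilibrium

For each SNP pair, complete-case haplotype counts give
D = p₁₁ − p₁q₁ and r² = D²/(p₁(1−p₁)q₁(1−q₁)); pairs with a monomorphic
complete-case margin are dropped (counted). Distances are assembly-
coordinate differences; cross-chromosome pairs are the unlinked background,
summarized by their mean r² and 80th percentile. The distance classes are
<0.1 kb, 0.1–0.5, 0.5–10, 10–25, 25–50, 50–100 kb, every 100 kb to 1 Mb,
then 1 Mb windows; intervals are left-closed, right-open. A bin is declared
*elevated* only if it contains more than 10 pairs and its mean strictly
exceeds the unlinked 80th percentile (a 10⁻¹² guard keeps exact ties from
flipping the flag).

The decay test permutes distances against r² over linked pairs
(1000 permutations by default) with Spearman rank correlation as the
statistic — chosen for robustness to the extremely skewed r² distribution;
Pearson is available by flag. One-sided p for negative correlation with the
add-one rule.

## Recombination

**Four-gamete / Rm.** Incompatible pairs (all four haplotypes among
complete cases) define intervals that must contain a breakpoint.
Hudson–Kaplan: discard intervals containing another interval, scan by right
endpoint, greedily select non-overlapping intervals; Rm is the count.
Computed per chromosome and summed; tested against exhaustive
minimum-hitting-set search on ≤10-site matrices.

**Moment estimator of ρ.** We equate the across-pair sample variance of
pairwise difference counts with a coalescent expectation assembled from the
standard two-locus covariance of pairwise coalescence times,
g(c) = (c+18)/(c²+13c+18) (time in 2N units; g(0)=1 recovers the
exponential variance, g→0 as loci unlink). Writing p_s for the per-site
expected pair difference rate (unbiased heterozygosity), the expectation is

    E[V](ρ) ≈ (T₁ − b₁·Σp_s − b₂·Σp_s²) + (1−b₂)·Σ_{s≠s'} p_s p_{s'} g(ρ d_{ss'}/L)

with T₁ = Σ p_s(1−p_s) and b₁, b₂ Tajima's (1983) coefficients for the
variance of the pair-averaged difference count — the subtraction corrects
for estimating a within-sample variance rather than a cross-replicate one,
with the θ² part damped by the same g. E[V] is monotone decreasing in ρ, so
the estimate is a bisection solve on [0, 10⁴] at tolerance 10⁻³; an
observed variance above the ρ=0 expectation returns 0 with a
`no_recombination_signal` flag and the upper bound is flagged `boundary_max`.
This is a reconstruction in the spirit of the variance-of-pairwise-
differences moment methods, not a line-for-line transcription of any one
published derivation; its accuracy claim is the simulation-recovery test
(median within a factor of 3 of truth at ρ=40, n=25, 500 kb panels).

**Composite likelihood.** A Monte-Carlo two-locus lookup table is built by
simulating two-locus genealogies (lineages as per-locus sample bitmasks;
coalescence at rate k(k−1)/2, recombination at ρ/2 per doubly ancestral
lineage) and placing one mutation per locus on a branch chosen
proportionally to length — the θ→0 one-mutation-per-locus conditioning.
Folded configurations (allele relabeling at either locus, locus swap) are
tallied on a ρ grid (default 21 points on [0,100], 10⁵ genealogies per
point; reduced tables are used where speed matters and their size is always
recorded in the table object). Each SNP pair then contributes
log P(config; ρ_T·d/L) with linear interpolation on the grid (clamped at
the ends); the region estimate is the grid argmax of the summed curve.
Pairs whose complete-case sample size is below the table's n (missing data)
are rescaled to n and matched to the nearest stored configuration by L1
distance; the fallback count is reported. Unseen configurations are floored
at half a Monte-Carlo count before logging.

**Likelihood permutation test.** SNP physical positions are permuted with
genotype columns fixed and the composite likelihood re-maximized each time.
The statistic is the maximized composite log-likelihood: when LD genuinely
decays with distance, the true position arrangement explains the pairwise
configurations better than scrambled ones. (The re-maximized ρ̂ itself is
available as an alternative statistic, but it points the wrong way:
scrambling positions makes data look *more* recombined, so ρ̂ has
essentially no power as a one-sided statistic — we measured p≈0.3 on data
simulated at ρ=40 versus p≈0.001 for the likelihood statistic.) Add-one
rule; crossing-over is modeled linear in bp distance (no gene conversion).

## Clustering and geography

K2P distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) over jointly non-missing columns
(P transitions, Q transversions); saturated pairs are reported undefined
rather than coerced. Neighbor joining is scikit-bio's Saitou–Nei
implementation (negative branch lengths clamped with the deficit moved to
the sibling edge). Bootstrap support resamples columns of the concatenation
with replacement — implemented as a multinomial reweighting of collapsed
unique column patterns, which is equivalent and far cheaper at 10³
replicates × ~65 kb — and scores each original internal bipartition by the
percentage of replicate trees containing it (strict bipartition matching on
unrooted trees). Geographic distances are haversine great circles
(R = 6371 km); any two strains sharing a site name get a fixed within-site
distance (1 km default), generalizing the single-station convention.
The Mantel test correlates upper-triangle entries (Pearson) with strain-
label permutations of one matrix, one-sided for positive association.

## Social (chimera) statistics

For fruiting-body proportions p₁..p_N of a focal strain with mean p̄ and
measured initial-mix proportion p_o:

* r_i = (p_i − p̄)/(1 − p̄) and r_i′ = (p̄ − p_i)/p̄;
  r_fb = (1/N) Σ [p_i r_i + (1−p_i) r_i′]. The 1/N normalization is chosen
  so the stated endpoints hold exactly: identical proportions give 0,
  proportions all at {0,1} give 1 — and r_fb(p) = r_fb(1−p) exactly.
* Dominance d = mean(p_i) − p_o (antisymmetric in the focal strain); |d|
  is summarized per marker/replicate.
* LS = mean |x_j − x̄| (the Levene transform); arcsine variance is the
  ddof=1 variance of arcsin(√x_j).

These follow the assay literature's verbal definitions; where a displayed
formula was not recoverable, the endpoint constraints above fixed the
normalization, and that reconstruction status is flagged here deliberately.
p̄ is the mean over fruiting bodies, not p_o, which is used only for d.
Two markers per pair are technical replicates: statistics are computed per
(marker, replicate) series and averaged, with the series-level rows kept.
The sympatric-vs-allopatric comparison is a one-sided permutation test on
the difference of group mean r_fb (Welch's t by flag); regressions of r_fb
and |d| on SNP divergence report OLS R²; pairs are also split at the median
divergence. Standard curves are OLS of peak height on known proportion;
proportions are recovered by inverse regression, clipped to [0,1] with the
clip count reported.

## Synthetic data generator

The coalescent simulator is Hudson's algorithm with recombination:
lineages carry ancestral-material intervals annotated with sample bitmasks;
coalescence merges interval overlays (dropping segments that reach their
MRCA), recombination splits at a uniform point within a lineage's span, and
mutations accrue at θ_site/2 per bp per lineage per 2N-generation,
restricted to fragment windows when a windowed layout is simulated (the
ancestry still spans the whole region, so inter-fragment linkage is real).
Infinite-sites mutations at continuous positions are discretized to unique
integer bp. Agreement with msprime (mean S and mean π at matched
parameters) is part of the test suite; msprime is used only as that
cross-check, never as the implementation.

The study-design generator emits 137 fragments of 400–600 bp: 94 on the
dense chromosome with adjacent spacings drawn uniformly and rescaled so
their mean is exactly 55.6 kb within a [2.3, 233.7] kb range, and 43 spread
over the other five chromosomes. Those remaining fragments are simulated as
independent loci: at the generator's per-bp recombination density their
hundreds-of-kb spacings put them far past the LD scale, so independence is
the faithful limit (the cost is that same-chromosome LD off the dense
chromosome carries no decay signal; all decay analyses target the dense
chromosome). Defaults are the study conditions themselves: n=25 strains,
θ_site=0.0008, ρ=40 for the dense region (the order of its
composite-likelihood estimate), 2% missing calls, 13 strains at one dense
collection site. 0/1 alleles map to transitions on an ~78% AT background,
matching the organism's base composition and keeping K2P distances
non-degenerate; a transversion fraction is available but defaults to 0.

The chimera generator is a clonal/mixed mixture: with probability s
(*segregation*) a fruiting body is clonal (one strain, chosen with
probability p_o), otherwise it mirrors the initial mix; truncated-Gaussian
noise σ is applied per marker. Under the implemented r_fb the expectation
equals s itself, so recovery tests have an interpretable target. What the
generator does **not** emulate: real pyrogram artifacts, plate effects,
strain-specific growth differences, demography (bottlenecks/growth),
selection, or gene conversion — passing tests certify estimator
correctness under the neutral model, not robustness to those features.

## Problem sizes and numerical choices

Simulation-based checks run at the study scale (n=25, the 94-fragment
dense layout) with 50–500 replicates per claim; the two-locus tables used
in tests and in the acceptance script are reduced (11 grid points on
[0,100], 3×10³ genealogies per point) — the package default (21 × 10⁵)
is the production setting and takes minutes on one core. Permutation
counts: 1000 for the LD decay, Mantel and likelihood tests (199 or 99
inside repeated-calibration loops, where only the α=0.05 decision matters).
Ties and degenerate inputs: constant r² yields p=1; p̄∈{0,1} makes r_fb
undefined; monomorphic complete-case margins drop an LD pair; saturated
K2P pairs propagate as named errors into tree building. All randomness
flows through explicit integer seeds; every simulator is a pure function
of (parameters, seed).

## Known limitations

* The moment and composite ρ estimators are moderately biased upward on
  MAF-filtered, sporadically missing panels (the nearest-configuration
  fallback coarsens per-pair likelihoods); both are order-of-magnitude
  instruments, which is how their outputs should be read.
* Tajima's D constants from panel n slightly mis-weight sites with missing
  calls.
* Bootstrap supports assume the concatenation is one exchangeable column
  pool; fragment boundaries are deliberately ignored.
* The within-site 1 km geographic convention is a modeling choice, not a
  measurement.
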