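# Methods

`diffislands` detects *genomic islands of differentiation*: contiguous
stretches of a genome where population differentiation, measured SNP by
SNP, is systematically higher (HDI) or lower (LDI) than the genome-wide
background. The pipeline has four statistical stages — a per-locus
F-statistic scan, a coalescent null model, a hidden-Markov segmentation
with false-discovery-rate control, and downstream enrichment tests —
plus a synthetic-data generator that defines the conditions under which
everything is validated.

## Per-locus statistics

Differentiation at each biallelic SNP is the Weir–Cockerham θ estimator,
built from the among/within-population components of allele-frequency
variance with the usual finite-sample corrections (observed heterozygote
proportions enter the correction terms; missing genotypes are dropped
per population). θ is not clipped at zero: slightly negative estimates
are informative about the lower tail and clipping would bias the null
comparison. The multilocus (ratio-of-sums) estimator is used wherever a
genome-wide level is needed, because it — not the mean of per-locus
ratios — is the quantity that island-model theory predicts.

Between-population heterozygosity is defined as H_BP = 2·p̄(1−p̄) with p̄
the *unweighted* mean of population allele frequencies. The quantity
exists to condition the null distribution of θ on allele frequency;
among the variants of "between-population heterozygosity" in the outlier-
scan literature, the pooled-unweighted-mean form was chosen because it is
computable identically for observed and simulated loci and is insensitive
to unequal sample sizes. The alternative (average pairwise heterozygosity)
can be swapped in behind the same function without touching callers.

Hierarchical structure is summarized by three fixation indices from a
nested allele-count ANOVA (gene copies in populations in continental
groups, unequal-size coefficients): F_CT (among groups), F_SC (among
populations within groups) and F_ST (populations against the total),
with per-locus variance components summed over loci before the ratios
are taken, so (1−F_ST) = (1−F_SC)(1−F_CT) holds exactly.

Spatial clustering of a statistic along a chromosome is tested with a
Wald–Wolfowitz runs test: dichotomize at the chromosome median, count
runs, and use the normal approximation with continuity correction,
one-sided toward fewer runs (clustering). The approximation is accurate
to ~0.01 against exhaustive enumeration at n = 12 and improves rapidly
with n; the default guard requires n ≥ 20.

## The coalescent null

The null distribution of (θ, H_BP) for a neutral SNP comes from the
structured coalescent on a world of demes. Time is scaled in units of 2N
generations: lineages in the same deme coalesce pairwise at rate 1 and
every lineage migrates at rate M/2, where M = 4Nm. Under the **finite
island model (FIM)** the destination is uniform over the other demes;
under the **hierarchical island model (HIM)** the world is partitioned
into groups and a lineage moves with total rate M1/2 to the other demes
of its own group and M2/2 to demes of other groups (uniform within each
class). One SNP per genealogy is created by dropping a single mutation
on a branch chosen proportionally to branch length — which guarantees
polymorphism in the total sample — and gene copies are paired within
demes into diploid genotypes so that the very same θ estimator runs on
simulated and observed data.

The event loop is a purpose-built numba kernel. An event-driven
simulation of this process is dominated by migration events; the kernel
keeps per-deme occupancy counts and the total coalescence rate
incrementally, so a locus costs microseconds-to-milliseconds even at the
default world of 10 groups × 100 demes. The kernel is cross-checked in
the test suite against msprime on a small island model (two-sample KS on
the θ distribution) and against the closed-form island-model expectation
F_ST ≈ 1/(1 + M·(d/(d−1))²).

Defaults: the HIM world is 10 groups of 100 demes and the FIM a single
group of 100 demes; the genome-wide null has 50,000 loci. The tests and
the acceptance script run a scaled world (10 × 20 demes) and 5,000-locus
nulls, which keeps every property being tested intact while holding the
suite to minutes; the world size enters only through weak
finite-number-of-demes corrections that calibration absorbs.

**Sampling layout.** The null mirrors the observed data: the same number
of sampled groups, demes per group and gene copies per deme. The null of
a statistic depends on the sampling configuration at least as much as on
the migration rates, so simulating the full world but sampling the
observed layout is not optional.

**Ascertainment.** SNP panels are ascertained against rare variants. The
`ModelConfig.maf_min` field applies the same total-sample
minor-allele-frequency cutoff to simulated loci (rejected genealogies are
replaced), so the null mirrors the panel's SNP character. Without it the
half of the null mass below the panel's heterozygosity range coarsens
the conditioning near the boundary. The companion generator
`coalescent_panel` draws *observed* panels from the same process with
the same cutoff.

**Migration calibration.** M1 and M2 are tuned so that the simulated
mean F_SC and F_CT match the observed panel's values: coordinate-wise
bisection on log M1 (driving F_SC) and log M2 (driving F_CT), pilot
simulations of 2,000 loci per evaluation, absolute tolerance 0.005
(knobs exposed). All pilots within a round share one random seed —
common random numbers make the pilot objective a smooth, monotone
function of the rate, so bisection converges to the pilot noise floor
instead of rattling; each round closes with a fresh-seed check. A
non-convergent calibration raises an error carrying the best
configuration found.

**P-values and normal scores.** Null loci are split into equal-count
H_BP bins (default 20, the standard conditioning realization for this
family of outlier tests). Within the observed locus's bin,
q = (#{θ_sim < θ_obs} + ½·#{ties} + 0.5) / (n_bin + 1): the mid-rank
treats ties symmetrically and the continuity term keeps q strictly
inside (0, 1), which matters because the HMM consumes z = Φ⁻¹(q) and
must never see ±∞. p_high = 1−q is the evidence for unusually high
differentiation, p_low = q for unusually low. One genome-wide null is
simulated and reused across chromosomes (the null is locus-exchangeable);
per-chromosome nulls, and per-chromosome calibration for sex chromosomes
with their reduced effective size, are available by re-running the scan
per chromosome with its own config.

Validation of this stage is a self-consistency property: a neutral panel
drawn from the HIM itself (with MAF ascertainment), scanned against a
null *calibrated from that panel's own F-statistics*, yields ~1% of loci
with p_high ≤ 0.01 and z indistinguishable from standard normal; the
same panel scanned against a FIM null shows an excess of significant
loci and a right-skewed z distribution — the signature of unmodelled
hierarchical structure masquerading as selection. The Balding–Nichols
generator (below) is a *different* process from the coalescent: it
matches the null in its first moments but not in the conditional shape
of θ given H_BP, so it is not used for this particular property.

## The hidden Markov segmentation

Per-SNP z-values on one chromosome are modelled by a 3-state hidden
Markov chain — L (low differentiation), I (intermediate), H (high) —
with Gaussian emissions N(μ_s, σ_s²) and a transition matrix whose
direct L↔H entries are structurally zero: a genome cannot jump between
extreme regimes without passing through background. The multiplicative
Baum-Welch update preserves exact zeros, so the constraint holds through
any number of EM iterations. An unconstrained variant is available as a
sensitivity check.

Estimation is per chromosome, EM with random restarts (default 1,000;
the test profile uses 20), convergence at objective gain < 1e-6 or 500
iterations, best final likelihood kept, and states relabelled so that
μ_L < μ_I < μ_H. Four safeguards address well-known failure modes of
maximum-likelihood Gaussian-mixture HMMs; all four are documented
parameters, not hidden behavior:

1. **σ floor** (`sigma_min_frac`, default 0.3·sd(z)): the likelihood is
   unbounded as a component collapses onto near-coincident points, and a
   collapsed "spike" state produces absurdly confident posteriors.
   Since emissions are z-scores, no genuine state is a razor-thin slice
   of the data spread. σ is clamped at the floor (quantile saturation of
   strong islands produces exactly-tied z-values that an unclamped fit
   would collapse onto); a fit reaching the absolute floor 1e-4 is
   discarded as degenerate.
2. **Admissible label order**: the structural zeros forbid transitions
   between the two states carrying labels 0 and 2, which is only the
   intended model when those labels hold the extreme means. Restarts
   converging with the middle mean on an extreme label are discarded.
3. **Intermediate-majority rule**: the method presumes a mostly-neutral
   genome — the intermediate state is the background. Restarts that park
   the data bulk in an extreme state are discarded, because decoding
   such a fit marks entire chromosomes as confident islands.
4. **Transition prior** (`trans_pseudocount`, default 1 per allowed
   entry): on data with no genuine spatial structure the likelihood is
   nearly flat in the transition matrix and EM can drift to
   near-absorbing self-transitions whose dynamic reinforcement
   manufactures machine-precision posteriors. One prior count is
   negligible against genuinely persistent states. With the prior the
   engine maximizes (and asserts the monotonicity of) the penalized
   objective; at pseudocount 0 that objective is the plain likelihood.

The initial distribution is replaced after fitting by the stationary
distribution of the transition matrix (`init_dist="stationary"`). With a
single sequence per chromosome the free-π maximum-likelihood solution is
a point mass on whichever state best fits the first SNP, making that
SNP's posterior exactly degenerate (LIS = 0) and auto-selecting it at
any FDR level — one guaranteed false island per chromosome. The raw EM
estimate is available via `init_dist="em"`.

**Model check.** A chromosome's decoding is only used if the fitted
3-state model beats a single Gaussian by BIC (10 free parameters against
2). A hidden-state segmentation is meaningful only where the data carry
multi-state structure; on a featureless chromosome the ML 3-state fit is
an arbitrary mixture decomposition of the bulk whose extreme components
claim ordinary tail observations with near-certainty. Island-bearing
chromosomes clear the check by hundreds of log-units; pure-noise
chromosomes fail it by construction. Chromosomes failing the check are
treated as all-intermediate.

**Decoding and island calling** follow a two-step rule. The Viterbi path
(ties broken toward the lower state index — measure-zero for continuous
emissions but deterministic) delimits maximal runs of H or L. Separately,
each SNP's Local Index of Significance, LIS_s = 1 − γ(s), the posterior
probability of *not* being in state s, is pooled genome-wide across
chromosomes per target state; sorting ascending and keeping the largest
prefix whose running mean stays ≤ α controls the genome-wide FDR at
α = 0.001 (the selected SNPs are FDR-SNPs). A Viterbi run becomes an
island only if it contains at least one FDR-SNP of the matching state.
Island genomic span runs from the first to the last member SNP
(SNP-span semantics, not midpoints to neighbours). Genome-wide pooling
of per-chromosome LIS values is the reading most consistent with a
"genome-wide" FDR; per-chromosome pooling would control a different
error rate.

The LIS-FDR guarantee (realized false-discovery proportion ≈ α) holds
*under the fitted model*; the suite verifies it on data simulated from a
known chain. Under model misspecification the realized FDP can exceed α
— in practice the strongly supported islands carry LIS values orders of
magnitude below α and dominate the selection.

## Enrichment analyses

All island-level association tests preserve the observed island/gap
length structure. The block permutation re-orders, per chromosome, the
alternating sequence of island blocks and gap blocks uniformly at random
(lengths preserved), recomputing the overlap statistic (count of islands
touching a feature, or total bp) each time; the empirical p-value is
(#extreme + 1)/(n_perm + 1), two-sided around the null mean by default
with one-sided variants. Permutations are per chromosome (blocks never
change chromosome) — the conservative reading of permuting "across the
whole genome"; a cross-chromosome variant would require deciding how
lengths map between chromosomes of different sizes.

Questions about non-genic islands (zero gene overlap, the same predicate
used everywhere) use conditioned permutation: each island is re-placed
uniformly among the gene-free positions of its chromosome, by rejection
sampling with an exact enumeration fallback when the feasible region is
narrow. Statistics: mean distance to the closest gene, or count of
islands overlapping a TFBS.

Categorical enrichment (genic, non-synonymous) is Fisher's exact test on
the 2×2 membership table; F_ST contrasts between SNP classes use a
one-sided Mann–Whitney U (exact enumeration at n ≤ 8 — the normal path
refuses nothing but ties are handled by mid-ranks either way).
Island-vs-background recombination uses a weighted two-sample t-test
(statsmodels frequency weights; an island's weight is the number of
recombination-map windows it overlaps, a precision proxy — the method's
source does not state the weights, and window count is the natural
choice). The island-size/recombination relationship is an OLS ANCOVA of
log10(length) on rate × genic status; lengths span three orders of
magnitude, so the log response is the defensible default (raw scale by
flag). Recombination hotspots are map windows with standardized rate
strictly greater than 10, adjacent qualifying windows merged. Per-SNP
continental assignment takes, for each group, the absolute difference
between the unweighted mean frequency inside and outside the group, and
assigns the SNP to the argmax (fixed-order tie-break, logged).

## Synthetic data

Two generators define the study conditions.

`synth_panel` draws hierarchical **Balding–Nichols** panels: ancestral
frequency p0 ~ U(0.05, 0.95) (array-like ascertainment against rare
variants), group frequency Beta-distributed with mean p0 and variance
F_between·p0(1−p0), deme frequency likewise around the group frequency
with F_within, genotypes Binomial(2, p_deme). Defaults: 4 groups × 5
demes × 10 diploids, 3 chromosomes × 5,000 SNPs, F_within = 0.05,
F_between = 0.08 — of the order seen among human continental groups —
with 1% missingness. Planted segments multiply the Beta variance
parameter (not F_ST directly, keeping frequencies in [0, 1] without
clipping): multipliers > 1 plant high-differentiation islands, < 1 low.
Island-recovery tests plant one H and one L segment of 150 SNPs per
chromosome at multipliers 8.0 and 0.02 — strong effects, and both types
on every chromosome as in real genomes, which also gives every HMM state
genuine support. The generator is fast and has closed-form F
expectations, but models no linkage disequilibrium (loci independent
given the planted track) and is not the coalescent: per-locus θ given
H_BP has a different conditional shape, so pipeline z-values on
Balding–Nichols input carry a small systematic offset that the HMM
absorbs but a KS test against N(0, 1) would detect.

`coalescent_panel` draws neutral panels from the structured-coalescent
null itself (with MAF ascertainment) and is the right input for
properties about a *correctly specified* null.

`synth_annotations` produces non-overlapping genes at a set density,
TFBS clustered near gene starts, and a tiling recombination map with
log-normal rates, a set fraction of windows promoted to hotspot rates;
`synth_filter_fixture` builds a worldwide-panel-sized set of lightweight
records with exactly the four disjoint QC-removal categories
(12 all-missing / 4 untyped-in-a-population / 50 monomorphic / 188 on
excluded chromosomes) so the filter arithmetic is reproducible. All
generators are bit-for-bit reproducible under a seed.

What passing tests on these generators show — and what they do not: the
pipeline's statistical calibration is demonstrated under independence of
loci; real panels have LD, so effective numbers of independent loci are
smaller and island boundaries softer. Ascertainment here is a clean MAF
cutoff; real array ascertainment is population-biased in ways the test
conditions do not emulate.

## QC filtering

Panel QC applies four rules *sequentially*, attributing each removed SNP
to the first rule it trips, so the per-rule counts are additive: (1)
only missing data; (2) not typed at all in at least one population
(evaluated on populations, not groups); (3) monomorphic across all
populations; (4) on an excluded chromosome (Y, the X/Y pseudoautosomal
labels, mtDNA). The X chromosome is carried as an ordinary chromosome
with a ploidy flag; male hemizygosity is out of scope (synthetic data is
diploid-coded everywhere).

## Numerical choices and degenerate inputs

Scaled (not log-space) forward-backward with per-step normalization;
posteriors renormalized defensively, falling back on the filtered
distribution if a row degenerates. Quantiles never reach 0 or 1 by the
continuity correction. Monomorphic loci carry NaN θ and are excluded
from the scan. Empty FDR selections, empty island lists, empty BED
files, and islands outside recombination-map coverage are all legal and
return empty/NaN results rather than raising. Errors are reserved for
contract violations: malformed files name the offending row/cell, a
single population cannot yield θ, all-tied runs-test input has no
dichotomy, calibration targets must lie in (0, 1).

## Known limitations

- No linkage disequilibrium anywhere: the synthetic generators draw loci
  independently and the null is single-locus. The LIS machinery models
  dependence *of the state sequence*, not of the observations given
  states.
- The FDR guarantee is model-conditional (see above).
- Calibration matches first moments of (F_SC, F_CT); residual
  shape mismatch between a true demography and the island-model family
  is not corrected — which is the method's own stated limitation, not an
  implementation one.
- X-chromosome-specific effective-size handling is exposed only through
  per-chromosome recalibration, not automated.
- The test-profile problem sizes (5,000-locus nulls, 10 × 20-deme world,
  20 restarts, 3,000-SNP chromosomes) were chosen to keep the suite at
  desk scale; all defaults remain at the full study scale.
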