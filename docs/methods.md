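# Methods

## The spectrum model

gBGC behaves like genic selection of population-scaled strength
B = 3N_E·b (haplodiploids) on weak/strong alleles. For a derived allele
subject to bias B, the stationary sojourn-time density over population
frequency x is

    φ(x; B) = (1 − e^{−B(1−x)}) / ((1 − e^{−B}) · x(1−x)),   φ(x; 0) = 1/x,

and binomial sampling of n haplotypes gives the expected spectrum
G_i(B) = ∫₀¹ C(n,i)xⁱ(1−x)ⁿ⁻ⁱφ(x;B)dx for derived counts i = 1..n−1.
SW mutations experience −B; WW/SS mutations are neutral.

Observed class spectra are modelled as independent Poisson counts

    E_i[WS] = r_i ((1−e_WS) θ_WS G_i(B)  + e_SW θ_SW G_{n−i}(−B))
    E_i[SW] = r_i ((1−e_SW) θ_SW G_i(−B) + e_WS θ_WS G_{n−i}(B))
    E_i[N]  = r_i θ_N ((1−e_N) G_i(0) + e_N G_{n−i}(0))

with per-class influx scales θ > 0, polarization-error probabilities
e ∈ [0, 0.5] (a mispolarized site swaps class and mirrors its frequency,
i → n−i), and a multiplicative distortion vector r_i > 0 shared across
classes with r_1 ≡ 1 for identifiability. The distortion is a nuisance
parameterization in the Eyre-Walker style: it absorbs demography,
population structure and ascertainment effects that perturb all classes
alike, so B is identified from the *relative* class composition across
frequencies, not from the overall spectrum shape. Poisson (rather than
multinomial) cells keep the θ scales free and let strata of unequal size
be fitted with the same code path.

Assumptions worth stating: sites are exchangeable and unlinked within a
class; B is constant within a fitted dataset; the error process is
class-symmetric mirroring (appropriate for outgroup misassignment, not
for reference bias); ancestral states are hard assignments (sites below
the confidence threshold are dropped, not weighted).

## Maximum likelihood

Given (B, θ, e), the likelihood is maximized in r analytically: for
i ≥ 2 the optimal r_i equals the observed over modelled total at
frequency i (and r_i = 0 where nothing was observed). The numerical
search therefore runs over only seven parameters — B, log θ_WS/SW/N, and
logit-transformed e's — with bounded L-BFGS-B from 8 seeded starts (one
moment-based, the rest jittered; best log-likelihood wins, ties broken
toward smaller |B|). This profiling is exact joint maximization, not an
approximation. Profile-likelihood CIs for B re-optimize the six nuisance
parameters on a bracketing search and locate the χ²₁ deviance crossing
by root finding; an endpoint that never crosses within the B bounds
([−50, 50] by default) is reported at the bound.

Quadrature is fixed-order 256-node Gauss–Legendre on (0,1); the binomial
kernel regularizes the endpoint singularities of φ for 1 ≤ i ≤ n−1
(verified against a 10⁶-point trapezoid oracle to 1e−7). |B| < 1e−6 is
routed to the analytic neutral limit G_i(0) = 1/i.

Derived quantities: λ = (θ_SW/GC)/(θ_WS/(1−GC)) converts the fitted
influx scales to a per-site mutation-rate ratio given the base
composition of the analysed context; GC* = 1/(1+λe^{−B}) is the
stationary GC content under mutation–conversion balance; b = B/(3N_E)
and r = ρ/(3N_E) (4N_E for diploids) convert population-scaled
parameters to per-meiosis ones, with r per bp × 10⁸ = cM/Mb.

## Polarization

For an ingroup polymorphism {X, Y} with outgroup allele O, the two
scenarios are weighted by μ(anc→der) for the ingroup mutation and by
σ(anc→O) for any outgroup-lineage substitution needed to explain O
(σ-free when O equals the assumed ancestral allele). μ is estimated from
polymorphism counts per outgroup-base opportunity and σ from
ingroup/outgroup fixed differences per aligned base, in a single pass.
The larger-weight scenario is accepted when its posterior weight exceeds
a threshold (default 0.9); ties and zero-weight cases are unresolved
with reason codes. Note an asymmetry this creates under strong AT
mutation bias: when σ is large, the confidence of W-ancestral calls is
capped near μ_WS/(μ_WS + λ·μ_WS·σ), so a strict threshold preferentially
filters WS sites rather than mispolarizing them — the error/censoring
trade-off is controlled by the threshold, and the truth-comparison
harness measures the realized error per labelled class.

Flanking dinucleotide context (CpG/GpC creating/destroying) is taken
from the ingroup reference; adjacent polymorphisms are ignored — a
documented limitation. Internally all coordinates are 0-based half-open;
VCF/GFF3 stay 1-based with conversion at the I/O boundary only.

## Windowed statistics and comparisons

Windows are fixed and non-sliding, anchored at 0 per chromosome
(default 100 kb; a terminal partial window is kept if it spans at least
half the window). Annotation overlaps resolve by precedence
CDS > UTR > intron > intergenic, and unannotated bases are intergenic.
An element statistic is reported only when the element covers at least
200 bases in the window (absent, never zero). Regression p-values come
from the t distribution of the OLS slope with no multiple-testing
correction; bootstrap CIs are percentile intervals from 200 resamples,
and class comparisons are gene-weighted (one observation per gene).
The LMET/HMET split of methylated genes uses the proportion of CDS CpGs
methylated (controls for CpG availability) and cuts the ranked list in
half, so the class sizes differ by at most one with at-boundary ties
preferring HMET. Gene flanks are geometric (both sides pooled,
strand-ignored): 50 kb starting 10 kb out (near) and 100 kb starting
50 kb out (far), truncated at chromosome ends and excluding other
genes' CDS by default.

## The synthetic-data generator

Defaults emulate the study conditions of an African honeybee
resequencing panel: n = 60 haplotypes; element-specific composition
(CDS GC 0.39, introns 0.23, intergenic 0.31; CpG_O/E 1.04 coding, ~1.7
noncoding) produced by first-order Markov chains whose transition matrix
is calibrated by fixed-point iteration so the *stationary* GC and
CpG_O/E hit the targets; ~57 genes/Mb with planted LCpG/HCpG classes
(CDS CpG_O/E targets 0.6 vs 1.6); a lognormal piecewise-constant ρ map
(mean 390/kb, sd 167/kb, ~5 kb segments) with per-class CDS multipliers
(HCpG 3.37× by default, the within-CDS ratio the gene-class comparison
should recover); AT bias λ = 12; transition-specific conversion strength
B_ti = 6.47, B_tv = 0.03; outgroup branch 0.03 substitutions/site with a
95% coverage mask.

Derived-allele frequencies are drawn from φ(x; B) discretized on a
10⁴-point grid, then k ~ Binomial(n, x) with joint (x, k) rejection
until 0 < k < n. Expected class counts are the mutational influx
θ_class × eligible bases × the class's *relative mean sojourn*
Σ_iG_i(B)/Σ_iG_i(0) (and the observed Ti fraction is tilted by the same
factors): the number of segregating sites a mutation class contributes
is influx times mean sojourn time, and without this factor the fitted
θ ratio — hence λ — would be biased by construction (≈2.5× at B = 5.71).
At B = 0 the factor is 1, so neutral count ratios reduce to
λ × opportunity. Mispolarization pressure is mechanistic — the outgroup
consensus is the reference evolved along the branch (single hit per
site), so double hits genuinely mislead the parsimony stage — and the
truth table flags sites whose outgroup allele differs from the true
ancestor; a direct label-flip error mode is available through the
e parameters of the fast spectrum-level generator.

What the generator does **not** emulate: linkage (sites are independent,
so LD-based rate estimation itself cannot be tested, only consumed),
explicit demography (the spectra are stationary; distortion is exercised
through the r_i parameters, not through population history), sequencing
or genotyping error, and within-class variation in B. Passing tests
therefore demonstrate estimator correctness under the model's own
sampling assumptions, not robustness to everything real data does.

## Problem sizes and numerical conventions

The test suite and drivers run at desk scale by choice: 0.3–1 Mb
genomes, ~3×10⁴–10⁵ SNPs per run, 20-replicate recovery batches at
~3×10⁵ SNPs per spectrum, 200 bootstrap resamples, 8 (fits) or 4
(batch/binned fits) optimizer starts. Empirically these sizes give
profile-CI coverage of 20/20 at the strong-conversion parameter point
and ~1–10% relative error on λ. Statistics that cannot be computed are
NaN; empty strata raise; multi-allelic and indel VCF records are skipped
with counted diagnostics; all randomness flows through
`numpy.random.default_rng` seeded per run, and equal seeds give
byte-identical outputs.

## Known limitations

* The pooled fit on transition/transversion mixtures returns a
  compromise B with inflated error parameters (they absorb the
  low-frequency excess of the weakly-converted subclass); fit Ti and Tv
  separately when the bias is class-specific, as the drivers do.
* Near B = 0 the polarization-error parameters are weakly identified
  (mirroring is nearly symmetric there), so ê and λ̂ wobble more than B̂.
* Hard ancestral assignment discards the per-site confidence after
  thresholding; no soft-weighted spectrum is built.
* CpG context uses the reference flanks only and ignores neighbouring
  polymorphisms.
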