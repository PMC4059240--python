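# Methods

This note documents the models implemented in `codonsfs`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish about real data.

## Preference scores

Codon preference is estimated by factor analysis of per-gene codon usage.
Each gene that uses all 18 degenerate amino acids contributes a row of
within-amino-acid relative usage over the 59 degenerate codons (count of the
codon divided by the count of its amino acid). This input matrix — rather
than raw counts or RSCU — is used because it makes the two columns of every
twofold amino acid perfectly anticorrelated, so their loadings are forced to
equal magnitude and opposite sign, the symmetry seen in the bundled
*D. pseudoobscura* reference table (e.g. Lys ±0.700).

Extraction is the first principal component of the column-standardized
matrix; loadings are reported as the correlation of each codon's column with
the per-gene component scores, so they live in [−1, 1] like classic factor
loadings. PCA was chosen over iterated principal-axis factoring because it is
deterministic, dependency-light, and reproduces the published sign structure;
`infer_preference_table(method=...)` leaves room for alternatives. The factor
is polarized by two anchors that both measure uneven usage: gene scores must
correlate positively with the scaled chi-square Chi/L and negatively with
ENC. If the anchors disagree in sign the function raises with both
correlations rather than guessing. Columns with zero variance get loading 0
and are flagged unpreferred; a score of exactly 0 is "unpreferred" for the
F_op flag, but Δpref always uses the raw signed score.

Because the extraction and any rotation used for the published table are not
fully determined, the reference scores are a qualitative target (signs and
ordering), not a bit-exact one; the package therefore ships the published
table as a fixture (`load_reference_scores`) and uses it, not re-inferred
scores, as the default for downstream stages.

**ENC.** The class-homozygosity form ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6
is used with the *plain* within-amino-acid homozygosity F = Σp². The
bias-corrected estimator F̂ = (nΣp² − 1)/(n − 1) is the more common choice in
modern implementations, but the plain form is what makes perfectly even
usage give exactly 61 and single-codon usage exactly 20, which are the
boundary conditions the rest of the package assumes. Isoleucine is its own
threefold class. Amino acids absent from a gene are skipped and the class
average taken over the remainder; a class with no usable amino acid falls
back to its even-usage homozygosity.

## Site inclusion and polarization

A base in a non-reference strain is unresolved when phred consensus quality
< 30 or coverage < 15 (strict "below": 30/15 are kept); the reference strain
is exempt. A codon or intron site enters only if fully resolved in all k + 1
sequences (ingroup plus outgroup). Synonymous polymorphic sites are codons
where the ingroup segregates exactly two codons that are synonymous and
differ at one position; pairs differing at two or more positions are
excluded even when each change is synonymous, because the biallelic
single-position definition underlies Δpref and the pair classes. Parsimony
polarization requires the outgroup base at the varying position to match one
of the two alleles; unpolarizable and multiallelic columns go to a drop log
with reasons, never silently.

Synonymous site totals are fractional: each codon position contributes the
share of its three possible single-base changes that are synonymous (1.0 for
a fourfold third position, 1/3 for a twofold, with first-position
contributions for Leu/Arg). Divergence counts compare the reference strain
with the outgroup at fully resolved codons and count single-position
synonymous differences; multi-hit and nonsynonymous codon differences are
not counted. Intron sites count 1.0 each. Coordinates are 0-based half-open
internally, 1-based in the site table.

## SFS tests

The selection statistic is T = Σ d·Δpref over synonymous biallelic sites.
Significance is the fraction of random permutations of d against Δpref with
T_perm strictly greater than T_obs (one-tailed); a reported p of 0 means no
exceedance, i.e. p < 1/replicates. The default is 100,000 permutations in
the CLI and acceptance-scale runs; tests use fewer where the binomial error
is accounted for.

The ASM-corrected variant redraws each site's polarity before permuting:
a site keeps its parsimony assignment with probability odds/(1 + odds),
where the posterior odds are ((k−d)/d)·(1/b) and b = D̂ − ((k−1)/k)·θ̂, and
otherwise flips (d → k−d, Δpref → −Δpref). How to aggregate over polarity
draws is not pinned down by the original description; the implementation
averages the permutation p-value over `assignment_draws` independent draws
(default 20), each with its own permutation null, and documents the choice —
a single draw is recovered by `assignment_draws=1`. Per-class (e.g.
per-amino-acid) θ̂ and D̂ can be supplied.

Shift tests are one-tailed Student's t and Mann-Whitney U (normal
approximation with tie and continuity corrections; exact enumeration is used
as an oracle in tests at tiny n). Slope contrasts across recombination
classes fit per-group OLS slopes of d on Δpref, pool residual variance, and
refer pairwise differences to the studentized-range distribution
(Tukey-Kramer); one-tailed p-values halve the two-sided tail. The two-way
ANOVA (site type × direction) uses sequential Type-I sums of squares with
main effects before the interaction, matching the convention of the R
environment this analysis style comes from; unbalanced designs are allowed
but empty cells raise. G-tests are plain G = 2ΣO·ln(O/E) without
small-sample correction.

## Null models

The neutral spectrum is p_d ∝ 1/d (constant-size Wright-Fisher), giving
mean d = (k−1)/a_k = 3.414 and singleton share 1/a_k = 34.1% at k = 11, and
4.374 for the mean over d = 2..k−2 (both d = 1 and d = k−1 count as
singletons).

**ASM forward model.** The probability that the outgroup lineage carries the
derived allele — flipping apparent polarity — is taken as b/(1 + b) with
b = D̂ − ((k−1)/k)·θ̂, the odds of one versus zero substitutions on the
outgroup branch beyond the ingroup coalescent. The presented spectrum is
presented_d = p_d(1−f) + p_{k−d}·f. This is the reading that reproduces the
published worked values (equal-tail divergence 0.0424 at θ = 0.0222, 4.1%
in each tail class, tail ratio 1.12 at D = 0.0763); the prose description
"probability 1/(LR+1)" conflates the likelihood ratio with the posterior
odds and does not reproduce them. The equal-tail solve is closed-form
(b = (1/(k−2) − 1/(k−1))/(1 − 1/2)) and is cross-checked against bisection
on the forward model in the tests.

**Sequencing error.** Errors are independent per base per sequence at rate
ε and all produce the same state: at a segregating site, the derived state
(errors on derived copies are no-ops); at an invariant site, one designated
alternative. Observed counts are d + Binomial(k−d, ε); an observed count of
k presents as invariant. Mixing the true class frequencies (invariant
1 − θa_k, class d at θ/d) through this matrix yields the apparent-singleton
share, which is solved for ε by bracketed Brent iteration on the rising
branch (the share peaks near ε ≈ 2% and falls; the smaller root is
returned; tolerance 1e−10). This model reproduces the published 98.91% /
1.09% / 99.00% / 0.99% conversion rates at ε = 0.1% and the ≈0.33% rate
implied by a 55.1% singleton share. The forward evaluation at ε = 0.1%
gives ≈42.7% apparent singletons; the figure printed in the source for that
case (42.3%) is not exactly recovered by any literal reading of the stated
model we found, so it is deliberately not asserted anywhere.

## Synthetic data

The generator's defaults are the study conditions: k = 11, θ_syn = 0.0222
and D_syn = 0.0763 per synonymous site, θ_intron = 0.0085 and
D_intron = 0.0297, sequencing error off, ASM on. Genes are random coding
sequences (start codon, one GT..AG intron, stop codon) whose within-amino-
acid codon choice is exponentially tilted toward the bundled preference
scores with a per-gene bias drawn from U(0, 2), so genes span a realistic
range of ENC/Chi-L and the factor analysis has structure to recover.

Selection enters through the derived-count sampler: a site with preference
change Δpref gets γ_site = γ·Δpref and d is drawn from
P(d) ∝ C(k,d)∫ x^{d−1}(1−x)^{k−d−1}·(1−e^{−2γ(1−x)})/(1−e^{−2γ}) dx,
the stationary sampling distribution of a semidominant selected allele
(numerical quadrature, cached on a 0.01 grid of γ; the γ = 0 limit is
exactly 1/d). γ = 1 is the planted-selection condition used in the
acceptance properties and γ = 0 the neutral control. Per-codon polymorphism
probability is θ_syn·a_k times the codon's fractional synonymous sites
(intron sites analogously), outgroup substitutions are placed at
monomorphic positions at the divergence rate, and ASM is planted by putting
the derived allele on the outgroup with probability b/(1+b). An optional
"singleton inflation" multiplier reweights the d = 1 class to mimic the
demographic singleton excess seen in real spectra; it is phenomenological
and off by default — no growth model is fitted because none is fitted in
the source analysis. A synthetic two-testcross recombination map draws
lognormal segment rates observed twice with independent noise, with an
optional θ(rate) coupling rising linearly to saturation at 2 cM/Mb.

What the generator does *not* emulate: linkage (sites are independent given
their segment), gene conversion, inversion polymorphism, base-compositional
mutation bias, and realistic gene structure (one intron, uniform amino-acid
usage). Passing tests therefore establish that the pipeline's inference is
correct under its own assumptions — filters, polarization, test calibration,
parameter recovery — not that those assumptions hold in any particular
genome.

## Problem sizes and numerical choices

The test suite runs the full parameter-recovery property at 560 genes × 300
codons (≈6,000 synonymous sites) with 20,000 permutations, three seeds for
the planted-selection condition and 200 fast direct-sampler replicates for
the type-I calibration; these sizes give three-standard-error margins on
every Monte Carlo assertion while keeping a full run around half a minute.
Permutation p-values use strict exceedance; random number streams all
derive from explicit seeds (numpy Generator); solvers use bracketed Brent
iteration with tolerance 1e−10 on the root variable. Rate classes are
upper-closed ((0.00–0.25], (0.25–0.50], …, >6.00) with the first class
closed at 0, matching the conventional class labels; physical segment
intervals are half-open (start, end] to agree.

## Known limitations

* The preference factor analysis is PCA-based; oblique or varimax-rotated
  principal-axis variants could shift weak loadings (|score| ≲ 0.1) across
  zero, which is why near-zero codons are not sign-asserted in tests.
* The ASM model treats the flip probability as site-independent given the
  class (θ̂, D̂); it ignores the d-dependence of the true flip risk that the
  posterior-odds correction itself models, which is the standard
  forward/backward asymmetry of this approximation.
* Divergence counting ignores multiple hits; at D ≈ 0.08 per site this
  undercounts by a few percent, consistently for all classes.
* The error model excludes three-state observations by construction;
  real error processes can create them (they are dropped as multiallelic by
  the caller, so the analysis path is consistent).
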