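# Methods

## Design and model

The package analyzes a matched case-control design: each affected animal is
paired with one unaffected pen mate, and the pair identifier is carried in
the ped file's family-ID column. Inference is conditional on the pair.
For a given SNP, risk allele and inheritance model, each fully-typed pair
falls into one of four cells by the (case, control) risk-genotype pattern;
only the discordant cells *b* (case-only carrier) and *c* (control-only
carrier) carry information. Under the null of no association, conditional
on *t = b + c*, *b* ~ Binomial(*t*, ½).

Six scenarios are scored per SNP: {a1, a2} × {1-copy, 1-or-2-copies,
2-copies}, where a1 is the most frequent allele in the pooled sample
(ties broken alphabetically for reproducibility). The 1-or-2-copy scenario
of one allele is the exact complement of the 2-copy scenario of the other
— its quadrants are the same table with b and c swapped — so the six
scenarios contain three distinct tests per SNP, each reported in both
orientations (an enriched orientation with OR > 1 and a "protective" one
with OR < 1).

### Test statistics

The primary p-value is the binomial **mid-p**, `2(F(k;t,½) − ½f(k;t,½))`
with *k = min(b,c)*, capped at 1. The cap matters near *b = c*, where the
doubled one-tail sum exceeds 1. The two-sided **exact conditional p**,
`min(1, 2F(k;t,½))`, is always emitted alongside, because the two
conventions genuinely differ on a lattice (for a 28/1 split: mid-p
5.8×10⁻⁸ versus exact 1.1×10⁻⁷) and downstream users need to know which
they are quoting. Asymptotic χ² statistics are provided with and without
the continuity correction; the corrected form is floored at 0 when
|b−c| < 1. The Wald CI for OR = b/c uses SE = √(1/b + 1/c) on the log
scale and is reported as undefined (no Haldane correction) when either
quadrant is zero — a deliberate choice to keep the estimate interpretable
as the raw discordant ratio. Cohen's g = max(b,c)/t − ½ is the effect
size; the per-marker polygenic-risk value is g × (t / n_pairs_used), where
n_pairs_used excludes pairs with a missing member at that SNP (this
exclusion is what makes printed informative-pair proportions like 55/101
rather than 55/102 come out right).

One known discrepancy is documented rather than forced: for a 44/11 split
the adopted mid-p formula gives −log₁₀ p = 5.27, while the corresponding
published table prints 5.18; no parenthesization of the formula reproduces
5.18, so the formula validated against the other rows is kept.

X-chromosome genotypes are treated as ordinary diploid calls in all
scenarios; bead-array exports code males as homozygous diploid and no
hemizygote special-casing is attempted.

## Quality control

Pre-association filters mirror the standard PLINK options, applied to the
pooled sample of 2N animals: MAF ≥ 0.05, per-SNP missingness ≤ 0.05, and a
Hardy-Weinberg exact test with mid-p adjustment at 10⁻⁴. The HWE test
conditions on the allele counts and enumerates all heterozygote counts of
matching parity; mid-p = P(configurations strictly less probable) +
½ P(equally probable, observed included). Degenerate tables with a single
achievable configuration return 1 (nothing can be rejected). Membership in
the kept set is the conjunction of the three filters; the removal report
attributes each dropped SNP to the first failing filter in the order
MAF → missingness → HWE, so the order affects accounting only.
Post-association removals drop SNPs on chromosome codes 0 (unmapped),
31 (Y) and 32 (MT), and SNPs with b + c = 0 in every scenario.

## Multiplicity on a discrete lattice

Bonferroni: α/m over the filtered SNP count. Storey q-values are computed
as π₀·m·p/rank with a top-down cumulative minimum; with π₀ = 1 they equal
Benjamini-Hochberg adjusted p-values exactly (cross-checked in tests
against statsmodels). π₀ is estimated on a λ grid of 0:0.01:0.95 (the
default of the MATLAB `mafdr` implementation this emulates) either by the
Storey-Tibshirani bootstrap (λ minimizing bootstrap MSE against the grid
minimum, 100 resamples, seeded) or by a cubic polynomial fit of π₀(λ)
evaluated at the grid maximum. McNemar p-values pile up mass at and near 1
(b ≈ c splits), which inflates π₀(λ) as λ → 1; the polynomial estimator
chases that rise while the bootstrap favors smaller λ, so bootstrap π₀ ≤
polynomial π₀ on such data — the tests assert this qualitative ordering on
a lattice-heavy simulation rather than any specific value. The q-value
step consumes, per model, each SNP's better allele orientation; taking
that minimum makes small p-values about twice as frequent as a fixed
orientation would, which depresses π₀ on null data. This is a property of
the best-orientation convention, not a defect of the estimator.

Q-Q expectations cannot use the uniform null: each SNP's p-value lives on
the lattice determined by its own t. The expected distribution pools, over
all scanned SNPs, every achievable p-value weighted by its null
probability f(k; t, ½), and reads off deterministic quantiles at the
plotting positions (i−½)/n. The lattice is generated for the same p-value
variant as the observed statistic (mid-p by default). By enumeration the
exact p is valid on its lattice (P(p ≤ α) ≤ α at every achievable α);
the mid-p can exceed α slightly by construction, which is why type-I-error
assertions in the tests use the exact variant.

## Population substructure

Pairwise IBS distance = 1 − (shared alleles)/(2 × co-called SNPs),
computed over autosomal SNPs only and over pairwise-complete calls
(PLINK's convention). Classical (Torgerson) MDS double-centers the squared
distance matrix and eigendecomposes; coordinates are ordered by
eigenvalue, truncated to the positive spectrum, and each axis's sign is
fixed so its largest-magnitude loading is positive (eigenvectors are
otherwise sign-ambiguous and plots would not reproduce). The
implementation is cross-checked in tests against scikit-bio's PCoA.

## Power

Simulation is the reference: per replicate t ~ Binomial(n, ψ) and
b ~ Binomial(t, θ/(1+θ)), rejecting when the chosen test (exact, mid-p, or
corrected χ²) gives p ≤ α. Default 20,000 replicates put the Monte-Carlo
SE near 0.0015 at power 0.95. The closed-form cross-check is a two-sided
normal approximation conditional on the expected discordant count
t = nψ, with a continuity correction of half a lattice cell:
Φ((δ√t − z/2 − 1/(2√t))/σ) + Φ((−δ√t − z/2 − 1/(2√t))/σ), δ = |p₁ − ½|,
σ = √(p₁(1−p₁)). The correction term mirrors the exact test's
discreteness; without it the approximation overshoots simulation by up to
~0.07 in the mid-power range, with it the two agree within 0.03 on the
tested grid. The published operating points (95% power at OR 8.51 with 25%
discordant pairs and at OR 2.94 with 70%, α = 0.01, 102 pairs) were
produced by commercial software whose exact formula variant is not public;
they are therefore checked as an interval [0.90, 0.99] around the
simulated value, not as an equality.

## Synthetic data

The generator's defaults are the study's conditions: 102 pairs, phenotype
codes 1/2, 29 autosomes plus X in rotation, MAF drawn uniformly from
[0.05, 0.5], 1% missing calls, within-pair correlation 0.05–0.1 in the
fixtures (shared ranch origin induces mild within-pair relatedness; the
study design makes no stronger claim, so a small positive value is used).

Null SNPs: each pair draws a latent frequency q ~ Beta with mean p and
variance ρp(1−p) — the Balding-Nichols construction — then both members
sample genotypes from HWE at q; any two allele draws within a pair then
have correlation exactly ρ, and ρ = 0 degenerates to independent HWE
sampling. Risk loci are simulated exposure-first: the control member's
exposure prevalence e₀ is its HWE genotype-class probability under the
chosen model, the case member's exposure odds are θ times the control's,
and the pair's 2×2 cell is drawn assuming member independence given the
effect — which makes the discordant-cell ratio b/c estimate θ exactly,
turning parameter recovery into a sharp test. Genotypes are then sampled
from the HWE distribution conditioned on the drawn exposure status, which
keeps the marginal allele frequency near target. Configurations whose
exposure prevalence collapses to 0 or 1 (no discordant pairs possible) are
rejected at validation.

What the generator does **not** emulate: linkage disequilibrium (every SNP
is independent), pedigree structure beyond the single within-pair
correlation knob, genotyping batch effects, and allele-frequency
differences between cases and controls beyond the specified risk loci.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to LD-induced dependence
among tests or cryptic relatedness in real arrays.

Deterministic fixtures (`fixture_from_quadrants`, `fixture_two_locus`)
construct explicit pair genotypes realizing exact quadrant counts; these
are how printed table rows are reproduced verbatim without the original
600 MB genotype files.

## Problem sizes in the tests

The suite exercises the pipeline at the study's pair count (102) with
10,000 SNPs — enough for the discrete-lattice effects that motivate the
method to be visible — and uses 500 single-locus replicates for parameter
recovery and 8 seeded replicates for spiked-locus retrieval. All
randomness flows from named seeds; identical configuration and seed
reproduce every artifact byte-for-byte.

## Interfaces

All tabular outputs are TSV with fixed headers; filter reports are JSON;
plots are emitted as coordinate data files (Manhattan x = position plus
cumulative terminal positions of preceding chromosomes, order 1..29 then
X), with image rendering left to the user. The `penmate` CLI wraps the
library thinly: `simulate`, `all`, `power`, `risk`.
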