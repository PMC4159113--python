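# Methods

## Data model

Expression data are dense gene × sample grids of log2 values
(`ExpressionMatrix`), with per-sample metadata (genotype, treatment,
clinical fields) in a companion table. Values are expected on the log2
scale already; `log2_transform(mat, pseudocount)` is available when they
are not, and missing values are an error rather than being imputed — the
downstream set logic is only unambiguous on complete data. When real
array data are consumed, probe-to-gene collapse is the caller's
responsibility; the convention we recommend is keeping the
maximum-mean probe per gene.

`quantile_normalize` maps every sample onto the common mean-reference
distribution: the reference is the per-rank mean of the column-sorted
values, assigned back in each column's own rank order. Tied values
receive the mean of the reference values across their tie span, which
makes the output invariant to within-tie order. On tie-free data the
transform is exactly idempotent; with ties, re-application can shift
tied entries by a sub-noise amount because the first pass makes column
multisets unequal. At least two samples are required.

## Differential calling and set constructions

Calling is deliberately threshold-only, with no variance filter or
moderated statistic: a gene is up-regulated when the difference of group
means of log2 expression strictly exceeds log2(fold threshold)
(default 2-fold, i.e. log2 difference > 1). Replicates enter only
through the mean. "Differentially expressed" between two genotypes means
the union of up- and down-calls at the same threshold.

The preactivated set is the exact intersection of (a) the set induced by
oxidant in differentiated cells and (b) the set already up-regulated in
de-differentiated cells at baseline. The uniquely-induced set removes
from (a)∩(b) the genes the oxidant also induces in de-differentiated
cells; it requires the preactivated set to be contained in (a), which
the pipeline guarantees by construction.

## Hypergeometric overlap statistics

For sets of sizes K and n with observed overlap k in a universe of N
measured genes, the enrichment statistic is the upper tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n). Terms are computed as
log-gamma binomial coefficients and combined with log-sum-exp, which
keeps deep tails (p ≪ 1e-50) accurate to ~1e-13 absolute; a vectorized
whole-tail variant (`hypergeom_tail_upper_all`) shares the same term
computation. Only the enrichment (upper) tail is provided — depletion
testing is out of scope — and p-values are reported raw; a
Benjamini–Hochberg helper exists but is not applied by default.

The universe is an explicit, configurable input (default: all genes
measured in the matrix at hand). This matters: the same 7-of-54 overlap
against a 1,013-gene target list is p ≈ 6e-5 in a ~55k-feature universe
but p ≈ 0.02 at N = 20,000. Published overlap p-values that do not state
their universe cannot be reproduced exactly, only bracketed.

## Signature scoring and stratification

A signature is the top-N genes (default 500) by log2 fold change in a
derivation contrast — for a pathway-inhibition signature, the most
down-regulated genes under the inhibitor, so a high score tracks high
pathway activity. Ties are broken by gene id so derivation is
deterministic.

A sample's score is the unweighted sum of its log2 expression over the
signature genes present in the cohort. No per-gene standardization is
applied; the score is therefore comparable only within a cohort, which
is also why stratification is done per cohort. Signature genes absent
from a cohort are dropped and the retained fraction is reported as
coverage, with a warning below 0.8.

Stratification labels the floor(fraction·n) highest-scoring samples
"high" and the same number lowest "low" (default fraction 0.15, applied
within each cohort independently); boundary ties are resolved by sample
id. Score ties therefore never change stratum sizes.

## Monte Carlo correlation null

Association between two signatures is measured by Spearman's ρ between
their score vectors (midranks for ties; delegated to scipy). The null
distribution resamples gene sets: `reps` sets of the same effective size
as signature A are drawn uniformly without replacement from the cohort's
measured genes, scored identically, and correlated with the fixed
signature-B scores. The two-sided empirical p uses the add-one rule,
p = (1 + #{|ρ_null| ≥ |ρ_obs|}) / (reps + 1), so p is never 0 and its
minimum is 1/(reps+1). Gene-set resampling (rather than sample-label
permutation) preserves the score's gene count and the cohort's
inter-sample structure, which is the appropriate null for "is this
specific gene membership informative". A seed is mandatory for every
stochastic entry point and the result is bit-reproducible given the
seed.

## Survival and response

Kaplan-Meier estimation and the Mantel-Cox (log-rank) test are delegated
to lifelines behind this package's record types: at tied times events
are handled before censorings (the standard convention), the log-rank
statistic is the 1-df chi-square form without continuity correction, and
curves are reported as ordered (time, survival) step pairs beginning at
(0, 1). Responder fraction is (complete + partial) / stratum size over
the closed category vocabulary {complete, partial, stable_progressive}.
Endpoint semantics (overall vs metastasis-free survival) are carried
only as a free-text label; they do not change the computation.

## Synthetic data generators

The cell-line generator plants, in a 10,000-gene universe, the exact
set structure the analysis chain is designed to detect, with default
sizes matching the experimental design it emulates: 181 and 170
oxidant-induced genes per genotype sharing a 44-gene core; 54
preactivated genes, 38 of them uniquely induced in the differentiated
genotype (so 16 of the common core are preactivated); 847 genes up and
847 down at baseline in the de-differentiated genotype (1,694
differential — the published total; its up/down split is not published,
and an even split is this package's choice); a 500-gene
inhibitor-responsive program; and a 1,013-gene reference target list
with 142 members in the baseline-up program, 7 of those preactivated and
58 inhibitor-responsive. Baseline log2 means are N(7, 1.5²) per gene,
effects are additive shifts of δ = 1.5 log2 units (comfortably above the
1.0 calling threshold, so the zero-noise design is exactly recoverable),
and noise is i.i.d. N(0, 0.3²) per measurement with 3 replicates per
arm. The design has 2 genotypes × 3 treatments (vehicle / oxidant /
inhibitor): the inhibitor arm is required for signature derivation.
Truth sets are returned as `GeneSet`s and written as GMT by the CLI, so
tests never reach into generator internals.

The cohort generator draws a latent activity a_i ~ N(0,1) per sample;
signature genes get expression μ_g + β·a_i + ε (β = 0.8, ε ~ N(0, 0.5²)),
other genes μ_g + ε. Survival is exponential with rate
λ0·exp(γ·a_i) (λ0 = 0.05 per time unit, γ = ln 2.5 per activity SD —
i.e. a planted hazard ratio of 2.5), administratively censored at C = 60;
response is Bernoulli with P(responder) = logistic(α − κ·a_i)
(α = 1, κ = 1.5), responders split evenly between complete and partial.
Defaults give a 200-sample, 5,000-gene cohort with a 500-gene signature.

What the generators deliberately do not emulate: probe-level array
artifacts, batch or platform effects, correlated gene-gene noise,
non-proportional hazards, or competing risks. Passing tests on this
synthetic data therefore validate the pipeline's logic and calibration,
not its robustness to those real-data pathologies.

## Verification and calibration

- Hypergeometric tails are checked against an exact integer-arithmetic
  enumeration for every parameterization with N ≤ 60 (agreement ≤ 1e-12)
  and against scipy's survival function in the deep tail.
- Spearman ρ is checked against an independent midrank-then-Pearson
  computation on 1,000 random tied/untied vectors; KM and log-rank
  against hand-computed product-limit and O/E/V tables.
- The Monte Carlo p-value is verified uniform under the null
  (500 independent runs at reps = 1000 on the default cohort,
  Kolmogorov-Smirnov test); log-rank type-I error is verified at
  0.05 ± 0.02 over 1,000 null simulations (Exponential(1) arms, n = 50
  each, ~20% censoring).
- Recovery: the zero-noise cell-line experiment is recovered exactly
  (all planted counts); default-noise recovery and the end-to-end
  cohort log-rank power at the planted hazard ratio of 2.5 were
  calibrated once at fixed seeds and frozen as regression values
  (176/181 induced genes recovered with one false positive;
  100 of 100 power simulations rejected, frozen bound 95 of 100).

Problem sizes used in the verification suite are the generators'
defaults except where a property is size-independent, in which case
smaller instances are used.

## Known limitations

- Threshold-only differential calling has no error control; it is a
  faithful reimplementation of a fold-change screen, not a recommended
  general-purpose DE method.
- Summed scores are cohort-relative; cross-cohort score comparisons are
  meaningless without a shared normalization.
- The Monte Carlo null conditions on the observed cohort; it does not
  model sampling variability of the cohort itself.
- Quantile normalization is not idempotent in the presence of ties
  (sub-tolerance drift; see above).
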