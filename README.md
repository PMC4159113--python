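# preactivation

Analysis pipeline for a recurring question in tumor biology: do
de-differentiated (EMT/mesenchymal-like, stem-like) cells *pre-activate*
oxidative-stress response genes — expressing, without any stress, the
genes that differentiated cells only induce after oxidant exposure — and
does the pathway driving that program (PERK–Nrf2 signaling) mark patients
with worse therapy response and survival?

The package implements the complete computational chain for answering it
from bulk expression data, for computational biologists working with
genotype × treatment expression designs and clinical cohorts:

1. **Differential calling** — threshold-based: gene g is up-regulated in a
   contrast when the difference of mean log2 expression exceeds
   log2(fold threshold), strictly (default 2-fold).
2. **Set constructions** — the oxidant-induced set per genotype, their
   common core, the *preactivated* set (induced by oxidant in
   differentiated cells ∩ already up at baseline in de-differentiated
   cells), and the uniquely-induced remainder.
3. **Hypergeometric enrichment** — for an overlap of k genes between sets
   of sizes K and n in a universe of N measured genes,
   P(X ≥ k), X ~ Hypergeom(N, K, n), computed in log space from log-gamma
   binomial coefficients so deep tails (p < 1e-50) are exact to ~1e-13.
4. **Signature scoring** — a pathway signature (e.g. the top 500 genes
   down-regulated by PERK inhibition) scores each patient sample by the
   plain sum of its log2 expression over the signature genes; cohorts are
   stratified into high / low tails (default top/bottom 15%).
5. **Monte Carlo correlation null** — signature–signature Spearman ρ is
   tested against reps size-matched random gene sets drawn from the
   cohort's measured genes, with the add-one empirical p
   (1 + #{|ρ_null| ≥ |ρ_obs|}) / (reps + 1).
6. **Outcome comparison** — Kaplan-Meier curves, the Mantel-Cox (log-rank)
   test between high and low strata, and responder fractions
   (complete + partial response).
7. **Synthetic data** — generators for the cell-line design (planted
   induced / preactivated / differential programs with exact truth sets)
   and for patient cohorts (a latent pathway activity that drives
   signature-gene expression, an exponential survival hazard, and a
   logistic response model), so the entire pipeline is testable with
   known ground truth.

## Worked example

```python
from preactivation import (
    CellLineSimParams, simulate_cellline_experiment, run_preactivation,
    hypergeom_tail_upper,
)

mat, truth = simulate_cellline_experiment(CellLineSimParams(noise_sd=0.0))
report = run_preactivation(mat)
print(report["counts"])
print(f'{report["common_induced_overlap"]["p_upper"]:.3g}')
```

prints

```
{'induced_differentiated': 181, 'induced_dedifferentiated': 170,
 'common_induced': 44, 'preactivated': 54, 'uniquely_induced': 38,
 'dediff_up': 847, 'dediff_down': 847, 'differential': 1694}
1.65e-39
```

Reading: in the noise-free simulated experiment, oxidant treatment
induces 181 genes in differentiated and 170 in de-differentiated cells;
44 are shared (an overlap far beyond chance in the 10,000-gene simulated
universe — p ≈ 1.6e-39); 54 of the 181 are already up-regulated in
de-differentiated cells without treatment (the preactivated program), and
38 of those are induced *only* in differentiated cells. At published
scale, the same statistic for 44 shared genes between 181- and 170-gene
sets in a 20,000-gene universe is

```python
>>> hypergeom_tail_upper(44, 181, 170, 20000)
2.1243235486211384e-52
```

The same workflows are available from the shell:

```sh
preact simulate cellline --seed 1 --out sim/
preact preactivation --expr sim/expression.tsv --meta sim/metadata.tsv --out analysis/
preact simulate cohort --seed 2 --out cohort/
preact cohort --expr cohort/expression.tsv --meta cohort/clinical.tsv \
    --gmt cohort/true_signature.gmt --seed 3 --out cohort_analysis/
```

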