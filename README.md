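# tdfe — tensor-decomposition unsupervised feature extraction for dose-response screens

`tdfe` screens large compound-perturbation expression experiments for
dose-dependent activity and infers drug target proteins, without training
labels. The input is a complete three-mode tensor *x<sub>ijℓ</sub>* of
expression values measured at dose *i* (of D, typically six) for compound *j*
(of J, hundreds) and gene *ℓ* (of L, a fixed landmark panel), built per cell
line from a long-format measurement table. It is aimed at computational
biologists working with L1000-style dose-titration screens who want an
unsupervised alternative to per-pair correlation testing — which, with only
six dose points, needs |r| ≥ 0.9996 to survive multiple-testing correction at
α = 10⁻⁷ and is therefore hopeless.

## Method

1. **Decomposition.** Higher-order SVD:
   *x<sub>ijℓ</sub>* = Σ G<sub>k₁k₂k₃</sub> · x<sub>k₁i</sub> · x<sub>k₂j</sub> · x<sub>k₃ℓ</sub>,
   where each factor matrix holds the left singular vectors of the matching
   mode unfolding and G is the all-orthogonal core tensor.
2. **Dose component.** The dose-mode component most correlated with the dose
   gradient (empirically the second, almost linear in dose) is identified as
   the dose-dependence component k₁\*.
3. **Truncation.** The compound and gene modes are truncated at the smallest
   K (default 6, escalating to 8) whose leading (D, K, K) core block carries
   ≥ 95% of the tensor energy. A χ² screen of the core slice
   (G<sub>k₁\*k₂k₃</sub>/σ<sub>G</sub>)² is reported as a diagnostic.
4. **Feature extraction.** Compounds are scored by
   S<sub>j</sub> = Σ<sub>k₂≤K</sub> (x<sub>k₂j</sub>/σ<sub>k₂</sub>)²
   against a χ²(K) null (genes likewise on the gene mode), P-values are
   Benjamini–Hochberg adjusted, and items with adjusted P < 0.01 become the
   *inferred compounds* and *inferred genes*.
5. **Target inference.** The inferred genes are enriched (one-sided Fisher
   exact test, BH across sets) against a gene-set library of single-gene
   perturbation signatures or hub-protein interactors; set names passing
   adjusted P < 0.01 are the *predicted targets*. Predictions can be
   intersected across cell lines — the expected random C-way overlap is
   N·(m/N)<sup>C</sup> — and validated against known drug-target references by
   a two-sided Fisher test over a 20,000-gene background.

## Worked example

```python
import tdfe

# synthetic screen: 6 doses x 100 compounds x 500 genes, 10 active compounds
# perturbing 50 signature genes linearly in dose (effect 2, noise 1)
tensor, truth = tdfe.simulate_tensor(seed=0)
results = tdfe.DoseResponseScreen(tensor).fit()
print(results.summary())
```

```
Dose-response tensor screen
============================================================
tensor shape (dose, compound, gene): (6, 100, 500)
dose levels: 0.1, 0.251189, 0.630957, 1.58489, 3.98107, 10
dose component k1* = 2, |r| = 0.9989 vs index
truncation K2 = 8, K3 = 8 (cumulative contribution 0.514)
core couplings significant at adj. P < 0.01: 32
inferred compounds (adj. P < 0.01): 100 / 100
inferred genes    (adj. P < 0.01): 0 / 500
```

The dose ramp lands in dose-mode component 2 with |r| ≈ 1, exactly the
geometry the method expects. The compound and gene counts illustrate the two
power regimes discussed in `docs/methods.md`: the shared gene baseline makes
the first compound component nearly constant, which the uncentred χ²
statistic flags wholesale, while at this panel size (500 genes, 50 active)
gene loadings cannot clear the BH 0.01 bar. Enrichment of the planted
signature genes against a matched library recovers the planted perturbation
sets:

```python
library = tdfe.simulate_library(truth, seed=1)
pred = tdfe.predict_targets(truth.active_genes, library)
print(pred.targets)          # ['SIGSET_001', ..., 'SIGSET_005'], no noise sets
```

Analytic utilities reproduce the screen-design numbers: a 13-way random
intersection of 600-target predictions from a 1595-name library has expected
size `tdfe.expected_common_overlap(1595, 600, 13)` ≈ 4.8×10⁻³ (essentially
zero, so a large observed common-target set is not chance), and
`tdfe.pcc_significance_threshold(6, 1e-7, "one")` = 0.99963.

A command-line interface mirrors the library
(`tdfe simulate | build-tensor | decompose | select | enrich | validate | run | analytics`);
`tdfe run --expression expr.tsv --library sets.gmt --cell-line A375 --out out/`
writes TSV result tables and a JSON run summary.

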