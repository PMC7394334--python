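# Methods

## Model and procedure

The screen treats one cell line's measurements as a complete three-mode
tensor x[i, j, ℓ] (dose level i = 1…D, compound j = 1…J, gene ℓ = 1…L).
Replicate measurements at the same (compound, dose, gene) are averaged
arithmetically when the tensor is built; any compound lacking a measurement
for some (dose, gene) cell is dropped entirely, because the decomposition
admits no missing values. No centring or scaling is applied by default — the
decomposition runs on the averaged raw tensor (a `gene_center` flag removes
per-gene means for users who want the baseline component suppressed).

**HOSVD.** Each factor matrix is the full set of left singular vectors of the
corresponding mode unfolding (economy size: per-mode component count =
min(mode dimension, product of the other dimensions)); the core is the tensor
contracted with all three factor transposes. With all components retained the
reconstruction is exact, the factor rows are orthonormal, the core is
all-orthogonal, and squared core entries partition the total energy. SVD sign
ambiguity is removed by orienting every component so its largest-magnitude
loading is positive; all downstream statistics are squares of loadings and
therefore sign-invariant regardless.

**Dose component.** Each dose-mode component is correlated (Pearson) against
a dose covariate — the dose index 1…D by default, log₁₀ dose optionally; the
doses in these screens are near-geometric, so the index is the natural linear
scale. The component with the largest |r| is taken as the dose-dependence
component k₁\*; in practice this is component 2, component 1 being the
dose-invariant baseline. An override pins k₁ when the user prefers the
conventional choice a priori. Components with numerically zero singular value
or zero loading variance are skipped; if none remains (e.g. a constant
tensor) the input is reported as degenerate.

**Core screen (diagnostic).** Entries of the slice G[k₁\*, :, :] are scored
as (G/σ_G)² with σ_G the sample standard deviation (n−1 denominator) of the
slice, given upper-tail χ²(1) P-values, and BH-adjusted. This reproduces the
published screening statistic, but it typically flags on the order of a
thousand (k₂, k₃) couplings — far too many to define a truncation — so it is
reported as a table only.

**Truncation.** K2 = K3 = the smallest K in [6, 8] at which the leading
(D, K, K) core block carries ≥ 95% of the total energy, falling back to the
cap with a warning when the spectrum is too flat (noise-dominated tensors).
The default band starts at 6 because with six dose levels the first six
compound/gene components span everything the dose mode can couple to in
practice; the cap of 8 accommodates cell lines whose seventh/eighth
components still carry non-negligible energy. An explicit override reproduces
any fixed choice exactly. K2 and K3 are tied to one K by default (separate
values are accepted) since the truncations play symmetric roles.

**Feature extraction.** Compound j is scored by
S_j = Σ_{k₂≤K2} (x[k₂, j]/σ_{k₂})², where σ_{k₂} is the sample standard
deviation of component k₂'s loadings across compounds; genes are scored the
same way on the gene mode. S is referred to the upper tail of χ² with K
degrees of freedom, BH-adjusted, and items with adjusted P < 0.01 are the
inferred compounds/genes. Two fidelity choices are deliberate and load-bearing:
the standard deviation is the centred sample estimate, but the statistic
itself does **not** subtract the component mean — the published formulas
divide by σ only. A threshold of exactly 1 is treated as "select everything"
(adjusted P is capped at 1, so a strict inequality would otherwise exclude
maximally null items).

**Target inference.** The inferred genes are tested per library set with the
one-sided (enrichment-direction) Fisher exact test on the 2×2 membership
table, BH-adjusted across sets; set names under adjusted P < 0.01 are the
predicted targets (the set name — the perturbed gene or hub protein — not the
members, is the prediction). The background defaults to the union of library
and query genes and can be pinned (e.g. 20,000). Cross-cell-line predictions
are combined by a presence count ("predicted in ≥ C lists"); the expected
random C-way intersection is N·(m/N)^C, each of N names surviving C
independent m-out-of-N draws with probability (m/N)^C.

**Validation.** Predicted-vs-known target overlap uses the two-sided Fisher
test (the default of the statistical environments these comparisons are
usually run in) on a 20,000-gene background with significance at P < 0.05;
compounds absent from the reference are marked "no data". The negative
control draws `set_size` (default 50) random genes `trials` (default 100)
times and records library sets under adjusted P < 10⁻⁴ — 10⁻² shared across
10² repeats. The minimal significant correlation is the exact inversion of
t = r√(n−2)/√(1−r²): r* = t_{1−α,(n−2)} / √(n−2+t²). The one-sided convention
is the package default because it reproduces the conventional 0.9996 figure
at n = 6, α = 10⁻⁷ (two-sided gives 0.9997).

## Synthetic data

`simulate_tensor` draws
x[i, j, ℓ] = μ_ℓ + β·s_j·w_ℓ·t_i + ε[i, j, ℓ], with gene baselines
μ_ℓ ~ N(0, 1), active-compound indicator s, gene weights w ∈ {−1, 0, +1}
(balanced signs so the dose signal is orthogonal to the baseline), t the
standardized linear ramp over dose index (a quadratic option probes
mis-specification), and ε ~ N(0, σ²). Defaults — 6 doses, 100 compounds,
500 genes, 10 active compounds, 50 active genes, β = 2, σ = 1 — represent a
mid-sized single-cell-line screen. `simulate_library` plants signal sets
drawing 80% of their members from the active genes among uniform noise sets;
`simulate_drug_targets` links active compounds to signal-set names. All
randomness flows from one seed.

What the generator does **not** emulate: compound-specific baseline
signatures (every compound shares the same μ_ℓ), plate/batch structure,
L1000 inference noise, or heavy-tailed expression. The first omission matters
(next section).

## Known behaviour of the selection statistic on the synthetic defaults

Two regimes of the published statistic are visible on this generator and are
reported honestly by the acceptance checks rather than patched:

1. **Compound mode, baseline constancy.** Because μ_ℓ is shared by all
   compounds, the first compound-mode singular vector is almost exactly
   constant (loadings ≈ J^{−1/2} with spread only of order 1/s₁ from noise).
   The uncentred statistic then contains a (mean/σ)² ≈ 10³ term for *every*
   compound, so all compounds are selected at any threshold — at β = 0 as
   well. On real screens compound loadings of the leading component vary with
   the compounds' overall signature strength and the statistic is
   informative; on this generator it is not. Gene-centring the tensor
   (`gene_center=True`) removes the baseline and restores ordinary behaviour.

2. **Gene mode, unit-norm ceiling.** Factor loadings are unit-norm, so an
   active gene's standardized loading on the signal component is
   ≈ √((L−1)/n_active) regardless of β — about 3.2 at (L = 500, n = 50),
   giving raw χ²(6) P ≈ 0.02, above the BH 0.01 bar over 500 genes at any
   effect size. The same arithmetic clears the bar at a 978-gene panel with
   50 active genes (standardized ≈ 4.4, adjusted P just under 0.01), i.e.
   the statistic's power depends on the active fraction of the panel, not on
   the effect amplitude, once the signal component is resolved.

The pure-noise case without a shared baseline behaves as designed: near-zero
selections at threshold 0.01.

## Numerical choices

- Sample standard deviations use the n−1 denominator throughout.
- BH adjustment accepts P = 0 (χ² tails underflow for extreme statistics).
- Fisher one-sided P is the hypergeometric upper tail; two-sided sums tables
  with probability ≤ observed (with the conventional 1+10⁻⁷ tie tolerance).
  Zero-margin tables return P = 1 with a warning.
- Dose-component detection skips components with singular value ≤ 10⁻¹²
  relative or loading spread ≤ 10⁻¹².
- Ties in BH are broken by stable sort on input order.
- Components are indexed 1-based in all reports.

## Problem sizes used by the automated checks

The test suite and `scripts/acceptance.py` use tensors up to 6×100×500
(the generator defaults), 50 random tensors up to 6×30×50 for the
decomposition oracles, all 2×2 tables with total ≤ 50 for the Fisher
enumeration, and 50 seeds for the null false-positive estimate.

## Limitations

- The completeness rule drops whole compounds; no EM-style tensor completion.
- Only the HOSVD flavour of Tucker decomposition is provided (no CP/PARAFAC).
- Enrichment replicates the Fisher/BH core of web enrichment services, not
  their combined rank scores.
- Predicted targets are identified, not ranked; adjusted P-values select but
  do not order them.
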