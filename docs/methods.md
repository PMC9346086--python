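# Methods

## Model and assumptions

The package models a large number of biallelic X-linked (or Z-linked)
loci, each held at deterministic mutation–selection balance in an
effectively infinite, randomly mating population. At locus *i* the female
genotypes AA / Aa / aa have fitness 1, 1 − h_i·s_f,i, 1 − s_f,i; the male
hemizygotes A / a have fitness 1, 1 − s_m,i. The fraction of each sex's
fitness effect acting through the focal component (survival or longevity)
is α_f,i and α_m,i, so the survival effects are h·s_f·α_f (heterozygous
females) and s_m·α_m (hemizygous males). Assumptions, in decreasing order
of importance:

- **Strong selection relative to mutation**: 2μ_f + μ_m ≪ 2hs_f + s_m per
  locus. The per-locus equilibrium p̂ = (2μ_f+μ_m)/(2hs_f+s_m) is only
  valid there; the package warns when mutation pressure exceeds 1% of the
  selection denominator and raises for loci neutral in both sexes.
- **Multiplicative fitness-component effects across loci**, no linkage,
  no epistasis. Genome loads are exp(−Σ per-locus effects); sums are
  accumulated in log space so 10⁴–10⁶ terms of order 10⁻⁷ lose no
  precision, and the exponential is taken once.
- **Partially recessive mutations** (0 < h < 0.5 on average). Ratios are
  still computed for h̄ ≥ 0.5 (with a warning) and come out ≤ 1;
  overdominance (h outside [0, 1]) is excluded.
- **No drift, no back-mutation.** The recursion oracle is deterministic by
  design; finite-population noise is out of scope.

## Ratio family and orientation

All ratio formulas return homogametic/heterogametic. ZW taxa are handled
by sex-label reversal only: the `system` tag controls labelling and the
inversion of β (which is always stored as s_m/s_f), never the mathematics.
The variant formulas reduce *bitwise exactly* to the baseline at their
degenerate parameter values (var(h) = 0, β = 1, k = 1); the shared
fraction is computed before the 3·U·α product specifically so these
identities hold in floating point, not just algebraically.

The no-dosage-compensation variant scales hemizygous selection and
survival effects by k ∈ (0, 1] while leaving homozygous female effects
untouched, giving exp(3·U_X·ᾱ·(k − 2h̄)/(k + 2h̄)). This is a
re-derivation: it reproduces the three qualitative behaviours the variant
is known for (dampening for all k < 1 unless h̄ = 0; the range of h
producing an effect shrinking to h̄ < k/2; no dampening under complete
recessivity) but the published formulation of this scenario appears only
in supplementary material we do not reproduce, so details could differ.

Combinations the theory does not define are rejected rather than guessed:
β ≠ 1 with k ≠ 1, and β ≠ 1 with var(h) > 0 (the variance correction is
derived for the equal-sex model only).

## Recursion oracle

`oracle.recursion_step` advances the exact two-sex dynamics: zygotes form
by random union (males receive their X from eggs), viability selection
applies the genotype fitnesses above, survivors make gametes, and one-way
A→a mutation acts in gametes (μ_f in eggs, μ_m in sperm). The census is at
zygotes and selection precedes gametogenesis — the convention under which
the closed-form equilibrium is derived; it is stated here because the
choice moves the equilibrium at order μ. Convergence uses an absolute
tolerance of 1e-12 on the per-generation change of both gamete
frequencies, max 10⁶ iterations, warm-started from the closed form (a
cold start from p = 0 is available and agrees to the convergence
residual, ~tol/selection-rate). A vectorized solver advances all loci of
a collection simultaneously for genome-scale validation.

**Census effects at strong absolute selection.** The pooled frequency is
defined as p_X = (2p_egg + p_sperm)/3. Hemizygous selection depresses the
sperm pool relative to eggs, so p_X sits below the closed form by
approximately s_m/3 − (2hs_f+s_m)/9 in relative terms. The analytic fixed
point of the linearized recursion is
p_egg = (2μ_f + (1−hs_f)μ_m)/(2hs_f + s_m − hs_f·s_m), which tracks the
closed form to ~1% even at s = 0.2. Consequently the 1% oracle-agreement
checks sample s ∈ [0.01, 0.03] — strong relative to mutation, mild in
absolute terms, and the empirically typical range for the mean deleterious
effect — while a separate test documents the O(s/3) pooled-census
deviation at s = 0.2. At h = 0 with hemizygous selection present the
closed form remains accurate (males still purge the allele); the
frequently cited square-root-of-μ recessive equilibrium requires selection
confined to homozygous females, for which the closed form has no finite
prediction and the package raises.

## Parameters and defaults

| parameter | meaning | default | basis |
|---|---|---|---|
| U_H | haploid genomic deleterious rate (per haploid genome per generation) | scenario-specific: 0.5 (Drosophila-like), 1.1 (vertebrate-like) | mutation-accumulation and pedigree estimates |
| P_X, P_Z | sex-linked fraction of the haploid genome | 0.2 fly, 0.05 mammal, 0.1 bird, 1 haplodiploid | karyotype/assembly data |
| R_mu | male/female per-site mutation rate ratio | 1 (fly), 4 (bird scenario) | trio and molecular-evolutionary estimates; typically 1–4 |
| h̄ | mean dominance of deleterious mutations | 0.25 | mutation-accumulation meta-analyses (plausible range ~0.18–0.36) |
| ᾱ | component effect relative to total fitness | 0.3 (viability); 0.1–0.2 typical for longevity | Drosophila mutation-accumulation estimates |
| β | s_m/s_f | 1 (baseline), 1.5 (sexual-selection scenarios) | Drosophila sex-specific selection estimates |
| k | hemizygous expression scaling without dosage compensation | 1 | modelling assumption |

The mammal baseline uses R_mu = 1; male-biased mutation only shrinks the
predicted X-linked effect further, so the baseline is an upper-end
prediction for mammals at these parameters.

Reported precision follows the quantities' conventional precision: ratios
to 4 significant figures, percents to 1 decimal place.

## Synthetic data

`synthetic.sample_loci` draws per-locus parameters independently across
loci, matching the independence assumption of the summary-level formulas.
Dominance uses a scaled beta, h = 0.5·Beta(a, b), with mean 0.25 and a
concentration parameter (default 20, giving sd ≈ 0.05); only the moments
of h are empirically constrained, the family is a package choice.
Selection defaults to a point mass at s = 0.02 with an optional lognormal
mode (mean-matched); mutation rates default to 10⁻⁶ per locus per
generation; α defaults to a point mass at 0.3. The β coupling sets
s_m = β·s_f and, by default, α_m = α_f/β so that α_f·s_f = α_m·s_m
(mutations affect viability equally in the sexes — the constraint under
which the sex-differential formula is derived); an independent-sexes mode
disables it. A single integer seed drives `numpy.random.default_rng`; no
global state.

`synthetic.sample_rmu_table` emulates literature compilations of
R_mu estimates: lognormal species-level values about a per-group
arithmetic mean, replicate estimates per species, multiplicative interval
bounds, and injected outlier species. What these generators deliberately
do **not** emulate: real distributions of fitness effects (gamma DFEs),
between-locus mutation-rate heterogeneity, correlated h–s relationships,
phylogenetic non-independence of R_mu estimates, and heteroskedastic or
asymmetric published confidence intervals. Tests passing on this
synthetic structure demonstrate internal consistency of the pipeline, not
fidelity of any real compilation.

## R_mu curation pipeline

Pipeline order is fixed: load/validate → exclusions → per-species
arithmetic averaging (species-level records only) → per-group summary.
Exclusions run *before* averaging so an excluded extreme estimate cannot
contaminate its species' mean — the order matters for species with
multiple estimates and is therefore stated prominently. Row-level failures
on load (non-positive or unparseable estimates, bounds that do not bracket
the point estimate) are diverted to an audit report with line numbers,
never silently dropped; missing bounds are permitted, as many
molecular-evolutionary estimates lack them. The per-group "central range"
is reported as the 5th–95th percentile band. Group labels are open-ended
strings; mammal/bird/other are conventions, not an enum.

## Scale of the validation runs

Genome-level equivalence checks run on 10⁴ synthetic loci (exact sum vs
second-order formula, <0.1% on log-ratio) and 10³ loci through the full
recursion oracle (<1%); the oracle agreement grid covers 63 parameter
combinations. These sizes make the standard checks complete in seconds
while keeping sampling error far below the asserted tolerances.

## Known limitations

- The closed forms inherit all the mutation–selection-balance caveats:
  no drift (important for small effective population sizes or very weak
  selection), no linkage or background-selection interference, no
  epistasis (synergistic epistasis would amplify hemizygous loads).
- The per-locus survival factors are linearized in p̂; parameters that
  drive any factor to ≤ 0 raise rather than clamp, because the
  multiplicative model is meaningless there.
- Sex-limited-effects results use the idealized half-female-limited /
  half-male-limited architecture; real architectures interpolate.
- The dosage-compensation variant is a re-derivation (see above).
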