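# Methods

## Rate law

All kinetics assume a rapid-equilibrium random-ordered bi-bi mechanism:
either G6P (A) or the oxidized cofactor (B) binds first, all binding steps
equilibrate fast relative to turnover, and catalysis proceeds only from the
ternary complex E·A·B. For one cofactor branch,

    v = kcat·e0·[A][B] / ( Kia·Kb·(1+p) + Kb·[A]·(1+p) + Ka·[B] + [A][B]·s )

with Ka = `km_g6p` (G6P off the ternary complex), Kb = `km_cofactor`
(cofactor off the ternary complex), Kia the dissociation of G6P from free
enzyme, p = [own reduced cofactor]/`kic_product`, and
s = 1 + [B]/`kis_cofactor` when substrate inhibition is present (modeled as
a dead-end ternary·B complex), else 1. Units package-wide: concentrations
µM, time s, rates µM/s.

Kia is not measured directly; it is closed through the thermodynamic box of
the random-order cycle, Kia·Kb = Kib·Ka, giving
Kia = `ki_cofactor`·`km_g6p`/`km_cofactor`. The reverse reaction is
neglected (initial-rate conditions far from equilibrium), as are pH and
temperature corrections.

**Product inhibition is own-branch only.** Each branch's competitive
inhibition constant was measured against that branch's own reduced cofactor
(NADH on the NAD⁺ branch, NADPH on the NADP⁺ branch), and that is how it is
applied: the reduced cofactor binds free enzyme and the enzyme·G6P complex
with the same kic. Cross-branch inhibition constants (e.g. NADH acting on
the NADP⁺ branch) are not available and are not invented. This choice also
keeps the output-ratio surface strictly monotone along both redox axes —
with cross-inhibition through the measured own-branch constants the surface
would lose monotonicity in physiologically reasonable regions, an artifact
of borrowing a constant measured for a different ligand.

## Dual-cofactor modes

With both cofactor pools present, two treatments are provided:

* `independent` (default): each branch obeys its own rate law in which the
  opposite oxidized cofactor enters as a competitive species at the cofactor
  site — binding free enzyme with its `ki_cofactor` and the enzyme·G6P
  complex with its `km_cofactor`. This form reproduces the observed
  G6P-dependence of the NADH:NADPH output split.
* `shared_pool`: a single rapid-equilibrium enumeration over
  {E, E·G6P, E·B₁, E·B₂, E·P₁, E·P₂, E·G6P·B₁, E·G6P·B₂, E·G6P·P₁,
  E·G6P·P₂} with one free-enzyme G6P constant. The two branches imply
  different box-closed Kia values; their geometric mean is used
  (`shared_kia`). In this form the flux ratio is analytically
  G6P-independent — the E·G6P factor cancels — which is why both modes are
  offered: strict pool-sharing cannot express the G6P sensitivity that the
  independent form shows.

The output ratio v_NADH/v_NADPH is `inf` when only the NAD⁺ branch carries
flux and `nan` (undefined) when both fluxes vanish; grid sweeps convert
these to per-cell flags and never abort.

## Redox grids

Default surface: 25 log-spaced ratios from 0.01 to 100 on each redox axis,
G6P at 100 µM and 1 mM. A ratio r at pool total T is converted to
oxidized = T·r/(1+r), reduced = T/(1+r). Intracellular pool totals are not
fixed by the enzyme data; the defaults — 2,600 µM NAD(H) and 400 µM
NADP(H), the latter bracketing the ~276 µM NADPH reported for glucose-grown
KT2440 — are configurable and recorded in every output. G6P sensitivity is
the mean over redox cells of |log ratio(G6P_hi) − log ratio(G6P_lo)|,
excluding flagged cells. No parameters are shipped for the *E. coli*
comparison enzyme; users must supply their own.

## Fitting machinery

* **V₀ extraction**: points with product ≤ 5% of the initial limiting
  substrate (≥ 5 required) are fitted with a quadratic in time; the linear
  coefficient is the rate. Negative estimates are returned with a warning,
  not clamped.
* **Direct linear plot**: each (s, v) observation defines the line
  Vmax = v + (v/s)·Km; the estimate is the component-wise median of all
  pairwise intersections, skipping parallel pairs.
* **Global fit**: all design points enter one objective,
  Σ((v_obs − v_model)/w)², with relative weighting w = |v_obs| (observed
  rather than modeled rates as the scale, avoiding the degeneracy of
  model-weighted relative residuals; proportional error is the standard
  heteroscedasticity model for rate data). Optimization runs in log₁₀
  parameter space under box bounds (scipy `least_squares`, TRF,
  ftol = xtol = 1e-12) from 16 starts: one anchored by direct-linear-plot
  estimates of the apparent constants, the rest log-uniform over the bounds
  from the seeded generator. The best converged start wins.
* **Model discrimination**: candidates (± product inhibition, ± substrate
  inhibition, ± first-order enzyme decay) are ranked by small-sample AICc
  with Akaike weights; near-ties resolve toward fewer parameters. The
  relative SSR is floored at 1e-16 per point (residuals below 1e-8 relative
  are numerically meaningless at the optimizer tolerance), so "perfect" fits
  of nested models compare exactly by their parameter penalty. Candidates
  with as many parameters as observations are excluded with a warning.
* **Enzyme decay** enters through an optional per-observation timestamp:
  a rate observed at assay age t is modeled as v·exp(−decay_rate·t). This
  discriminates inactivation from rate data without integral fitting of full
  progress curves, which is out of scope.
* **Confidence intervals**: parametric bootstrap with relative-residual
  resampling — rᵢ = (v_obs − v_fit)/v_fit resampled with replacement onto
  the fitted curve, each replicate refitted from the original estimates;
  ci95 = 2.5/97.5 percentiles (default 1,000 replicates; tests use 200).
  If over 20% of refits fail, intervals come from the successes with a
  warning. Measured coverage at CV = 5% over 20 seeds is ≈ 94% at nominal
  95%.
* **Selwyn test**: curves recorded at different e0 are rescaled to the
  e0·t axis, interpolated onto their common range (100 points), and the RMS
  pairwise deviation normalized by the maximum product is compared with a
  threshold of 0.05 (a heuristic standing in for the visual overlap
  judgment; simulated stable enzymes score ≲ 0.002, fast inactivation
  ≳ 0.3).

## Sequence classification

Anchoring is by deterministic pairwise global alignment (Biopython
`PairwiseAligner`, BLOSUM62, gap open −11 / extend −1) of each query to a
single anchored reference, rather than per-order multiple alignment — one
reproducible alignment per query, no external MSA tool. The reference
carries a 1-based `anchor_pos` whose residue must be R. A query is
NADP-specific iff its residue in the anchor-equivalent column is arginine;
any other residue is "relaxed"; a gap, X, or failed mapping is unresolved.
All coordinates are 1-based on ungapped sequences.

Species rollups count unresolved calls toward the isoform number but never
toward "has a relaxed isozyme"; isoform counts are binned 1/2/3/4plus.
Glycolysis calls follow the marker rule: KDPG aldolase (Eda) ⇒ ED-capable
(`eda_only`, default; `edd_or_eda` also accepts the dehydratase), Pfk ⇒
EMP-capable, both ⇒ ED_EMP, neither ⇒ other ("other" and "unknown" are one
category). Taxon summaries report fractions by isoform bin, relaxed-within-
bin, glycolysis category and the glycolysis × bin cross-tab; every partition
sums to 1 within 1e-12.

Caveat: a deletion of the anchor arginine adjacent to another arginine is
undetectable by any alignment (the neighbor fills the column); the planted-
truth generators therefore keep indels outside a ±10 window of the anchor,
matching how the recovery guarantees are stated.

## Synthetic data

Generators are fully deterministic under one seed; independent sub-streams
(scaffold, anchor draws, substitutions, indels, marker categories, rate
noise) derive from it with documented stream indices.

* **Rate datasets**: default design crosses cofactor
  {20, 50, 100, 200, 500, 1000, 2000} µM with G6P
  {95, 300, 1000, 3000, 5000} µM (the assay ranges of the underlying
  experiments), optionally adding reduced-cofactor levels for product-
  inhibition designs; noise is multiplicative Gaussian, CV default 5%,
  truncated at −0.9 so rates stay positive.
* **Progress curves**: d[product]/dt integrated with LSODA at 1e-6 relative
  tolerance; substrate and oxidized cofactor deplete stoichiometrically,
  the reduced cofactor accumulates into product inhibition, enzyme decays
  as e0·exp(−kd·t) when requested. Curves are noiseless by design.
* **Protein cohorts**: a 500-aa scaffold with uniform residue background,
  the cofactor fingerprint planted at position 12 and the anchor at
  position 50 (echoing the R50 convention). Per record the anchor residue is
  drawn from a configurable distribution (default 70% R / 20% H / 10% K);
  substitutions (per-site Bernoulli) avoid the anchor and fingerprint;
  indel events — round(rate × length) per record, length 1–5 — start outside
  a ±10 anchor window and the fingerprint. Marker tables are drawn from a
  glycolysis mixture (default 40/30/20/10% ED/EMP/ED_EMP/other). What this
  emulates: orthologue sets with a conserved discriminating residue and
  genome-derived marker calls. What it does not: phylogenetic correlation
  between sequences (no tree-structured evolution), alignment-hostile
  low-complexity regions, or annotation errors in marker tables — so
  passing recovery tests demonstrates the pipeline's bookkeeping and
  alignment anchoring, not robustness to real orthology noise.

## Problem sizes and defaults used in the checks

Estimator checks run at the default 35-point design; noisy-recovery and
CI-coverage checks use 20 seeds with 200 bootstrap replicates; oracle
equivalence uses 1,000 random parameter/mixture draws at 1e-9 relative
tolerance; classifier recovery uses cohorts of 20–400 species (~100–1,000
records). These sizes give stable statistics while keeping the whole suite
fast.

## Known limitations

* Kia values closed via the thermodynamic box inherit the rounding of the
  printed constants; Haldane-estimated kic values are taken as given.
* The shared-pool mode's single free-enzyme G6P constant is a modeling
  compromise (geometric mean of the two branch values).
* The independent mode ignores cross-branch product binding entirely;
  real enzymes likely show some.
* Bootstrap CIs are conditional on the fitted model; model-selection
  uncertainty is not propagated.
* The classifier's single-reference anchoring assumes the query family is
  alignable to the chosen reference; deeply divergent families should be
  classified against a family-specific reference (or a pre-computed
  alignment, which the API also accepts as equal-width segments).
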