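# g6pdhkit

Kinetics, redox-output simulation and sequence classification for bacterial
glucose-6-phosphate dehydrogenase (G6PDH) isozymes.

G6PDH catalyzes the first committed step of the oxidative pentose phosphate
pathway and feeds the Entner-Doudoroff (ED) route, reducing either NAD⁺ or
NADP⁺. Which cofactor it reduces matters: NADH is re-oxidized for ATP, NADPH
drives anabolism and oxidative-stress defense. The soil bacterium
*Pseudomonas putida* KT2440 encodes three G6PDH isozymes (G6PDH-A, -B, -C)
with sharply different cofactor preferences, and across bacteria the number
of G6PDH isozymes and their cofactor specificity track the host's glycolytic
strategy. This package provides, for anyone studying such enzymes:

* **Mechanistic rate laws** (`g6pdhkit.kinetics`) — the rapid-equilibrium
  random-ordered bi-bi mechanism for G6P + NAD(P)⁺, with competitive product
  inhibition by the reduced cofactor, optional substrate inhibition, and the
  cofactor specificity constant
  φ = (k_cat/K_m)_NADP⁺ / (k_cat/K_m)_NAD⁺. The measured central kinetic
  constants of the three KT2440 isozymes ship as a packaged YAML file.
* **Estimation machinery** (`g6pdhkit.fitting`) — initial rates from progress
  curves (quadratic fit below 5% substrate consumption), the direct linear
  plot (median of pairwise intersections), seeded multistart global fitting
  with relative weighting, AICc model discrimination with Akaike weights,
  parametric-bootstrap 95% CIs, and the Selwyn test for enzyme inactivation.
* **Redox output simulation** (`g6pdhkit.redox`) — NADH:NADPH flux-ratio
  surfaces over grids of NAD⁺/NADH and NADP⁺/NADPH ratios at fixed pool
  totals and G6P levels, when both cofactors compete for one enzyme.
* **Sequence classification** (`g6pdhkit.classify`) — pairwise-alignment
  anchoring of the β2-α2 cofactor-discriminating residue (the R50-equivalent
  arginine that hydrogen-bonds the 2′-phosphate of NADP⁺): arginine ⇒
  NADP-specific, anything else ⇒ relaxed; plus the N-terminal
  G-[G/A]-X-G-D-L-[A/V]-[K/L] cofactor-binding fingerprint, conserved-site
  screens, per-species isoform profiles, marker-gene glycolysis calls
  (Pfk ⇒ EMP; Eda, optionally Edd ⇒ ED) and taxon-level fraction tables.
* **Synthetic data** (`g6pdhkit.synth`) — seeded generators for assay grids,
  progress curves and protein cohorts, each with a machine-readable truth
  table, so every stage is testable without external downloads.

## Worked example

```
$ python examples/01_specificity_constants.py
isozyme           phi   preference
G6PDH-A          3.34   NADP+
G6PDH-B          0.86   NAD+ (dual)
G6PDH-C       2081.98   NADP+

phi(G6PDH-C) / phi(E. coli) = 5.08-fold
```

φ > 1 means the enzyme turns over NADP⁺ more efficiently than NAD⁺ at
saturation. G6PDH-A prefers NADP⁺ about 3-fold, G6PDH-B is essentially
cofactor-neutral (φ ≈ 0.86), and G6PDH-C is an extreme NADP⁺ specialist —
5-fold beyond the archetypal *E. coli* enzyme (φ = 410).

Under competing cofactor pools the picture shifts
(`examples/02_output_surfaces.py`, default grid, independent-branch mode):

```
 enzyme  median_ratio  g6p_sensitivity
G6PDH-A      2.154351         0.108692
G6PDH-B      7.234720         0.451285
G6PDH-C      0.005226         0.363171
```

`median_ratio` is the median NADH:NADPH flux ratio over the grid: G6PDH-B
mostly feeds the NADH pool and its output split reacts strongly to the G6P
level (`g6p_sensitivity`, mean |Δlog ratio| between 100 µM and 1 mM G6P),
while G6PDH-C produces almost pure NADPH everywhere. The other examples show
global fitting with bootstrap CIs on synthetic assay data
(`03_fit_synthetic_rates.py`), the Selwyn inactivation test
(`04_selwyn_test.py`), and cohort classification with taxon summaries
(`05_classify_cohort.py`).

A thin CLI wraps the same functionality:

```
g6pdhkit phi                      # specificity constants of the packaged set
g6pdhkit simulate --mode independent --out run/
g6pdhkit synth --kind proteins --n-species 50 --seed 1 --out run/
g6pdhkit classify --fasta run/proteins.fasta --mapping run/mapping.tsv \
    --markers run/markers.tsv --ref run/reference.fasta --anchor-pos 50 \
    --out run/cls
g6pdhkit report --manifest run/cls/manifest.json
```

Every run writes a `manifest.json` with SHA-256 checksums; identical config
and seed reproduce identical checksums.

## Layout

```
src/g6pdhkit/        kinetics, fitting, redox, classify, synth, io,
                     pipeline, cli; data/kt2440_g6pdh_params.yaml
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      model assumptions, defaults and numerical choices
```
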