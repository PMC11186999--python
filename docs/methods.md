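# Methods

## The scientific question

Across amniotes, karyotypes differ strikingly: most birds and non-avian
reptiles (sauropsids) carry many microchromosomes, while mammals carry
almost none. `karyomorph` implements a comparative analysis that asks
whether two karyotype parameters — the haploid chromosome number *n* and the
chromosome **dispersity** *K* = *L*max/*L*min (the length ratio of the
longest to the shortest autosome at mitosis) — covary with sperm head
morphology, controlling for genome size *C* and for the phylogenetic
relatedness of species.

Two head morphologies are analyzed as separate cohorts: **spatulate**
(flattened, rounded; typical eutherian mammals), quantified by head length
ℓ, width *w*, and projected area *A* = (π/4)ℓ*w*; and **vermiform**
(elongated, ~1 μm diameter; most sauropsids), quantified by ℓ alone.

## Trait derivation

* **Electron-microscopy correction.** Dimensions measured by SEM/TEM run
  systematically ~1 μm below optical measurements, so a fixed offset
  (default 1.0 μm, configurable for sensitivity analysis) is added to all
  SEM/TEM head lengths and to mammal widths; optical values are untouched.
  The correction precedes the area computation, since *A* is defined from
  the corrected ℓ and *w*.
* **Dispersity.** *K* = max/min over autosome lengths (sex and B
  chromosomes excluded). *K* is invariant to mitotic contraction because
  relative chromosome lengths are conserved; values of *L*min below ~0.5 μm
  are flagged as imprecise (logged, never excluded).
* **Genome normalization.** *A*/*C* (μm²/pg) and ℓ/*C* (μm/pg) proxy the
  DNA-per-area (hence mean nuclear thickness) of a head; species without a
  genome size simply drop out of normalized models by listwise deletion.
* **Cohort screen.** Species whose nucleus occupies <50% of head length are
  excluded when that fraction is recorded; records lacking the datum are
  presumed pre-screened by curation. Every exclusion is logged.

Units are fixed (μm, μm², pg); no unit inference from headers.

## Models

### Joint shortest-autosome power law (OLS)

log10 *L*min = δ + α·log10 *C* + β·log10 *K* + γ·log10 *n*, equivalently
*L*min = *D·C*^α·*K*^β·*n*^γ with *D* = 10^δ. Fit by ordinary least squares
on complete cases — deliberately *not* phylogenetic, since the object of
interest is the shape of the occupied trait space rather than an
evolutionary regression.

### PGLS under Pagel's λ

Every other model is a single-predictor (or single-indicator) regression on
log10 scale with residual covariance σ²·V(λ), where V is the phylogenetic
covariance matrix (V[i,i] = root-to-tip depth; V[i,j] = depth of the most
recent common ancestor) and V(λ) multiplies the off-diagonal by λ ∈ [0, 1].
λ = 0 removes phylogenetic structure; λ = 1 is full Brownian covariance.

Estimation profiles λ: at fixed λ the GLS coefficients
(XᵀV⁻¹X)⁻¹XᵀV⁻¹y and σ̂² have closed forms (computed by Cholesky whitening,
never an explicit inverse), leaving a one-dimensional bounded likelihood
maximized by Brent search on [0, 1] to 1e-6 absolute tolerance, with both
endpoints checked explicitly and boundary solutions flagged. REML is the
default criterion (ML available by configuration); the two differ little at
these sample sizes and the reported λ̂ records which was used.

Inference details:

* standard errors from σ̂² = êᵀV(λ̂)⁻¹ê/(N−k); two-sided t-tests with
  df = N − k, where k counts mean parameters only (λ is not charged against
  df, following common practice);
* R² on the λ̂-whitened model: 1 − (êᵀV⁻¹ê)/(ẽᵀV⁻¹ẽ) with ẽ the residuals
  about the GLS-estimated grand mean — this reduces to ordinary R² at
  V = I;
* λ is clamped to [0, 1]; unconstrained implementations can wander outside,
  and boundary hits are reported rather than hidden;
* a constant predictor after listwise deletion raises an
  insufficient-variation error instead of producing a zero-SE fit.

### The battery

Per cohort, six models: each of log10 *n* and log10 *K* against the
cohort's head dimension (area for spatulate, length for vermiform), genome
size, and the normalized dimension. Four pooled models follow: *n* and *K*
against *C* across both cohorts, and against the head-shape indicator
*s* (0 = spatulate mammal, 1 = vermiform sauropsid). Each slope is flagged
significant at two-sided p < 0.05. Cells that cannot be fit are emitted
with N = 0 rather than dropped, so the output shape is fixed (16 rows).

## Synthetic data

The generator adopts the weakest structure the inference assumes — which is
exactly what parameter recovery must validate:

* **Trees**: pure-birth (Yule) simulation conditioned on tip count, with one
  extra exponential waiting time after the last split; ultrametric, scaled
  to unit root-to-tip depth (all exponents and λ are invariant to the time
  unit). The two-cohort database joins a mammal and a sauropsid subtree at
  a root, the mammal crown set younger (0.55 vs 0.75 of total depth),
  echoing amniote timetrees.
* **Traits**: log10 predictor evolves by Brownian motion; the response is
  intercept + slope·predictor + ε with ε ~ MVN(0, σ²·V(λ)).
* **Karyotypes**: longest and shortest autosomes pinned to the target
  dispersity exactly; interior lengths log-uniform (right-skewed, like real
  karyotypes); lengths rescaled to a fixed total.

Default settings are the study conditions: 103 spatulate mammals (87 with
genome size) and 90 vermiform sauropsids (55 of 90), i.e. 142 of 193
species with *C*; a mammal *n*–area exponent of 0.23 with λ = 0.33 and a
sauropsid *K*–length exponent of 0.43 with λ = 0.71. Residual standard
deviations (0.123 and 0.42 on log10 scale) and Brownian rates (0.08 and
0.10) were set so the cross-species spread of each trait and the implied
fit R² (~0.12 and ~0.05) match the magnitudes reported for the real
cohorts. The joint *L*min law uses exponents (α, β, γ) =
(0.1, −0.63, −0.57) with noise sd 0.162, chosen in closed form so the
population R² of the N = 65 complete-case fit is 0.72; δ = 0.9 and α = 0.1
are the package's own choices for the two parameters reported only as
non-significant.

One deliberate schema simplification: the species table derives *K* from
the stored L-columns, so the generator emits L-values for every species
(giving *K* for all 193, as the cohort battery requires), while the
complete-case joint *L*min fit is exercised through a dedicated N = 65
generator entry point (`simulate_lmin_table`) matching that regression's
sample size.

What the generator does **not** emulate: measurement error in ℓ and *w*
beyond the EM offset, non-Brownian trait evolution (OU, rate shifts),
correlated missingness of genome sizes, integer/ratio discreteness of real
karyotypes beyond rounding *n*, and phylogenetic error in the input tree.
Passing recovery tests therefore validate the estimator under its own
assumptions — they do not certify the biological conclusions on real data.

## Numerical choices

* Species are ordered lexicographically everywhere, so covariance matrices
  and outputs are reproducible; Newick underscores are normalized to
  spaces for name matching.
* Polytomies are accepted as-is (TimeTree emits them); no random
  resolution.
* Non-ultrametric trees trigger a warning, not an error.
* Rank deficiency is detected by pivoted QR and reported with the names of
  the dependent columns; singular covariance matrices (duplicated tips,
  zero terminal branches) raise a dedicated error.
* Output tables are formatted to 6 significant digits so re-runs are
  byte-identical; analysis subcommands consume no randomness at all.

## Problem sizes

The test suite and the acceptance script use replicate counts of 200 (500
for the large-sample coverage check) at the cohort sample sizes above;
tree-level checks use 4–200 tips. The full suite runs in well under a
minute; the acceptance script in under a minute.

## Known limitations

* Only single-predictor PGLS is exposed (plus the indicator model); the
  joint model is OLS by design. No OU or measurement-error correlation
  structures.
* λ is restricted to [0, 1]; data preferring λ > 1 (more similarity than
  Brownian) will pile up at the boundary.
* Real-data reproduction depends on the specific phylogeny consumed;
  tree-version drift moves λ̂ and slopes within roughly one standard error.
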