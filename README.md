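# karyomorph

Comparative analysis of amniote karyotype parameters and sperm head
morphology.

Mammalian karyotypes lack microchromosomes; most sauropsid (bird and
non-avian reptile) karyotypes have many. `karyomorph` tests whether two
karyotype parameters — the haploid chromosome number *n* and the chromosome
**dispersity** *K* = *L*max/*L*min (longest over shortest autosome length at
mitosis) — track sperm head morphology across species, controlling for
genome size *C* and for phylogeny. It is aimed at comparative biologists
working from a species trait table (head dimensions in μm, karyotype,
genome size in pg) and a time-calibrated Newick phylogeny.

Two models sit at the core:

* the joint shortest-autosome power law, fit by OLS on log-transformed
  data:

  log₁₀ *L*min = δ + α·log₁₀ *C* + β·log₁₀ *K* + γ·log₁₀ *n*,
  i.e. *L*min = *D·C*^α·*K*^β·*n*^γ with *D* = 10^δ;

* phylogenetic generalized least squares (PGLS) under Pagel's λ for a
  battery of single-predictor power laws y = *A·x*^β per head-shape cohort
  (spatulate mammals: *n* or *K* vs head area, *C*, area/*C*; vermiform
  sauropsids: the same with head length), with λ estimated by profile
  (restricted) maximum likelihood on [0, 1].

The PGLS engine (covariance construction, λ profiling, GLS via Cholesky
whitening, whitened R²) is implemented here from first principles and is
cross-checked in the test suite against independent implementations. A
synthetic-data generator produces Yule trees, Brownian traits with
λ-thinned residuals, and karyotype tables at the study's sample sizes, so
the whole pipeline is testable without any downloads. See
[docs/methods.md](docs/methods.md) for the model details and design choices.

## Worked example

Simulate a database at the study conditions (103 spatulate mammals, 90
vermiform sauropsids, genome sizes for 142 of 193) and run the full
analysis:

```sh
karyomorph simulate --seed 7 --out-dir demo
karyomorph run --species-table demo/species.csv --tree demo/tree.nwk --out-dir demo/results
karyomorph report demo/results/battery.csv --lmin demo/results/lmin_model.csv
```

which prints (abridged):

```
Joint shortest-autosome power law L_min = D C^alpha K^beta n^gamma (OLS):
  N=142.0  D=7.56  alpha=+0.104  beta=-0.583  gamma=-0.597  R2=0.812
Cohort battery (PGLS, Pagel's lambda):
  spatulate_mammal     log10_n  ~ log10_area           N=103 slope=+0.356 SE=0.067 lambda=0.00 p=5.52e-07 R2=0.221 *
  spatulate_mammal     log10_K  ~ log10_area           N=103 slope=+0.183 SE=0.163 lambda=0.24 p=0.264 R2=0.012
  vermiform_sauropsid  log10_n  ~ log10_length         N= 90 slope=-0.004 SE=0.057 lambda=0.14 p=0.949 R2=0.000
  vermiform_sauropsid  log10_K  ~ log10_length         N= 90 slope=+0.646 SE=0.196 lambda=0.69 p=0.00143 R2=0.110 *
  ...
```

Reading the output: each battery row is one power law; `slope` is the
exponent β, `lambda` the estimated phylogenetic signal, and `*` marks
exponents significantly different from zero (two-sided t-test, p < 0.05).
In this simulated replicate the mammal chromosome number rises with head
area (β̂ = 0.36; the generator's true exponent is 0.23 — single replicates
scatter around the truth) and sauropsid dispersity rises with head length
(β̂ = 0.65, truth 0.43, λ̂ = 0.69 near the generated 0.71), while the
uncoupled cells show no trend — matching the couplings built into the
generator. The lmin row says that species with high dispersity (β < 0) and
many chromosomes (γ < 0) have short smallest autosomes.

The same operations are available as library calls (`fit_lmin_model`, `pgls_fit`,
`run_battery`, `simulate_database`); real data are consumed from a
delimited species table and a single-tree Newick file.

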