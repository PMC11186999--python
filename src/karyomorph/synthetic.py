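"""Synthetic data with the statistical structure the analysis assumes.

The generator produces (i) ultrametric Yule (pure-birth) phylogenies, (ii)
power-law trait pairs whose residuals are multivariate normal with covariance
sigma^2 * V(lambda) — i.e. Brownian-motion deviations thinned by Pagel's
lambda, exactly the model the PGLS engine fits — and (iii) karyotype tables
with a controlled haploid number n and dispersity K. ``simulate_database``
assembles everything into the species-table schema that the traits module
consumes, with raw SEM/TEM dimensions de-corrected so that the pipeline's
electron-microscopy correction round-trips to the generated truth.

Default settings mirror the study conditions: 103 spatulate mammals (87 with
genome size) and 90 vermiform sauropsids (55 with genome size); a mammal
chromosome-number/head-area exponent of 0.23 with phylogenetic signal
lambda = 0.33, and a sauropsid dispersity/head-length exponent of 0.43 with
lambda = 0.71; shortest-autosome lengths follow the joint power law in genome
size, dispersity, and chromosome number with exponents (0.1, -0.63, -0.57).
Trees are emitted with unit root-to-tip depth; all fitted exponents and
lambda are invariant to the time unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny, lambda_transform, parse_newick, vcv
from .traits import TABLE_COLUMNS

__all__ = ["SyntheticConfig", "KaryotypeConfig", "MeasurementConfig",
           "simulate_yule_tree", "simulate_traits", "simulate_karyotype",
           "simulate_database"]


@dataclass
class KaryotypeConfig:
    n_range: tuple[int, int] = (9, 40)          # haploid autosome-pair count
    K_range: tuple[float, float] = (1.5, 20.0)  # dispersity interval
    total_length_scale_um: float = 150.0        # summed autosome length


@dataclass
class MeasurementConfig:
    method_mix: dict[str, float] = field(
        default_factory=lambda: {"optical": 0.5, "SEM": 0.3, "TEM": 0.2})
    em_offset_um: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.method_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"method mix proportions sum to {total}, not 1")


@dataclass
class SyntheticConfig:
    """Parameters for one synthetic trait set on one tree."""

    n_tips: int = 103
    birth_rate: float = 1.0
    true_intercept: float = 1.0
    true_slopes: dict[str, float] = field(default_factory=lambda: {"x": 0.23})
    sigma2: float = 0.0152          # residual variance on the log10 scale
    lambda_true: float = 0.33
    seed: int = 0
    x_log_mean: float = 1.4         # mean of log10 predictor
    x_bm_rate: float = 0.08         # Brownian rate of log10 predictor
    karyotype: KaryotypeConfig = field(default_factory=KaryotypeConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | np.random.Generator = 0,
                       label_format: str = "sp{:04d}",
                       normalize_depth: bool = True) -> Phylogeny:
    """Simulate an ultrametric pure-birth tree with labelled tips.

    Lineages split at total rate (number alive) * birth_rate; once ``n_tips``
    lineages exist the process runs for one further exponential waiting time
    and all pendant edges are cut at the present. By default the tree is
    rescaled to unit root-to-tip depth; with ``normalize_depth=False`` branch
    lengths stay in the birth process's own time units. Deterministic given
    the seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        active.append((child, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, start = active.pop(idx)
        node.edge.length = t - start
        for _ in range(2):
            active.append((node.new_child(), t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, start in active:
        node.edge.length = t - start
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label_format.format(i))
    if normalize_depth:
        scale = 1.0 / t
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return Phylogeny(tree)


def _mvn(rng: np.random.Generator, cov: np.ndarray) -> np.ndarray:
    """Draw one zero-mean multivariate normal via Cholesky (with PSD jitter)."""
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    return L @ rng.standard_normal(len(cov))


def simulate_traits(tree: Phylogeny, config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a power-law trait pair with phylogenetic residuals.

    log10 x evolves by Brownian motion on the tree (rate ``x_bm_rate`` about
    ``x_log_mean``); log10 y = intercept + slope * log10 x + eps with
    eps ~ MVN(0, sigma2 * V(lambda_true)). Returns a species-aligned frame
    with natural-scale columns x, y plus their log10 transforms.
    """
    rng = rng or np.random.default_rng(config.seed)
    cov = vcv(tree)
    V = cov.matrix
    slope = next(iter(config.true_slopes.values()))
    x_log = config.x_log_mean + _mvn(rng, config.x_bm_rate * V)
    eps = _mvn(rng, config.sigma2 * lambda_transform(cov, config.lambda_true).matrix)
    y_log = config.true_intercept + slope * x_log + eps
    return pd.DataFrame({"species": cov.species, "x": 10.0 ** x_log,
                         "y": 10.0 ** y_log, "log10_x": x_log, "log10_y": y_log})


def simulate_karyotype(haploid_n: int, K_target: float, total_length_scale: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Autosome lengths with dispersity pinned to ``K_target`` exactly.

    The longest and shortest autosomes are fixed at ratio K_target; interior
    lengths are log-uniform between them (karyotype length distributions are
    right-skewed); the list is rescaled so its sum equals
    ``total_length_scale``. Lengths are returned sorted, longest first.
    """
    if haploid_n < 2:
        raise ValueError("need at least 2 autosomes")
    if K_target < 1.0:
        raise ValueError(f"dispersity target must be >= 1, got {K_target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    interior = np.exp(rng.uniform(0.0, math.log(K_target) if K_target > 1 else 0.0,
                                  size=haploid_n - 2))
    lengths = np.sort(np.concatenate([[K_target, 1.0], interior]))[::-1]
    return lengths * (total_length_scale / lengths.sum())


# ---------------------------------------------------------------------------
# Full two-cohort database

#: study-condition cohort settings (sizes, couplings, phylogenetic signal)
_MAMMAL = dict(n_species=103, n_genome=87, dim_log_mean=1.40, dim_bm_rate=0.08,
               slope=0.23, lam=0.33, resid_sd=0.123, resp="n", resp_log_mean=1.30,
               other_log_mean=0.62, other_log_sd=0.25, genome_log_mean=0.52,
               genome_log_sd=0.10, genome_dim_coupling=1.0, aspect_log_mean=-0.20,
               aspect_log_sd=0.04)
_SAUROPSID = dict(n_species=90, n_genome=55, dim_log_mean=1.20, dim_bm_rate=0.10,
                  slope=0.43, lam=0.71, resid_sd=0.42, resp="K", resp_log_mean=1.25,
                  other_log_sd=0.12, genome_log_mean=0.23, genome_log_sd=0.10,
                  genome_dim_coupling=0.0, other_log_mean=1.25)

#: joint shortest-autosome power law: L_min = D * C^a * K^b * n^g * 10^eps;
#: the noise level puts the N=65 complete-case fit's population R^2 at ~0.72
_LMIN_LAW = dict(delta=0.9, alpha=0.1, beta=-0.63, gamma=-0.57, resid_sd=0.162)


def _two_cohort_tree(n_mammals: int, n_sauropsids: int, birth_rate: float,
                     rng: np.random.Generator) -> Phylogeny:
    """Join two unit-depth Yule subtrees at a root; total depth stays 1."""
    mam = simulate_yule_tree(n_mammals, birth_rate, rng, label_format="msp{:04d}")
    sau = simulate_yule_tree(n_sauropsids, birth_rate, rng, label_format="ssp{:04d}")
    # mammal crown younger than sauropsid crown, as in amniote timetrees
    mam_h, sau_h = 0.55, 0.75

    def _scaled(phy: Phylogeny, h: float) -> str:
        for edge in phy.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= h
        return phy.as_newick().replace("[&R]", "").strip().rstrip(";")

    joined = "({}:{:.10g},{}:{:.10g});".format(
        _scaled(mam, mam_h), 1 - mam_h, _scaled(sau, sau_h), 1 - sau_h)
    return parse_newick(joined)


def simulate_database(config: SyntheticConfig | None = None,
                      n_mammals: int = 103, n_sauropsids: int = 90,
                      n_genome_mammals: int = 87, n_genome_sauropsids: int = 55,
                      seed: int | None = None,
                      mammal_overrides: dict | None = None,
                      sauropsid_overrides: dict | None = None,
                      ) -> tuple[pd.DataFrame, Phylogeny]:
    """Generate a full two-cohort species table plus its phylogeny.

    Spatulate mammals carry a chromosome-number/head-area coupling; vermiform
    sauropsids carry a dispersity/head-length coupling (slopes and lambdas
    from the module defaults). Genome sizes are present for the configured
    subsets; shortest/longest autosome lengths follow the joint power law in
    C, K, and n. Raw SEM/TEM dimensions are de-corrected by the
    electron-microscopy offset so the pipeline's correction restores truth.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    tree = _two_cohort_tree(n_mammals, n_sauropsids, config.birth_rate, rng)
    full_cov = vcv(tree)

    mam_params = {**_MAMMAL, **(mammal_overrides or {})}
    sau_params = {**_SAUROPSID, **(sauropsid_overrides or {})}
    frames = []
    for params, cohort, prefix, n_sp, n_gen in (
            (mam_params, "spatulate_mammal", "msp", n_mammals, n_genome_mammals),
            (sau_params, "vermiform_sauropsid", "ssp", n_sauropsids,
             n_genome_sauropsids)):
        species = [s for s in full_cov.species if s.startswith(prefix)]
        sub = full_cov.reorder(species)
        V = sub.matrix
        m = len(species)

        genome_log = params["genome_log_mean"] + \
            params["genome_log_sd"] * rng.standard_normal(m)
        dim_log = params["dim_log_mean"] + _mvn(rng, params["dim_bm_rate"] * V) + \
            params["genome_dim_coupling"] * (genome_log - params["genome_log_mean"])
        eps = _mvn(rng, params["resid_sd"] ** 2 *
                   lambda_transform(sub, params["lam"]).matrix)
        resp_log = params["resp_log_mean"] + \
            params["slope"] * (dim_log - params["dim_log_mean"]) + eps
        other_log = params["other_log_mean"] + \
            params["other_log_sd"] * rng.standard_normal(m)

        if params["resp"] == "n":
            n_hap = np.maximum(3, np.rint(10.0 ** resp_log)).astype(int)
            K = np.maximum(1.05, 10.0 ** other_log)
        else:
            K = np.maximum(1.05, 10.0 ** resp_log)
            n_hap = np.maximum(3, np.rint(10.0 ** other_log)).astype(int)

        has_genome = np.zeros(m, dtype=bool)
        has_genome[rng.choice(m, size=min(n_gen, m), replace=False)] = True
        genome = np.where(has_genome, 10.0 ** genome_log, np.nan)
        genome_for_len = np.where(has_genome, 10.0 ** genome_log,
                                  10.0 ** params["genome_log_mean"])

        lmin = (10.0 ** _LMIN_LAW["delta"] * genome_for_len ** _LMIN_LAW["alpha"]
                * K ** _LMIN_LAW["beta"] * n_hap.astype(float) ** _LMIN_LAW["gamma"]
                * 10.0 ** (_LMIN_LAW["resid_sd"] * rng.standard_normal(m)))
        lmax = K * lmin

        if cohort == "spatulate_mammal":
            area = 10.0 ** dim_log
            aspect = 10.0 ** (params["aspect_log_mean"] +
                              params["aspect_log_sd"] * rng.standard_normal(m))
            length = np.sqrt(4.0 * area / (math.pi * aspect))
            width = aspect * length
        else:
            length = 10.0 ** dim_log
            width = np.full(m, np.nan)

        methods = rng.choice(list(config.measurement.method_mix),
                             p=list(config.measurement.method_mix.values()), size=m)
        off = config.measurement.em_offset_um
        is_em = np.isin(methods, ["SEM", "TEM"])
        raw_length = np.where(is_em, length - off, length)
        raw_width = width.copy()
        if cohort == "spatulate_mammal":
            raw_width = np.where(is_em, width - off, width)
        # keep raw measurements physical: tiny heads stay optical
        bad = is_em & ((raw_length <= 0.1) |
                       (np.nan_to_num(raw_width, nan=1.0) <= 0.1))
        methods = np.where(bad, "optical", methods)
        raw_length = np.where(bad, length, raw_length)
        if cohort == "spatulate_mammal":
            raw_width = np.where(bad, width, raw_width)

        nf = np.round(rng.uniform(0.55, 0.95, size=m), 3)
        nf_present = rng.random(m) < 0.5
        frames.append(pd.DataFrame({
            "species": species,
            "clade": "mammal" if cohort == "spatulate_mammal" else "sauropsid",
            "head_shape": ("spatulate" if cohort == "spatulate_mammal"
                           else "vermiform"),
            "head_length_um": np.round(raw_length, 4),
            "head_width_um": np.round(raw_width, 4),
            "method": methods,
            "nucleus_fraction": np.where(nf_present, nf, np.nan),
            "haploid_n": n_hap,
            "L_max_um": np.round(lmax, 4),
            "L_min_um": np.round(lmin, 4),
            "genome_pg": np.round(genome, 4),
            "source": "synthetic",
        }))
    table = pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]
    return table, tree


def simulate_lmin_table(n_species: int = 65, seed: int = 0,
                       delta: float = _LMIN_LAW["delta"], alpha: float = _LMIN_LAW["alpha"],
                       beta: float = _LMIN_LAW["beta"], gamma: float = _LMIN_LAW["gamma"],
                       resid_sd: float = _LMIN_LAW["resid_sd"]) -> pd.DataFrame:
    """Complete-case table for the joint shortest-autosome power law.

    Draws (C, K, n) over realistic ranges and sets L_min = 10^delta * C^alpha
    * K^beta * n^gamma * 10^eps with eps ~ N(0, resid_sd^2); the default noise
    level puts the joint fit's R^2 near the observed 0.72 at N = 65.
    """
    rng = np.random.default_rng(seed)
    genome_log = rng.uniform(0.0, 0.75, n_species)      # C in ~1-5.6 pg
    K_log = rng.uniform(0.1, 1.35, n_species)           # K in ~1.3-22
    n_log = rng.uniform(0.8, 1.55, n_species)           # n in ~6-35
    n_hap = np.maximum(3, np.rint(10.0 ** n_log)).astype(int)
    K = 10.0 ** K_log
    # L_min follows the power law in the *realized* integer n exactly
    lmin_log = (delta + alpha * genome_log + beta * K_log
                + gamma * np.log10(n_hap.astype(float))
                + resid_sd * rng.standard_normal(n_species))
    lmin = 10.0 ** lmin_log
    return pd.DataFrame({
        "species": [f"esp{i:04d}" for i in range(1, n_species + 1)],
        "clade": "mammal", "head_shape": "spatulate",
        "head_length_um": 6.0, "head_width_um": 4.0, "method": "optical",
        "nucleus_fraction": np.nan, "haploid_n": n_hap,
        "L_max_um": K * lmin, "L_min_um": lmin,
        "genome_pg": 10.0 ** genome_log, "source": "synthetic",
    })[TABLE_COLUMNS]
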