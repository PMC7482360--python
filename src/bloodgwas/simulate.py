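"""Seeded synthetic cohorts, coexpression networks, and trans-eQTL tables.

Everything downstream of this module (association scans, conditional analysis,
fine-mapping, network tests, polygenic scores) is exercised on data produced
here, so the generators encode the statistical structure those stages assume:

* genotypes with haplotype-block LD and a realistic MAF spectrum, produced by
  mosaic copying from a small pool of founder haplotypes per block;
* quantitative phenotypes built from a sparse set of large-effect causal
  variants, a dense polygenic background, covariate effects (age, age^2, sex,
  principal components), and Gaussian noise, with the total variance close
  to one;
* a gene coexpression matrix in which designated "core" genes have elevated
  mutual correlation and elevated degree;
* a trans-eQTL table whose per-gene record rate is enriched for core genes;
* binary disease labels drawn from a liability (logistic) model with a stated
  odds ratio per standard deviation of a polygenic score.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

logger = logging.getLogger(__name__)

#: number of founder haplotypes per LD block
N_FOUNDERS = 20
#: per-site probability of switching founder template during mosaic copying
SWITCH_RATE = 0.05
#: serial correlation of the latent Gaussian generating founder haplotypes
LATENT_RHO = 0.97

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a synthetic genotype/phenotype cohort.

    Parameters
    ----------
    n_samples, n_variants
        Cohort dimensions.
    ld_block_span
        Number of consecutive variants per haplotype block; variants in
        different blocks are generated independently.
    maf_range
        Per-variant target minor allele frequencies are drawn uniformly from
        this interval (each endpoint in (0, 0.5]).
    causal_spec
        Sparse large-effect architecture: ``[(variant_index, beta), ...]``
        with beta in phenotype SD per allele.
    h2_polygenic
        Variance fraction contributed by the dense polygenic background.
    covariate_effects
        Coefficients for standardized covariates, keys among
        ``{"age", "age2", "sex", "pc1", "pc2", ...}``; each coefficient
        contributes its square to the variance budget.
    dosage_noise_sd
        If positive, Gaussian noise is added to hard-call dosages (clipped to
        [0, 2]) and a per-variant INFO score (observed/expected dosage
        variance ratio) is recorded; if zero, hard calls with INFO = 1.
    locus_seed
        Seed for the variant panel (target MAFs, founder haplotypes,
        alleles).  Defaults to ``seed``; give two cohorts the same
        ``locus_seed`` and different ``seed`` to draw independent samples
        from the same population (same loci, same LD structure).
    """

    n_samples: int
    n_variants: int
    ld_block_span: int = 25
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_spec: Sequence[tuple[int, float]] = ()
    h2_polygenic: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    dosage_noise_sd: float = 0.0
    seed: int = 0
    locus_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("n_samples and n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_block_span < 1:
            raise ValueError("ld_block_span must be >= 1")
        idx = [i for i, _ in self.causal_spec]
        if len(set(idx)) != len(idx):
            raise ValueError("causal indices must be unique")
        if any(i < 0 or i >= self.n_variants for i in idx):
            raise ValueError("causal index out of range")
        if not 0.0 <= self.h2_polygenic < 1.0:
            raise ValueError("h2_polygenic must be in [0, 1)")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x variants) plus per-variant metadata.

    ``variants`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    eaf, info.  ``dosages`` counts copies of the effect allele.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    covariates: pd.DataFrame | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (monomorphic columns set to 0)."""
        g = self.dosages - self.dosages.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return g / sd

    def ld_r2(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Pairwise LD r^2 from dosage correlation in this sample."""
        g = self.standardized()
        if indices is not None:
            g = g[:, list(indices)]
        r = (g.T @ g) / g.shape[0]
        return r**2


def _founder_pool(
    mafs: np.ndarray, rng: np.random.Generator, n_founders: int = N_FOUNDERS
) -> np.ndarray:
    """Founder haplotypes with decaying inter-site LD.

    Each founder's alleles are thresholded from a latent AR(1) Gaussian
    (serial correlation LATENT_RHO), so the per-site marginal frequency is
    the target MAF while nearby sites are strongly correlated within the
    pool; mosaic copying then propagates that structure to the population.
    """
    width = mafs.shape[0]
    thresh = sps.norm.ppf(mafs)
    eps = rng.normal(size=(n_founders, width))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - LATENT_RHO**2)
    for j in range(1, width):
        z[:, j] = LATENT_RHO * z[:, j - 1] + scale * eps[:, j]
    return (z < thresh).astype(np.int8)


def _mosaic_haplotypes(
    founders: np.ndarray, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Copy ``n_hap`` haplotypes from a founder pool with template switches."""
    n_f, span = founders.shape
    start = rng.integers(0, n_f, size=n_hap)
    if span == 1:
        return founders[start, :]
    switch = rng.random((n_hap, span)) < SWITCH_RATE
    switch[:, 0] = True
    draws = rng.integers(0, n_f, size=(n_hap, span))
    draws[:, 0] = start
    # forward-fill the founder index from the last switch point
    cols = np.arange(span)
    marked = np.where(switch, cols, -1)
    last = np.maximum.accumulate(marked, axis=1)
    template = draws[np.arange(n_hap)[:, None], last]
    return founders[template, cols[None, :]]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Generate a dosage matrix with haplotype-block LD.

    Within each block of ``ld_block_span`` consecutive variants, haplotypes
    are mosaics of a pool of 20 founder haplotypes, giving decaying pairwise
    LD with distance; across blocks variants are independent.  Realized
    effect-allele frequency and INFO are recorded per variant.
    """
    locus_seed = config.seed if config.locus_seed is None else config.locus_seed
    rng_locus = np.random.default_rng(locus_seed)
    rng = np.random.default_rng(config.seed + 500_009)
    n, m, span = config.n_samples, config.n_variants, config.ld_block_span
    lo, hi = config.maf_range

    dosages = np.empty((n, m), dtype=float)
    for start in range(0, m, span):
        width = min(span, m - start)
        mafs = rng_locus.uniform(lo, hi, size=width)
        founders = _founder_pool(mafs, rng_locus)
        haps = _mosaic_haplotypes(founders, 2 * n, rng)
        dosages[:, start : start + width] = haps[:n] + haps[n:]

    info = np.ones(m)
    if config.dosage_noise_sd > 0:
        noisy = dosages + rng.normal(0.0, config.dosage_noise_sd, size=dosages.shape)
        noisy = np.clip(noisy, 0.0, 2.0)
        eaf_hard = dosages.mean(axis=0) / 2.0
        expected = 2.0 * eaf_hard * (1.0 - eaf_hard)
        with np.errstate(divide="ignore", invalid="ignore"):
            info = np.where(expected > 0, noisy.var(axis=0) / expected, 0.0)
        info = np.clip(info, 0.0, 1.0)
        dosages = noisy

    eaf = dosages.mean(axis=0) / 2.0
    pos = 1_000_000 + 5_000 * np.arange(m)
    allele_idx = rng_locus.integers(0, 4, size=m)
    effect = _BASES[allele_idx]
    other = _BASES[(allele_idx + 1 + rng_locus.integers(0, 3, size=m)) % 4]
    variants = pd.DataFrame(
        {
            "variant_id": [
                f"1:{p}_{min(a, b)}_{max(a, b)}"
                for p, a, b in zip(pos, effect, other)
            ],
            "chrom": "1",
            "pos": pos,
            "effect_allele": effect,
            "other_allele": other,
            "eaf": eaf,
            "info": info,
        }
    )
    covariates = _simulate_covariates(n, config.covariate_effects, rng)
    return GenotypeMatrix(dosages=dosages, variants=variants, covariates=covariates)


def _simulate_covariates(
    n: int, effects: Mapping[str, float], rng: np.random.Generator
) -> pd.DataFrame:
    """Age ~ U(40, 70), sex ~ Bernoulli(0.5), PCs ~ N(0, 1)."""
    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cov = pd.DataFrame({"age": age, "age2": age**2, "sex": sex})
    n_pcs = max(
        (int(k[2:]) for k in effects if k.startswith("pc")), default=0
    )
    for j in range(1, n_pcs + 1):
        cov[f"pc{j}"] = rng.normal(size=n)
    return cov


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTruth:
    """Ground truth stored for recovery tests."""

    sparse_effects: dict[int, float]
    polygenic_weights: np.ndarray
    components: dict[str, np.ndarray]
    noise_sd: float


@dataclass
class SimulatedPhenotype:
    table: pd.DataFrame  # column "phenotype" plus covariates
    truth: PhenotypeTruth

    @property
    def values(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()


def simulate_phenotype(G: GenotypeMatrix, config: SimConfig) -> SimulatedPhenotype:
    """Quantitative phenotype = sparse causal effects + polygenic background
    + covariate effects + Gaussian noise, total variance ~ 1.

    Sparse effects enter on the raw dosage scale (beta in SD per allele);
    the dense polygenic term is scaled to realize exactly ``h2_polygenic`` of
    variance; noise absorbs the remaining budget.  Raises ``ValueError`` when
    the variance budget (sparse + polygenic + covariates) reaches 1.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = G.n_samples
    causal = dict(config.causal_spec)
    for i in causal:
        if i >= G.n_variants:
            raise ValueError("causal index out of range for genotype matrix")

    sparse = np.zeros(n)
    var_sparse = 0.0
    eaf = G.variants["eaf"].to_numpy()
    for i, beta in causal.items():
        sparse += beta * (G.dosages[:, i] - G.dosages[:, i].mean())
        var_sparse += beta**2 * 2.0 * eaf[i] * (1.0 - eaf[i])

    weights = np.zeros(G.n_variants)
    poly = np.zeros(n)
    if config.h2_polygenic > 0:
        gstd = G.standardized()
        raw_w = rng.normal(size=G.n_variants)
        raw_w[list(causal)] = 0.0
        u = gstd @ raw_w
        sd_u = u.std()
        if sd_u == 0:
            raise ValueError("polygenic component degenerate (no variation)")
        scale = np.sqrt(config.h2_polygenic) / sd_u
        weights = raw_w * scale
        poly = u * scale

    cov_term = np.zeros(n)
    var_cov = 0.0
    if config.covariate_effects:
        assert G.covariates is not None
        for name, coef in config.covariate_effects.items():
            col = G.covariates[name].to_numpy()
            colz = (col - col.mean()) / col.std()
            cov_term += coef * colz
            var_cov += coef**2

    var_noise = 1.0 - var_sparse - config.h2_polygenic - var_cov
    if var_noise <= 0:
        raise ValueError(
            f"variance budget exceeded: sparse={var_sparse:.3f} "
            f"h2={config.h2_polygenic:.3f} covariates={var_cov:.3f}"
        )
    noise_sd = np.sqrt(var_noise)
    noise = rng.normal(0.0, noise_sd, size=n)
    y = sparse + poly + cov_term + noise

    table = pd.DataFrame({"phenotype": y})
    if G.covariates is not None:
        table = pd.concat([table, G.covariates.reset_index(drop=True)], axis=1)
    truth = PhenotypeTruth(
        sparse_effects=causal,
        polygenic_weights=weights,
        components={
            "sparse": sparse,
            "polygenic": poly,
            "covariates": cov_term,
            "noise": noise,
        },
        noise_sd=noise_sd,
    )
    return SimulatedPhenotype(table=table, truth=truth)


# ---------------------------------------------------------------------------
# coexpression network simulation
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimConfig:
    """Configuration of a synthetic gene coexpression network.

    The correlation matrix is the sample correlation of a latent-factor
    expression model (guaranteeing positive semi-definiteness): non-core
    genes form modules of ``base_degree + 1`` members with within-module
    correlation ``module_corr``; core genes share a common factor inducing
    core-core correlation ``core_mutual_correlation`` and additionally join
    ``~ core_degree_multiplier * base_degree / module_size`` modules (with
    loadings scaled to the variance budget), which elevates their degree at
    cutoffs below the module correlation.  ``n_obs`` expression samples set
    the background correlation level (~1/sqrt(n_obs)).
    """

    n_genes: int
    n_core: int
    base_degree: float = 5.0
    core_degree_multiplier: float = 1.0
    core_mutual_correlation: float = 0.1
    module_corr: float = 0.45
    n_obs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core > self.n_genes:
            raise ValueError("n_core must not exceed n_genes")
        if not 0.0 <= self.core_mutual_correlation < 1.0:
            raise ValueError("core_mutual_correlation must be in [0, 1)")
        if self.base_degree <= 0 or self.core_degree_multiplier <= 0:
            raise ValueError("degree parameters must be positive")


@dataclass
class GeneNetwork:
    """Gene-by-gene correlation matrix with per-gene flags.

    ``flags`` columns: core (bool), gwas (bool).  The edge set at cutoff c is
    the set of pairs with |correlation| > c.
    """

    genes: list[str]
    corr: np.ndarray
    flags: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def core_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.flags["core"]) if c]

    def adjacency(self, cutoff: float) -> np.ndarray:
        adj = np.abs(self.corr) > cutoff
        np.fill_diagonal(adj, False)
        return adj

    def degrees(self, cutoff: float) -> np.ndarray:
        return self.adjacency(cutoff).sum(axis=1)


def _nearest_psd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping followed by rescaling to unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, eps, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return np.clip(repaired, -1.0, 1.0)


def simulate_network(config: NetworkSimConfig) -> GeneNetwork:
    """Generate a coexpression correlation matrix with hub-like core genes.

    Expression for ``n_obs`` latent samples is built from unit-variance
    factor loadings and the sample correlation matrix returned (always
    positive semi-definite; a repair pass runs defensively and raises if it
    cannot restore PSD-ness).  At ``core_degree_multiplier = 1`` and a low
    ``core_mutual_correlation`` a core gene is indistinguishable from a
    regular module member.
    """
    rng = np.random.default_rng(config.seed)
    m, n_core = config.n_genes, config.n_core
    core = np.zeros(m, dtype=bool)
    core[:n_core] = True
    noncore_idx = np.flatnonzero(~core)

    q = config.module_corr  # within-module correlation
    cmc = config.core_mutual_correlation

    # partition every gene (core included) into modules
    module_size = max(2, int(round(config.base_degree)) + 1)
    module_of = np.empty(m, dtype=int)
    perm = rng.permutation(m)
    for k, i in enumerate(perm):
        module_of[i] = k // module_size
    n_modules = int(module_of.max()) + 1

    # core genes load their own module plus k-1 extra ones, with the total
    # module loading scaled to the variance budget left by the core factor
    k_mod = max(1, int(round(config.core_degree_multiplier * config.base_degree
                             / module_size)))
    k_mod = min(k_mod, n_modules)
    q_core = min(q, 0.95 * (1.0 - cmc) / k_mod)

    n_obs = config.n_obs
    f_mod = rng.normal(size=(n_obs, n_modules))
    f_core = rng.normal(size=n_obs)
    eps = rng.normal(size=(n_obs, m))

    X = np.zeros((n_obs, m))
    for i in np.flatnonzero(core):
        others = [j for j in range(n_modules) if j != module_of[i]]
        extra = rng.choice(len(others), size=k_mod - 1, replace=False) if k_mod > 1 else []
        mods = [module_of[i]] + [others[j] for j in np.atleast_1d(extra)]
        sig = np.sqrt(cmc) * f_core + np.sqrt(q_core) * f_mod[:, mods].sum(axis=1)
        load2 = cmc + k_mod * q_core
        X[:, i] = sig + np.sqrt(1.0 - load2) * eps[:, i]
    for i in noncore_idx:
        X[:, i] = np.sqrt(q) * f_mod[:, module_of[i]] + np.sqrt(1.0 - q) * eps[:, i]

    corr = np.corrcoef(X, rowvar=False)
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        corr = _nearest_psd(corr)
        if np.linalg.eigvalsh(corr).min() < -1e-6:
            raise ValueError("nearest-PSD repair failed")

    genes = [f"gene{i:04d}" for i in range(m)]
    flags = pd.DataFrame({"gene": genes, "core": core, "gwas": False}).set_index(
        "gene"
    )
    return GeneNetwork(genes=genes, corr=corr, flags=flags)


# ---------------------------------------------------------------------------
# trans-eQTL table simulation
# ---------------------------------------------------------------------------

@dataclass
class TransEqtlTable:
    """Records (variant, target gene, Z) plus per-gene median expression."""

    records: pd.DataFrame
    expression: pd.Series  # indexed by gene


def simulate_trans_eqtls(
    network: GeneNetwork,
    enrichment: float,
    n_eqtls: int,
    seed: int = 0,
    expression_core_shift: float = 0.5,
) -> TransEqtlTable:
    """Assign ``n_eqtls`` trans-eQTL records to target genes with the core
    genes' expected per-gene count equal to ``enrichment`` times the non-core
    expectation.  Core genes also get modestly higher median expression
    (``expression_core_shift`` SD), mirroring the detection-power confounding
    the matched enrichment test must correct for.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    if n_eqtls < 1:
        raise ValueError("n_eqtls must be >= 1")
    rng = np.random.default_rng(seed)
    core = network.flags["core"].to_numpy()
    w = np.where(core, enrichment, 1.0).astype(float)
    if w.sum() == 0:
        raise ValueError("all target weights zero")
    target_idx = rng.choice(network.n_genes, size=n_eqtls, p=w / w.sum())
    z = (4.0 + rng.exponential(1.5, size=n_eqtls)) * rng.choice(
        [-1.0, 1.0], size=n_eqtls
    )
    records = pd.DataFrame(
        {
            "variant": [f"trans{i:06d}" for i in range(n_eqtls)],
            "gene": [network.genes[i] for i in target_idx],
            "z": z,
        }
    )
    expr = rng.normal(5.0, 1.0, size=network.n_genes)
    expr[core] += expression_core_shift
    expression = pd.Series(expr, index=network.genes, name="median_expression")
    return TransEqtlTable(records=records, expression=expression)


# ---------------------------------------------------------------------------
# disease simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDisease:
    labels: np.ndarray
    intercept: float
    or_per_sd: float


def simulate_disease(
    pgs: np.ndarray, or_per_sd: float, prevalence: float, seed: int = 0
) -> SimulatedDisease:
    """Binary disease labels from a logistic liability model.

    The intercept is calibrated (1-d root finding) so the expected prevalence
    matches the target given the empirical score distribution.
    """
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be > 0")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pgs = np.asarray(pgs, dtype=float)
    slope = np.log(or_per_sd)

    def mean_risk(a: float) -> float:
        return float(special.expit(a + slope * pgs).mean()) - prevalence

    intercept = optimize.brentq(mean_risk, -40.0, 40.0)
    p = special.expit(intercept + slope * pgs)
    labels = (rng.random(pgs.shape[0]) < p).astype(int)
    return SimulatedDisease(labels=labels, intercept=intercept, or_per_sd=or_per_sd)
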