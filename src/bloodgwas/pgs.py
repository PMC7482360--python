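"""Polygenic score construction, evaluation, and disease association.

A polygenic score (PGS) is a weighted sum of allele dosages, with weights
oriented to trait-increasing alleles and the resulting score standardized to
unit variance.  Four variant-selection strategies are supported, mirroring
the comparison a discovery GWAS would run:

``a``  all scanned variants after LD pruning (r^2 0.8);
``b``  LD-pruned variants passing a marginal p-value threshold
       (thresholds compared: 0.05, 5e-4, 5e-6, 5e-8);
``c``  conditionally independent sentinels plus fine-mapped variants with
       posterior inclusion probability > 0.5;
``d``  conditionally independent sentinels only.

Evaluation reports Pearson R and R^2 against a quantitative trait; disease
models are logistic regressions of case status on the standardized score
(odds ratio per SD, Wald CI), refused below a minimum case count.  The
module also provides the carrier-penetrance odds ratio (2x2 table, Woolf CI
with the Haldane-Anscombe correction) and the check for systematic PGS
deviation of rare-variant carriers from the population mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

PRUNE_R2 = 0.8
P_THRESHOLDS = (0.05, 5e-4, 5e-6, 5e-8)
MIN_CASES = 40
PIP_CUTOFF = 0.5


@dataclass
class PgsModel:
    """Variant weights oriented to trait-increasing effect alleles."""

    weights: pd.DataFrame  # variant_id, effect_allele, other_allele, weight
    strategy: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.weights["variant_id"].duplicated().any():
            raise ValueError("duplicate variant IDs in PGS model")
        if (self.weights["weight"] < 0).any():
            raise ValueError("weights must be oriented non-negative")

    @property
    def n_variants(self) -> int:
        return len(self.weights)


def _orient_positive(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Flip alleles so every weight refers to the trait-increasing allele."""
    out = stats_df.copy()
    neg = out["beta"] < 0
    ea = out.loc[neg, "effect_allele"].copy()
    out.loc[neg, "effect_allele"] = out.loc[neg, "other_allele"].to_numpy()
    out.loc[neg, "other_allele"] = ea.to_numpy()
    out.loc[neg, "beta"] = -out.loc[neg, "beta"]
    return out


def ld_prune(
    stats_df: pd.DataFrame, G_ref: GenotypeMatrix, r2_max: float = PRUNE_R2
) -> pd.DataFrame:
    """Greedy LD pruning: sweep variants by ascending p (position as the
    tie-break) and keep each unless it has r^2 > ``r2_max`` with a variant
    already kept."""
    col_of = {v: i for i, v in enumerate(G_ref.variants["variant_id"])}
    idx = [col_of[v] for v in stats_df["variant_id"]]
    r2 = G_ref.ld_r2(idx)
    order = np.lexsort((stats_df["pos"].to_numpy(), stats_df["p"].to_numpy()))
    kept: list[int] = []
    for i in order:
        if not kept or np.all(r2[i, kept] <= r2_max):
            kept.append(int(i))
    return stats_df.iloc[sorted(kept)].reset_index(drop=True)


def select_variants(
    summary_stats: pd.DataFrame,
    strategy: str,
    sentinels: pd.DataFrame | None = None,
    finemap_tables: list[pd.DataFrame] | None = None,
    G_ref: GenotypeMatrix | None = None,
    p_threshold: float | None = None,
    prune_r2: float = PRUNE_R2,
    source: str = "",
) -> PgsModel:
    """Build a PGS model under one of the four selection strategies.

    ``sentinels`` (strategies c, d) carries joint-model betas; fine-map
    tables (strategy c) carry per-variant ``pip``.  Strategies a and b need
    an LD reference for pruning, and b a ``p_threshold``.  Weights are
    de-duplicated and oriented positive; an empty selection raises.
    """
    if strategy in ("a", "b"):
        if G_ref is None:
            raise ValueError("strategies a/b require an LD reference")
        sel = summary_stats
        if strategy == "b":
            if p_threshold is None:
                raise ValueError("strategy b requires p_threshold")
            sel = sel[sel["p"] < p_threshold]
        if len(sel) == 0:
            raise ValueError("no variants selected")
        sel = ld_prune(sel.reset_index(drop=True), G_ref, r2_max=prune_r2)
    elif strategy in ("c", "d"):
        if sentinels is None:
            raise ValueError("strategies c/d require sentinels")
        sel = sentinels.copy()
        if strategy == "c":
            if finemap_tables is None:
                raise ValueError("strategy c requires fine-mapping results")
            fm_ids: set[str] = set()
            for tbl in finemap_tables:
                fm_ids |= set(tbl.loc[tbl["pip"] > PIP_CUTOFF, "variant_id"])
            extra_ids = fm_ids - set(sel["variant_id"])
            extra = summary_stats[summary_stats["variant_id"].isin(extra_ids)]
            sel = pd.concat(
                [sel, extra[sel.columns.intersection(extra.columns)]],
                ignore_index=True,
            )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if len(sel) == 0:
        raise ValueError("no variants selected")
    need = {"effect_allele", "other_allele"}
    if not need <= set(sel.columns):
        # sentinels carry joint estimates but alleles live in the scan table
        sel = sel.merge(
            summary_stats[["variant_id", "effect_allele", "other_allele"]],
            on="variant_id",
            how="left",
        )
    sel = sel.drop_duplicates("variant_id")
    sel = _orient_positive(sel)
    weights = sel[["variant_id", "effect_allele", "other_allele", "beta"]].rename(
        columns={"beta": "weight"}
    )
    return PgsModel(
        weights=weights.reset_index(drop=True), strategy=strategy, source=source
    )


def compute_pgs(G: GenotypeMatrix, model: PgsModel) -> np.ndarray:
    """Standardized weighted dosage sum.

    Model variants missing from the genotypes are mean-imputed from sample
    EAF (a constant contribution, logged per variant); allele orientation is
    resolved per variant (dosage flipped to 2 - d when the model's effect
    allele is the genotype's other allele).  Zero score variance raises.
    """
    col_of = {v: i for i, v in enumerate(G.variants["variant_id"])}
    raw = np.zeros(G.n_samples)
    for row in model.weights.itertuples(index=False):
        j = col_of.get(row.variant_id)
        if j is None:
            logger.info("compute_pgs: %s missing, mean-imputed", row.variant_id)
            continue  # constant shift only; no effect after standardization
        d = G.dosages[:, j]
        g_ea = G.variants["effect_allele"].iat[j]
        g_oa = G.variants["other_allele"].iat[j]
        if row.effect_allele == g_ea:
            pass
        elif row.effect_allele == g_oa and row.other_allele == g_ea:
            d = 2.0 - d
        else:
            raise ValueError(f"allele mismatch for {row.variant_id}")
        raw = raw + row.weight * d
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero score variance")
    return (raw - raw.mean()) / sd


def evaluate_pgs(scores: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """Pearson R between score and trait, and the variance explained R^2."""
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if scores.shape != phenotype.shape or scores.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.ptp(scores) == 0 or np.ptp(phenotype) == 0:
        raise ValueError("constant input")
    r = float(stats.pearsonr(scores, phenotype).statistic)
    return r, r**2


@dataclass
class DiseaseAssociationResult:
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    p_bonferroni: float
    n_cases: int
    n_controls: int


def pgs_disease_association(
    scores: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    min_cases: int = MIN_CASES,
    n_diseases: int = 1,
) -> DiseaseAssociationResult:
    """Logistic regression of disease status on the standardized PGS.

    Reports the odds ratio per SD of score with a Wald 95% CI, plus the
    Bonferroni-corrected p across ``n_diseases`` tested disorders.  Refuses
    to fit below ``min_cases`` cases and on detected separation.
    """
    labels = np.asarray(labels, dtype=int)
    n_cases = int(labels.sum())
    if n_cases < min_cases:
        raise ValueError(f"{n_cases} cases < required minimum of {min_cases}")
    X = pd.DataFrame({"pgs": np.asarray(scores, dtype=float)})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    try:
        fit = sm.Logit(labels, X).fit(disp=False)
    except Exception as exc:  # includes PerfectSeparationError
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    coef = float(fit.params["pgs"])
    se = float(fit.bse["pgs"])
    if not np.isfinite(se) or se > 50:
        raise ValueError("separation suspected: unstable standard error")
    z = stats.norm.ppf(0.975)
    p = float(fit.pvalues["pgs"])
    return DiseaseAssociationResult(
        or_per_sd=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p=p,
        p_bonferroni=min(1.0, p * n_diseases),
        n_cases=n_cases,
        n_controls=int(len(labels) - n_cases),
    )


@dataclass
class PenetranceResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    table: np.ndarray  # [[a, b], [c, d]]
    corrected: bool = False


def carrier_penetrance(
    carrier: np.ndarray,
    trait_values: np.ndarray,
    normal_bound: float,
    direction: str = "below",
) -> PenetranceResult:
    """Odds ratio for carriers having blood indices outside the normal range.

    ``direction`` says which side of ``normal_bound`` is abnormal ("below",
    e.g. platelets < 150x10^9/L, or "above").  The 2x2 table odds ratio
    carries a Woolf CI; zero cells receive the Haldane-Anscombe 0.5
    correction (flagged).
    """
    carrier = np.asarray(carrier, dtype=bool)
    trait = np.asarray(trait_values, dtype=float)
    if carrier.all() or not carrier.any():
        raise ValueError("need both carriers and non-carriers")
    if direction == "below":
        outside = trait < normal_bound
    elif direction == "above":
        outside = trait > normal_bound
    else:
        raise ValueError("direction must be 'below' or 'above'")
    a = float(np.sum(carrier & outside))
    b = float(np.sum(carrier & ~outside))
    c = float(np.sum(~carrier & outside))
    d = float(np.sum(~carrier & ~outside))
    table = np.array([[a, b], [c, d]])
    corrected = min(a, b, c, d) == 0
    if corrected:
        logger.info("carrier_penetrance: zero cell, Haldane-Anscombe correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    wald = np.log(or_) / se
    return PenetranceResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - z * se)),
        ci_high=float(np.exp(np.log(or_) + z * se)),
        p=float(2.0 * stats.norm.sf(abs(wald))),
        table=table,
        corrected=corrected,
    )


@dataclass
class DeviationCheckResult:
    flags: np.ndarray
    flag_rate: float
    branch: str  # "logistic" or "threshold"
    group_p: float | None = None


def pgs_deviation_check(
    carrier_scores: np.ndarray,
    population_scores: np.ndarray,
    k: float = 2.0,
) -> DeviationCheckResult:
    """Do rare-variant carriers deviate systematically in PGS?

    Per-carrier flags mark |score| > k * SD of the population score.  With
    more than 10 carriers a logistic regression of carrier status on the
    score provides a group-level p; with 10 or fewer only the per-carrier
    threshold flags are reported.
    """
    carrier_scores = np.asarray(carrier_scores, dtype=float)
    population_scores = np.asarray(population_scores, dtype=float)
    if carrier_scores.size == 0:
        raise ValueError("empty carrier set")
    sd = population_scores.std()
    flags = np.abs(carrier_scores) > k * sd
    if carrier_scores.size > 10:
        y = np.concatenate(
            [np.ones(carrier_scores.size), np.zeros(population_scores.size)]
        )
        x = sm.add_constant(np.concatenate([carrier_scores, population_scores]))
        fit = sm.Logit(y, x).fit(disp=False)
        return DeviationCheckResult(
            flags=flags,
            flag_rate=float(flags.mean()),
            branch="logistic",
            group_p=float(fit.pvalues[1]),
        )
    return DeviationCheckResult(
        flags=flags, flag_rate=float(flags.mean()), branch="threshold"
    )
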