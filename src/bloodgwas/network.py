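"""Omnigenic-model test battery on a gene coexpression network.

The omnigenic model posits a small set of "core" genes (here: genes causing
Mendelian blood disorders) that directly drive a phenotype, with many
peripheral genes contributing heritability through trans-regulation of the
core.  This module implements the empirical checks of that picture:

* permutation overlap enrichment of a query gene set in an annotated set,
  with fold enrichment FE = observed / null mean and an add-one permutation
  p-value (floor 1/(n_perm+1));
* degree (connectivity) comparison of core vs non-core genes at a hard
  coexpression cutoff (one-sided Wilcoxon rank-sum);
* mutual-coexpression test: median absolute correlation among core-core
  pairs against equal-sized random gene draws;
* MAF-matched comparison of absolute GWAS effect sizes between variants
  assigned to core genes and matched controls, per annotation class;
* trans-eQTL target enrichment of core genes after matching non-core genes
  on expression level and eQTL |Z|;
* enrichment of a query set among first/second-degree network neighbors of
  the core genes.

Edges are defined by |correlation| > cutoff.  All permutation machinery is
seeded and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import inverse_normal_transform
from .simulate import GeneNetwork, TransEqtlTable

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Observed overlap vs a permutation null."""

    observed: float
    null_mean: float
    fold_enrichment: float
    p: float
    n_perm: int
    seed: int


def _perm_p(null: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value, floored at 1/(n_perm+1)."""
    return (1.0 + np.sum(null >= observed)) / (len(null) + 1.0)


def overlap_enrichment(
    query: set[str],
    annotated: set[str],
    universe: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment of ``query`` in ``annotated`` over ``universe``.

    Null draws are uniform same-size samples of the universe without
    replacement, repeated ``n_perm`` times.
    """
    universe = list(universe)
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= set(universe) or not annotated <= set(universe):
        raise ValueError("query and annotated sets must lie in the universe")
    rng = np.random.default_rng(seed)
    is_annot = np.array([g in annotated for g in universe])
    observed = float(len(query & annotated))
    k = len(query)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=k, replace=False)
        null[i] = is_annot[draw].sum()
    null_mean = float(null.mean())
    fe = observed / null_mean if null_mean > 0 else np.inf
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        fold_enrichment=fe,
        p=_perm_p(null, observed),
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class DegreeTestResult:
    core_degrees: np.ndarray
    other_degrees: np.ndarray
    p: float
    degenerate: bool = False


def degree_test(
    network: GeneNetwork, core_genes: set[str], cutoff: float
) -> DegreeTestResult:
    """One-sided Wilcoxon rank-sum test for core genes having more
    coexpression links than other genes at the given cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    core_mask = np.array([g in core_genes for g in network.genes])
    if not core_mask.any():
        raise ValueError("no core genes present in the network")
    deg = network.degrees(cutoff)
    core_deg, other_deg = deg[core_mask], deg[~core_mask]
    if deg.sum() == 0:
        logger.warning("degree_test: no edges at cutoff %.3f", cutoff)
        return DegreeTestResult(core_deg, other_deg, p=1.0, degenerate=True)
    p = stats.mannwhitneyu(core_deg, other_deg, alternative="greater").pvalue
    return DegreeTestResult(core_deg, other_deg, p=float(p))


@dataclass
class CoexpressionTestResult:
    observed_median: float
    null_medians: np.ndarray
    p: float


def core_coexpression_test(
    network: GeneNetwork,
    core_genes: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> CoexpressionTestResult:
    """Median absolute coexpression among core-core pairs vs random draws."""
    core_idx = [i for i, g in enumerate(network.genes) if g in core_genes]
    if len(core_idx) < 2:
        raise ValueError("need at least 2 core genes")
    rng = np.random.default_rng(seed)
    absC = np.abs(network.corr)

    def pair_median(idx: np.ndarray) -> float:
        sub = absC[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(np.median(sub[iu]))

    observed = pair_median(np.array(core_idx))
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(network.n_genes, size=len(core_idx), replace=False)
        null[i] = pair_median(draw)
    return CoexpressionTestResult(
        observed_median=observed,
        null_medians=null,
        p=_perm_p(null, observed),
    )


def match_nearest(
    values: np.ndarray,
    treated: np.ndarray,
    ratio: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Greedy nearest-neighbor 1:ratio matching without replacement.

    ``values`` is (n,) or (n, d); multi-covariate distances are Euclidean
    after rank-scaling each covariate to [0, 1].  Treated items are
    processed in covariate order for determinism.  Returns the selected
    control indices (ratio per treated item, no reuse).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    treated = np.asarray(treated, dtype=bool)
    scaled = np.empty_like(values)
    for j in range(values.shape[1]):
        r = stats.rankdata(values[:, j])
        scaled[:, j] = (r - 1) / max(len(r) - 1, 1)
    t_idx = np.flatnonzero(treated)
    c_idx = np.flatnonzero(~treated)
    if len(c_idx) < ratio * len(t_idx):
        raise ValueError("insufficient controls for requested matching ratio")
    # deterministic processing order: by first covariate then index
    t_order = t_idx[np.lexsort((t_idx, scaled[t_idx, 0]))]
    available = dict.fromkeys(c_idx.tolist())
    chosen: list[int] = []
    for t in t_order:
        avail = np.fromiter(available.keys(), dtype=int)
        d = np.linalg.norm(scaled[avail] - scaled[t], axis=1)
        picks = avail[np.lexsort((avail, d))][:ratio]
        for c in picks:
            del available[int(c)]
            chosen.append(int(c))
    return np.array(chosen, dtype=int)


@dataclass
class EffectComparisonResult:
    per_class: pd.DataFrame  # class, n_core, n_matched, fold_change, p
    skipped: list[str]


def matched_effect_comparison(
    variants: pd.DataFrame,
    min_per_group: int = 10,
    seed: int = 0,
) -> EffectComparisonResult:
    """MAF-matched effect-size comparison of core vs other variants.

    ``variants`` needs ``abs_beta``, ``maf``, ``annotation_class`` and a
    boolean ``core`` column.  Within each annotation class, non-core
    variants are matched 1:1 to core variants on MAF; the fold change is
    median(|beta| core) / median(|beta| matched) with a two-sided Wilcoxon
    rank-sum p.  Classes with fewer than ``min_per_group`` variants in
    either group are skipped with a log entry.
    """
    rows = []
    skipped: list[str] = []
    for cls, sub in variants.groupby("annotation_class", sort=False):
        sub = sub.reset_index(drop=True)
        core_mask = sub["core"].to_numpy(dtype=bool)
        n_core, n_ctrl = int(core_mask.sum()), int((~core_mask).sum())
        if n_core < min_per_group or n_ctrl < n_core:
            logger.info("matched_effect_comparison: class %r skipped", cls)
            skipped.append(str(cls))
            continue
        ctrl = match_nearest(
            sub["maf"].to_numpy(), core_mask, ratio=1, seed=seed
        )
        if len(ctrl) < min_per_group:
            skipped.append(str(cls))
            continue
        core_b = sub.loc[core_mask, "abs_beta"].to_numpy()
        ctrl_b = sub.loc[ctrl, "abs_beta"].to_numpy()
        fc = float(np.median(core_b) / np.median(ctrl_b))
        p = float(stats.mannwhitneyu(core_b, ctrl_b, alternative="two-sided").pvalue)
        rows.append(
            {
                "annotation_class": cls,
                "n_core": n_core,
                "n_matched": len(ctrl),
                "fold_change": fc,
                "p": p,
            }
        )
    if not rows and skipped:
        raise ValueError("no annotation class passes the minimum group size")
    return EffectComparisonResult(per_class=pd.DataFrame(rows), skipped=skipped)


@dataclass
class TransEqtlEnrichmentResult:
    fold: float
    p: float
    core_counts: np.ndarray
    matched_counts: np.ndarray


def trans_eqtl_enrichment(
    eqtls: TransEqtlTable,
    core_genes: set[str],
    seed: int = 0,
) -> TransEqtlEnrichmentResult:
    """Enrichment of core genes as trans-eQTL targets, after matching.

    Non-core genes are matched to core genes on rank-inverse-normalized
    median expression and mean eQTL |Z| (genes with no records get the
    overall mean |Z|), then per-gene record counts are compared by Wilcoxon
    rank-sum; the fold is the ratio of mean counts.
    """
    genes = list(eqtls.expression.index)
    counts = (
        eqtls.records.groupby("gene")["variant"].count().reindex(genes).fillna(0)
    )
    if (counts > 0).sum() < 2:
        raise ValueError("degenerate eQTL table: all records target one gene")
    meanz = (
        eqtls.records.assign(absz=lambda d: d["z"].abs())
        .groupby("gene")["absz"]
        .mean()
        .reindex(genes)
    )
    meanz = meanz.fillna(float(eqtls.records["z"].abs().mean()))
    expr_int = inverse_normal_transform(eqtls.expression.to_numpy())
    covars = np.column_stack([expr_int, meanz.to_numpy()])
    core_mask = np.array([g in core_genes for g in genes])
    if not core_mask.any() or core_mask.all():
        raise ValueError("need both core and non-core genes")
    matched = match_nearest(covars, core_mask, ratio=1, seed=seed)
    core_counts = counts.to_numpy()[core_mask]
    matched_counts = counts.to_numpy()[matched]
    denom = matched_counts.mean()
    fold = float(core_counts.mean() / denom) if denom > 0 else np.inf
    p = float(
        stats.mannwhitneyu(core_counts, matched_counts, alternative="greater").pvalue
    )
    return TransEqtlEnrichmentResult(
        fold=fold, p=p, core_counts=core_counts, matched_counts=matched_counts
    )


def neighbor_set(
    network: GeneNetwork, core_genes: set[str], degree: int, cutoff: float
) -> set[str]:
    """Genes within graph distance <= degree of any core gene at the cutoff
    (core genes themselves excluded)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    adj = network.adjacency(cutoff)
    core_mask = np.array([g in core_genes for g in network.genes])
    reach = adj[core_mask].any(axis=0)
    if degree == 2:
        reach = reach | adj[reach].any(axis=0)
    reach &= ~core_mask
    return {g for g, r in zip(network.genes, reach) if r}


def neighbor_enrichment(
    network: GeneNetwork,
    core_genes: set[str],
    query: set[str],
    degree: int = 1,
    cutoff: float = 0.3,
    n_perm: int = 1_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of a query gene set among network neighbors of the core."""
    nbrs = neighbor_set(network, core_genes, degree, cutoff)
    if not nbrs:
        raise ValueError("empty neighbor set at this cutoff")
    return overlap_enrichment(
        query=query,
        annotated=nbrs,
        universe=list(network.genes),
        n_perm=n_perm,
        seed=seed,
    )
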