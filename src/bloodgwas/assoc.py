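"""Single-variant association, harmonization, QC, and fixed-effects meta.

Summary statistics follow a GWAS-SSF-like tabular layout with columns
``variant_id, chrom, pos, effect_allele, other_allele, eaf, info, beta, se,
p, n``.  The association scan is ordinary least squares of the adjusted,
inverse-normalized phenotype on allele dosage (the synthetic cohorts are
unrelated, so a mixed model would reduce to OLS).  Cohorts are pooled with
the inverse-variance-weighted fixed-effects estimator.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

#: conditional-analysis genome-wide significance threshold
GENOME_WIDE_P = 8.31e-9
#: significance threshold used at the meta-analysis conditioning step
META_P = 5e-9

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "info",
    "beta",
    "se",
    "p",
    "n",
]

_VALID_ALLELE = frozenset("ACGT")


def harmonize_variant_id(chrom, pos, allele1: str, allele2: str) -> str:
    """Unique variant ID ``chrom:pos_A1_A2`` with deterministic allele order.

    Alleles are ordered shorter-first (indels) and lexicographically at equal
    length, so the ID is invariant to the allele order supplied.
    """
    a1, a2 = str(allele1).upper(), str(allele2).upper()
    for a in (a1, a2):
        if not a or not set(a) <= _VALID_ALLELE:
            raise ValueError(f"invalid allele {a!r}")
    if (len(a1), a1) > (len(a2), a2):
        a1, a2 = a2, a1
    return f"{chrom}:{pos}_{a1}_{a2}"


def qc_filter(
    stats_df: pd.DataFrame,
    info_max_excluded: float = 0.4,
    mac_max_excluded: float = 5.0,
) -> pd.DataFrame:
    """Remove variants failing imputation-quality or allele-count filters.

    A variant is dropped when INFO <= ``info_max_excluded`` or when its minor
    allele count MAC = 2*N*min(EAF, 1-EAF) <= ``mac_max_excluded`` (raise the
    MAC bound to 20 for designated large cohorts).
    """
    for col in ("eaf", "info", "n"):
        if col not in stats_df.columns:
            raise ValueError(f"missing column {col!r}")
        if stats_df[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
    eaf = stats_df["eaf"].to_numpy(dtype=float)
    mac = 2.0 * stats_df["n"].to_numpy(dtype=float) * np.minimum(eaf, 1.0 - eaf)
    keep = (stats_df["info"].to_numpy(dtype=float) > info_max_excluded) & (
        mac > mac_max_excluded
    )
    logger.info("qc_filter: %d of %d variants removed", (~keep).sum(), len(keep))
    return stats_df.loc[keep].reset_index(drop=True)


def allele_freq_check(
    cohort: pd.DataFrame, reference: pd.DataFrame, tolerance: float = 0.2
) -> pd.DataFrame:
    """Flag allele-frequency discordance against a reference panel.

    Both frames need ``variant_id``, ``effect_allele`` and ``eaf``; rows are
    matched on harmonized ID and effect allele, and a variant is discordant
    when |cohort EAF - reference EAF| > tolerance (typically a strand or
    allele flip).
    """
    merged = cohort.merge(
        reference[["variant_id", "effect_allele", "eaf"]],
        on=["variant_id", "effect_allele"],
        how="left",
        suffixes=("", "_ref"),
        validate="one_to_one",
    )
    if merged["eaf_ref"].isna().any():
        missing = merged.loc[merged["eaf_ref"].isna(), "variant_id"].tolist()
        raise ValueError(f"variants absent from reference: {missing[:5]}")
    diff = (merged["eaf"] - merged["eaf_ref"]).abs()
    out = merged[["variant_id", "eaf", "eaf_ref"]].copy()
    out["discordant"] = diff > tolerance
    logger.info(
        "allele_freq_check: %d of %d variants discordant",
        int(out["discordant"].sum()),
        len(out),
    )
    return out


def single_variant_scan(G: GenotypeMatrix, y: np.ndarray) -> pd.DataFrame:
    """Per-variant OLS of the adjusted phenotype on dosage.

    Returns summary statistics with two-sided p-values from the t
    distribution (df = n - 2).  Monomorphic variants are skipped with a log
    entry rather than reported.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if y.shape[0] != n:
        raise ValueError("phenotype and genotype sample counts differ")
    gc = G.dosages - G.dosages.mean(axis=0)
    yc = y - y.mean()
    sg2 = np.einsum("ij,ij->j", gc, gc)
    poly = sg2 > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("single_variant_scan: %d monomorphic variants skipped", n_mono)
    sgy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(poly, sgy / np.where(poly, sg2, 1.0), np.nan)
        rss = syy - beta**2 * sg2
        sigma2 = rss / (n - 2)
        se = np.sqrt(np.where(poly, sigma2 / np.where(poly, sg2, 1.0), np.nan))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = G.variants.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    return out.loc[poly, SUMMARY_COLUMNS].reset_index(drop=True)


def _orient_to(
    df: pd.DataFrame, effect: pd.Series, other: pd.Series
) -> pd.DataFrame:
    """Flip beta sign and EAF where the stated effect allele is swapped."""
    out = df.copy()
    same = out["effect_allele"].to_numpy() == effect.to_numpy()
    flipped = (out["effect_allele"].to_numpy() == other.to_numpy()) & (
        out["other_allele"].to_numpy() == effect.to_numpy()
    )
    if not np.all(same | flipped):
        raise ValueError("allele mismatch between cohorts for shared variant")
    out.loc[flipped, "beta"] = -out.loc[flipped, "beta"]
    if "eaf" in out.columns:
        out.loc[flipped, "eaf"] = 1.0 - out.loc[flipped, "eaf"]
    out.loc[flipped, ["effect_allele", "other_allele"]] = np.column_stack(
        [other[flipped], effect[flipped]]
    )
    return out


def meta_fixed_effects(cohorts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Each cohort frame must carry ``variant_id, effect_allele, other_allele,
    beta, se, n`` (``eaf`` optional).  Effect alleles are harmonized to the
    first cohort listing each variant, with beta sign and EAF flipped as
    needed.  Pooled: w_i = 1/SE_i^2, beta = sum(w_i b_i)/sum(w_i),
    SE = sum(w_i)^{-1/2}, p = 2*Phi(-|beta/SE|), N = sum(N_i).
    """
    if len(cohorts) == 0:
        raise ValueError("need at least one cohort")
    for df in cohorts:
        if (df["se"] <= 0).any():
            raise ValueError("standard errors must be positive")

    ref: dict[str, tuple[str, str]] = {}
    frames = []
    for df in cohorts:
        df = df.copy()
        for vid, ea, oa in zip(
            df["variant_id"], df["effect_allele"], df["other_allele"]
        ):
            ref.setdefault(vid, (ea, oa))
        target = df["variant_id"].map(ref)
        df = _orient_to(
            df,
            target.str.get(0),
            target.str.get(1),
        )
        frames.append(df)
    allstats = pd.concat(frames, ignore_index=True)
    w = 1.0 / allstats["se"] ** 2
    allstats["_w"] = w
    allstats["_wb"] = w * allstats["beta"]

    grouped = allstats.groupby("variant_id", sort=False)
    pooled = grouped.agg(
        chrom=("chrom", "first") if "chrom" in allstats else ("variant_id", "first"),
        pos=("pos", "first") if "pos" in allstats else ("variant_id", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        n=("n", "sum"),
    )
    if "eaf" in allstats.columns:
        # sample-size weighted pooled frequency
        allstats["_nf"] = allstats["n"] * allstats["eaf"]
        pooled["eaf"] = grouped["_nf"].sum() / pooled["n"]
    pooled["beta"] = pooled["_wb"] / pooled["_w"]
    pooled["se"] = np.sqrt(1.0 / pooled["_w"])
    z = pooled["beta"] / pooled["se"]
    pooled["p"] = 2.0 * stats.norm.sf(np.abs(z))
    pooled = pooled.drop(columns=["_w", "_wb"]).reset_index()
    return pooled


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
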