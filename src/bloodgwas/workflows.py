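"""End-to-end pipeline helpers: scan -> conditional -> fine-map -> score.

These orchestrate the per-module operations into the workflows a discovery
analysis actually runs, and provide the sparse-architecture cohort builder
used by the recovery and calibration batteries (causal effects sized on the
marginal z scale from realized allele frequencies, so the detection regime
is controlled rather than left to the frequency draw).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, conditional, finemap
from .simulate import (
    GenotypeMatrix,
    SimConfig,
    SimulatedPhenotype,
    simulate_genotypes,
    simulate_phenotype,
)


def beta_for_z(z: float, eaf: float, n: int) -> float:
    """Per-allele effect size giving expected marginal z-score ``z``."""
    return z / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


@dataclass
class SparseCohort:
    G: GenotypeMatrix
    phenotype: SimulatedPhenotype
    causal_indices: list[int]
    causal_betas: list[float]


def simulate_sparse_cohort(
    n_samples: int,
    n_variants: int,
    causal_positions: list[int],
    target_z: float | None = None,
    variance_per_causal: float | None = None,
    ld_block_span: int = 25,
    h2_polygenic: float = 0.0,
    seed: int = 0,
    locus_seed: int | None = None,
    alternate_signs: bool = True,
) -> SparseCohort:
    """Cohort with causal effects sized from realized allele frequencies.

    Either ``target_z`` (expected marginal z per causal) or
    ``variance_per_causal`` (phenotypic variance fraction per causal) fixes
    the effect scale.  Genotypes are drawn first so the realized frequency
    of each causal variant determines its beta; requested causal positions
    falling on rare or monomorphic variants (the founder pool can lose a
    low-frequency allele) are remapped to the nearest common variant
    (EAF in [0.1, 0.9]) so the causal architecture is the common-variant
    one the detection batteries assume.
    """
    base = SimConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        ld_block_span=ld_block_span,
        seed=seed,
        locus_seed=locus_seed,
    )
    G = simulate_genotypes(base)
    eaf = G.variants["eaf"].to_numpy()
    common = np.flatnonzero((eaf >= 0.1) & (eaf <= 0.9))
    if len(common) == 0:
        raise ValueError("no common variants generated")
    placed: list[int] = []
    for i in causal_positions:
        if not (0.1 <= eaf[i] <= 0.9) or i in placed:
            cand = common[~np.isin(common, placed)]
            i = int(cand[np.argmin(np.abs(cand - i))])
        placed.append(int(i))
    causal_positions = placed
    betas: list[float] = []
    for k, i in enumerate(causal_positions):
        p = float(eaf[i])
        if target_z is not None:
            b = beta_for_z(target_z, p, n_samples)
        elif variance_per_causal is not None:
            b = np.sqrt(variance_per_causal / (2.0 * p * (1.0 - p)))
        else:
            raise ValueError("need target_z or variance_per_causal")
        if alternate_signs and k % 2 == 1:
            b = -b
        betas.append(float(b))
    cfg = SimConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        ld_block_span=ld_block_span,
        causal_spec=list(zip(causal_positions, betas)),
        h2_polygenic=h2_polygenic,
        seed=seed,
        locus_seed=locus_seed,
    )
    pheno = simulate_phenotype(G, cfg)
    return SparseCohort(
        G=G, phenotype=pheno, causal_indices=list(causal_positions),
        causal_betas=betas,
    )


@dataclass
class ConditionalAnalysisResult:
    sentinels: pd.DataFrame  # joint-model estimates after refinement
    scan: pd.DataFrame
    selected_columns: list[int]  # column indices into G


def conditional_analysis(
    G: GenotypeMatrix,
    y: np.ndarray,
    p_thresh: float = assoc.GENOME_WIDE_P,
) -> ConditionalAnalysisResult:
    """Scan, partition significant variants into blocks, run stepwise
    selection per block, and refine jointly per chromosome."""
    scan = assoc.single_variant_scan(G, y)
    sig = scan[scan["p"] < p_thresh]
    col_of = {v: i for i, v in enumerate(G.variants["variant_id"])}
    if sig.empty:
        return ConditionalAnalysisResult(
            sentinels=scan.iloc[0:0], scan=scan, selected_columns=[]
        )
    blocks = conditional.partition_blocks(sig.reset_index(drop=True))
    selected: dict[str, list[int]] = {}
    for blk in blocks:
        ids = sig.reset_index(drop=True).loc[blk.indices, "variant_id"]
        cols = [col_of[v] for v in ids]
        sub = GenotypeMatrix(
            G.dosages[:, cols], G.variants.iloc[cols].reset_index(drop=True)
        )
        res = conditional.stepwise_select(sub, y, p_thresh=p_thresh)
        selected.setdefault(blk.chrom, []).extend(cols[j] for j in res.selected)

    all_cols: list[int] = []
    tables = []
    for chrom, cols in selected.items():
        if not cols:
            continue
        sub = GenotypeMatrix(
            G.dosages[:, cols], G.variants.iloc[cols].reset_index(drop=True)
        )
        ref = conditional.chromosome_joint_refine(sub, y, list(range(len(cols))))
        all_cols.extend(cols[j] for j in ref.selected)
        tables.append(ref.table)
    sentinels = (
        pd.concat(tables, ignore_index=True) if tables else scan.iloc[0:0]
    )
    return ConditionalAnalysisResult(
        sentinels=sentinels, scan=scan, selected_columns=sorted(all_cols)
    )


def finemap_region(
    G: GenotypeMatrix,
    scan: pd.DataFrame,
    region: finemap.Region,
    n: int,
    K: int | None = None,
    s: float = finemap.PRIOR_SD,
) -> finemap.FineMapResult:
    """Fine-map one region from the scan z-scores and in-sample LD."""
    in_region = scan[
        (scan["chrom"].astype(str) == region.chrom)
        & (scan["pos"] >= region.start)
        & (scan["pos"] <= region.end)
    ].reset_index(drop=True)
    if in_region.empty:
        raise ValueError("no scanned variants in region")
    col_of = {v: i for i, v in enumerate(G.variants["variant_id"])}
    cols = [col_of[v] for v in in_region["variant_id"]]
    gstd = GenotypeMatrix(
        G.dosages[:, cols], G.variants.iloc[cols].reset_index(drop=True)
    ).standardized()
    R = (gstd.T @ gstd) / gstd.shape[0]
    z = (in_region["beta"] / in_region["se"]).to_numpy()
    return finemap.enumerate_posteriors(
        z, R, K=K if K is not None else region.k, s=s, n=n,
        variant_ids=in_region["variant_id"].tolist(),
    )
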