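"""Exact stepwise conditional analysis and LD clumping.

The genome-wide-significant variants of a trait are partitioned into blocks
(split at every inter-variant gap of at least 5 Mb, each block capped at
2,500 variants), and within each block a parsimonious set of conditionally
independent variants is found by a stepwise multiple linear regression with
alternating addition and removal stages at a fixed t-test threshold
(8.31e-9).  Candidates in high LD (r^2 > 0.9) with a model member are never
tested for addition.  Block selections are then merged per chromosome and
the algorithm resumed at the removal stage.  Finally, sentinels are grouped
into loci by greedy LD clumping with between-tag r^2 <= 0.8.

All linear algebra runs on centered Gram matrices, so each candidate test is
a small solve rather than a full regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import GENOME_WIDE_P
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

MAX_BLOCK_SIZE = 2500
BLOCK_GAP_BP = 5_000_000
LD_SKIP_R2 = 0.9
CLUMP_R2 = 0.8
_MAX_ITER = 1000


@dataclass
class Block:
    """Contiguous set of significant variants analysed jointly."""

    chrom: str
    indices: list[int]  # row positions into the originating variant table
    positions: list[int]

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]


def _split_oversized(indices: list[int], positions: list[int], max_size: int):
    """Recursively split a block at its largest internal gap until all
    pieces respect the size cap."""
    if len(indices) <= max_size:
        return [(indices, positions)]
    gaps = np.diff(positions)
    cut = int(np.argmax(gaps)) + 1
    left = _split_oversized(indices[:cut], positions[:cut], max_size)
    right = _split_oversized(indices[cut:], positions[cut:], max_size)
    return left + right


def partition_blocks(
    variants: pd.DataFrame,
    gap: float = BLOCK_GAP_BP,
    max_size: int = MAX_BLOCK_SIZE,
) -> list[Block]:
    """Split significant variants into the largest number of blocks such
    that distinct blocks are separated by at least ``gap`` bp.

    ``variants`` needs ``chrom`` and ``pos`` columns, position-sorted within
    each chromosome (unsorted input raises).  Any block exceeding
    ``max_size`` is further split at its largest internal gaps.
    """
    blocks: list[Block] = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
        rows = list(sub.index)
        splits = np.flatnonzero(np.diff(pos) >= gap) + 1
        for piece_rows, piece_pos in zip(
            np.split(np.array(rows), splits), np.split(pos, splits)
        ):
            for idx, p in _split_oversized(
                list(piece_rows), list(piece_pos), max_size
            ):
                blocks.append(Block(chrom=str(chrom), indices=idx, positions=p))
    return blocks


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Selected variants of one block with their joint-model estimates."""

    selected: list[int]  # column indices into the block genotype matrix
    table: pd.DataFrame  # variant_id, chrom, pos, beta, se, p, iteration_added
    n_iterations: int = 0
    provenance: dict[int, int] = field(default_factory=dict)


class _GramModel:
    """Joint-regression bookkeeping on centered cross-products."""

    def __init__(self, G: GenotypeMatrix, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("phenotype is constant")
        gc = G.dosages - G.dosages.mean(axis=0)
        yc = y - y.mean()
        self.n = G.n_samples
        self.gram = gc.T @ gc
        self.gy = gc.T @ yc
        self.yy = float(yc @ yc)
        diag = np.diag(self.gram).copy()
        self.diag = diag
        self.poly = diag > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(np.outer(diag, diag))
            r = np.where(denom > 0, self.gram / denom, 0.0)
        self.r2 = r**2

    def univariable(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(self.poly, self.gy / np.where(self.poly, self.diag, 1), 0)
            rss = self.yy - beta**2 * self.diag
            sigma2 = rss / (self.n - 2)
            se = np.sqrt(np.where(self.poly, sigma2 / np.where(self.poly, self.diag, 1), np.inf))
        t = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df=self.n - 2)
        p[~self.poly] = 1.0
        return p, beta

    def fit(self, members: list[int]):
        """Joint OLS on ``members``; returns (beta, se, p) arrays.

        Rank-deficient member sets (perfectly collinear variants) fall back
        to the pseudoinverse, which inflates the collinear coefficients'
        p-values and lets the removal stage resolve the redundancy.
        """
        k = len(members)
        A = self.gram[np.ix_(members, members)]
        b = self.gy[members]
        try:
            coef = np.linalg.solve(A, b)
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
            coef = Ainv @ b
        rss = max(self.yy - coef @ b, 0.0)
        df = self.n - k - 1
        if df <= 0:
            raise ValueError("model larger than sample size")
        sigma2 = rss / df
        var = sigma2 * np.clip(np.diag(Ainv), 0.0, None)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, coef / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
        return coef, se, p


def _removal_stage(model: _GramModel, members: list[int], p_thresh: float) -> list[int]:
    """Steps 5-8: repeatedly drop the member with the largest drop-one p
    while that p is at or above the threshold."""
    members = list(members)
    while len(members) > 0:
        _, _, p = model.fit(members)
        worst = int(np.argmax(p))
        if p[worst] < p_thresh:
            break
        dropped = members.pop(worst)
        logger.debug("removal: dropped variant %d (p=%.3g)", dropped, p[worst])
    return members


def stepwise_select(
    G: GenotypeMatrix,
    y: np.ndarray,
    p_thresh: float = GENOME_WIDE_P,
    ld_skip_r2: float = LD_SKIP_R2,
) -> StepwiseResult:
    """Greedy add/remove stepwise regression on one block.

    The model is seeded with the variant of lowest univariable p (an empty
    model is returned if even that variant misses the threshold, which is
    the relevant behaviour when blocks are not pre-filtered to significant
    variants).  Addition candidates in LD r^2 > ``ld_skip_r2`` with any
    model member are skipped; after every addition the removal stage prunes
    members whose drop-one p reaches the threshold.  Convergence: no
    candidate addition attains the threshold.
    """
    if G.n_variants == 0:
        raise ValueError("empty block")
    model = _GramModel(G, y)
    if not model.poly.any():
        logger.info("stepwise_select: all variants monomorphic")
        return StepwiseResult(selected=[], table=_empty_table(), n_iterations=0)

    pos = G.variants["pos"].to_numpy()
    univ_p, _ = model.univariable()
    order = np.lexsort((pos, univ_p))
    best = int(order[0])
    if univ_p[best] >= p_thresh:
        return StepwiseResult(selected=[], table=_empty_table(), n_iterations=0)

    members = [best]
    provenance = {best: 0}
    candidates = np.flatnonzero(model.poly)
    prev_rss = np.inf
    iteration = 0
    while True:
        iteration += 1
        if iteration > _MAX_ITER:
            raise RuntimeError("stepwise selection failed to converge")
        best_p, best_cand = np.inf, None
        member_set = set(members)
        for v in candidates:
            if v in member_set:
                continue
            if np.any(model.r2[v, members] > ld_skip_r2):
                continue
            trial = members + [int(v)]
            _, _, p = model.fit(trial)
            pv = p[-1]
            if (pv, pos[v]) < (best_p, pos[best_cand] if best_cand is not None else np.inf):
                best_p, best_cand = pv, int(v)
        if best_cand is None or best_p > p_thresh:
            break
        members.append(best_cand)
        provenance[best_cand] = iteration
        coef, _, _ = model.fit(members)
        rss = model.yy - coef @ model.gy[members]
        if rss >= prev_rss:
            raise RuntimeError("residual sum of squares failed to decrease")
        prev_rss = rss
        members = _removal_stage(model, members, p_thresh)

    table = _joint_table(G, model, members)
    return StepwiseResult(
        selected=members,
        table=table,
        n_iterations=iteration,
        provenance={m: provenance.get(m, -1) for m in members},
    )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["variant_id", "chrom", "pos", "beta", "se", "p"]
    )


def _joint_table(
    G: GenotypeMatrix, model: _GramModel, members: list[int]
) -> pd.DataFrame:
    if not members:
        return _empty_table()
    beta, se, p = model.fit(members)
    meta = G.variants.iloc[members]
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"].to_numpy(),
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
        }
    )


def chromosome_joint_refine(
    G: GenotypeMatrix,
    y: np.ndarray,
    selected: list[int],
    p_thresh: float = GENOME_WIDE_P,
) -> StepwiseResult:
    """Place all block selections of a chromosome in one joint model and
    resume the stepwise algorithm at the removal stage.

    After removals converge there are no candidates outside the model, so
    the addition stage is vacuous and the surviving set is refit and
    returned.  Duplicate indices raise.
    """
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate variant indices in chromosome-level model")
    if not selected:
        return StepwiseResult(selected=[], table=_empty_table())
    model = _GramModel(G, y)
    members = _removal_stage(model, list(selected), p_thresh)
    return StepwiseResult(selected=members, table=_joint_table(G, model, members))


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    sentinels: pd.DataFrame,
    G_ref: GenotypeMatrix,
    r2_max_between_tags: float = CLUMP_R2,
) -> pd.DataFrame:
    """Group sentinels into loci by greedy LD clumping.

    Sentinels (columns ``variant_id`` and ``p``) are ordered by p; the best
    remaining sentinel becomes a tag, any remaining sentinel with LD
    r^2 > ``r2_max_between_tags`` to that tag joins its locus, and the
    procedure recurses.  By construction all between-tag r^2 are below the
    bound.  Sentinels absent from the LD reference raise.
    """
    col_of = {v: i for i, v in enumerate(G_ref.variants["variant_id"])}
    missing = [v for v in sentinels["variant_id"] if v not in col_of]
    if missing:
        raise ValueError(f"sentinels absent from LD reference: {missing[:5]}")
    idx = [col_of[v] for v in sentinels["variant_id"]]
    r2 = G_ref.ld_r2(idx)

    order = np.lexsort((np.arange(len(sentinels)), sentinels["p"].to_numpy()))
    locus = np.full(len(sentinels), -1, dtype=int)
    is_tag = np.zeros(len(sentinels), dtype=bool)
    next_locus = 0
    for i in order:
        if locus[i] != -1:
            continue
        locus[i] = next_locus
        is_tag[i] = True
        mates = np.flatnonzero((locus == -1) & (r2[i] > r2_max_between_tags))
        locus[mates] = next_locus
        next_locus += 1
    out = sentinels.copy().reset_index(drop=True)
    out["locus"] = locus
    out["is_tag"] = is_tag
    return out
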