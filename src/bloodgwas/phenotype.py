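"""Phenotype exclusions, derived traits, covariate adjustment, rank-INT.

Blood-count phenotypes are cleaned of clinically implausible extreme values,
white-cell subtype counts are derived from the total count and subtype
percentages, and each trait is regressed on covariates (age, age squared,
sex, principal components) with the residuals mapped to normal scores by a
rank-based inverse-normal transform before any association testing.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: extreme-measurement exclusion thresholds (trait units as named)
EXTREME_LIMITS: dict[str, float] = {
    "WBC": 200.0,   # 10^9 cells/L
    "HGB": 20.0,    # g/dL
    "HCT": 60.0,    # %
    "PLT": 1000.0,  # 10^9 cells/L
}

#: rank offset of the Blom normal-score convention
BLOM_OFFSET = 3.0 / 8.0

#: traits that are log10-transformed before covariate regression
LOG10_TRAITS = frozenset(
    {"WBC", "NEUT", "LYMPH", "MONO", "EO", "BASO"}
)


def apply_extreme_filters(
    table: pd.DataFrame, limits: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Flag samples whose measurements exceed clinical plausibility limits.

    Returns a copy of ``table`` with a boolean ``excluded`` column; samples
    exceeding any threshold present in the table are flagged, all others
    retained.  Traits named in ``limits`` but absent from the table raise
    ``KeyError``; negative measurements raise ``ValueError``.
    """
    limits = dict(EXTREME_LIMITS if limits is None else limits)
    out = table.copy()
    excluded = np.zeros(len(out), dtype=bool)
    for trait, limit in limits.items():
        if trait not in out.columns:
            raise KeyError(f"trait column {trait!r} not in table")
        vals = out[trait].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"negative values in trait {trait!r}")
        excluded |= vals > limit
    out["excluded"] = excluded
    n_excl = int(excluded.sum())
    logger.info(
        "extreme-value filter: %d of %d samples excluded", n_excl, len(out)
    )
    return out


def derive_subtype_counts(wbc_total, proportion):
    """Absolute subtype count = total white cell count x subtype proportion.

    Both arguments may be scalars or aligned arrays; proportion must lie in
    [0, 1] (a percentage should be divided by 100 first).
    """
    prop = np.asarray(proportion, dtype=float)
    if np.any((prop < 0) | (prop > 1)):
        raise ValueError("proportion must be in [0, 1]")
    result = np.asarray(wbc_total, dtype=float) * prop
    return result.item() if result.ndim == 0 else result


def inverse_normal_transform(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal (Blom) scores.

    z_i = Phi^{-1}((r_i - offset) / (n - 2*offset + 1)) with r_i the
    tie-averaged rank.  Requires at least 3 finite, not-all-equal values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array")
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 3 finite values")
    if np.all(x == x[0]):
        raise ValueError("all values equal; cannot rank-transform")
    ranks = stats.rankdata(x, method="average")
    q = (ranks - offset) / (x.size - 2.0 * offset + 1.0)
    return stats.norm.ppf(q)


def adjust_and_normalize(
    table: pd.DataFrame,
    trait: str,
    covariates: Sequence[str],
    log10_flag: bool = False,
) -> np.ndarray:
    """Covariate-adjust a trait and inverse-normalize the residuals.

    The trait (log10-transformed when flagged, as for the white-cell traits)
    is regressed on the covariate columns by OLS; residuals are mapped to
    normal scores and re-standardized so the output has mean 0 and unit
    variance to numerical precision.
    """
    y = table[trait].to_numpy(dtype=float)
    if log10_flag:
        if np.any(y <= 0):
            raise ValueError("log10 transform requires positive trait values")
        y = np.log10(y)
    if np.ptp(y) == 0:
        raise ValueError("constant trait")
    if covariates:
        X = np.column_stack(
            [np.ones(len(y))] + [table[c].to_numpy(dtype=float) for c in covariates]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    else:
        resid = y - y.mean()
    if np.ptp(resid) < 1e-12:
        raise ValueError("constant residuals; cannot rank-transform")
    z = inverse_normal_transform(resid)
    return (z - z.mean()) / z.std()
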