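"""Discovery-saturation models: how GWAS yield grows with sample size.

Four candidate growth curves are least-squares fit to (sample size, yield)
points, where the yield is a discovery count (variants, genes, loci) or the
heritability explained:

    linear       y = a + b*x
    sqrt         y = a + b*sqrt(x)
    sqrt+linear  y = a + b*sqrt(x) + c*x
    log          y = a + b*log(x)

The best form is chosen by the small-sample-corrected Akaike criterion
(AICc); with exactly four points the three-parameter sqrt+linear form is
not selectable (its correction term diverges), which guards against the
near-saturated model winning trivially.  For comparison with the observed
trend, projections also report the straight line through the first three
points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODEL_FORMS = ("linear", "sqrt", "sqrt+linear", "log")


def _design(form: str, x: np.ndarray) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(x), x])
    if form == "sqrt":
        return np.column_stack([np.ones_like(x), np.sqrt(x)])
    if form == "sqrt+linear":
        return np.column_stack([np.ones_like(x), np.sqrt(x), x])
    if form == "log":
        return np.column_stack([np.ones_like(x), np.log(x)])
    raise ValueError(f"unknown model form {form!r}")


def _aicc(rss: float, n: int, k: int) -> float:
    """AICc for Gaussian least squares; +inf when the correction denominator
    is non-positive (saturated model)."""
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class SaturationFit:
    """All four candidate fits plus the selected form."""

    x: np.ndarray
    y: np.ndarray
    coefficients: dict[str, np.ndarray]
    rss: dict[str, float]
    aicc: dict[str, float]
    selected: str

    def predict(self, form: str, x_new) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        if np.any(x_new <= 0):
            raise ValueError("sample sizes must be positive")
        return _design(form, x_new) @ self.coefficients[form]


def fit_saturation_models(x, y) -> SaturationFit:
    """Fit all four growth forms and select the best by AICc.

    Requires at least four strictly increasing positive sample sizes.  Ties
    in AICc go to the form with fewer parameters, then to the listed order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 (sample size, yield) points")
    if np.any(x <= 0):
        raise ValueError("sample sizes must be positive")
    if np.any(np.diff(x) <= 0):
        raise ValueError("sample sizes must be strictly increasing")

    coefficients: dict[str, np.ndarray] = {}
    rss: dict[str, float] = {}
    aicc: dict[str, float] = {}
    for form in MODEL_FORMS:
        X = _design(form, x)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        coefficients[form] = coef
        rss[form] = float(resid @ resid)
        aicc[form] = _aicc(rss[form], x.size, X.shape[1])

    selected = min(
        MODEL_FORMS,
        key=lambda f: (aicc[f], len(coefficients[f]), MODEL_FORMS.index(f)),
    )
    return SaturationFit(
        x=x, y=y, coefficients=coefficients, rss=rss, aicc=aicc, selected=selected
    )


@dataclass
class Projection:
    predicted: float
    linear_first3: float  # straight-line projection through the first 3 points
    form: str


def project_discovery(fit: SaturationFit, n_new: float) -> Projection:
    """Evaluate the selected model at a new sample size.

    Also reports the linear projection through the first three observed
    points, the reference line a reader compares the fitted curve against.
    """
    if n_new <= 0:
        raise ValueError("n_new must be positive")
    pred = float(fit.predict(fit.selected, n_new)[0])
    X3 = np.column_stack([np.ones(3), fit.x[:3]])
    coef3, *_ = np.linalg.lstsq(X3, fit.y[:3], rcond=None)
    lin3 = float(coef3[0] + coef3[1] * n_new)
    return Projection(predicted=pred, linear_first3=lin3, form=fit.selected)
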