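"""Regression, half-life and group-comparison statistics.

Divergence-versus-distance trends are summarised by ordinary least squares
in one of two forms: ``y = a*ln(x) + b`` (logarithmic, capturing the
saturation of raw pGOD) or ``y = a*x + b`` (linear, appropriate for the
corrected dGOD).  The *gene-order half-life* is the sequence distance at
which a fitted pGOD model reaches 0.5.  Group rate comparisons use one-way
ANOVA with Tukey HSD post hoc tests; two-group contrasts use the
equal-variance Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegressionModel",
    "GroupRates",
    "fit_divergence_model",
    "half_life",
    "rate_ratio",
    "compare_groups",
    "richness_correlation",
    "ttest_two_sample",
]

LOGARITHMIC = "logarithmic"
LINEAR = "linear"


@dataclass(frozen=True)
class RegressionModel:
    """Fitted divergence-versus-distance model.

    ``logarithmic`` predicts ``y = a*ln(x) + b`` (natural log);
    ``linear`` predicts ``y = a*x + b``.
    """

    kind: str
    a: float
    b: float
    r2: float = np.nan

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        t = np.log(x) if self.kind == LOGARITHMIC else x
        return self.a * t + self.b


@dataclass
class GroupRates:
    """Divergence rates of one lineage (subphylum, class or clade)."""

    group_id: str
    rates: list[float]

    @property
    def median(self) -> float:
        return float(np.median(self.rates))

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def sd(self) -> float:
        return float(np.std(self.rates, ddof=1)) if len(self.rates) > 1 else 0.0


def fit_divergence_model(
    points: list[tuple[float, float]] | np.ndarray, kind: str = LOGARITHMIC
) -> RegressionModel:
    """OLS fit of divergence against sequence distance.

    For the logarithmic kind the predictor is ``ln(x)``; distances must be
    positive.  Constant ``y`` yields a zero slope with ``r2 = 0``.
    """
    if kind not in (LOGARITHMIC, LINEAR):
        raise ValueError(f"unknown model kind {kind!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (distance, divergence) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValueError("sequence distances must be positive")
    t = np.log(x) if kind == LOGARITHMIC else x
    if np.ptp(t) == 0:
        raise ValueError("degenerate predictor: all distances equal")
    if np.ptp(y) == 0:
        return RegressionModel(kind, 0.0, float(y[0]), 0.0)
    fit = sps.linregress(t, y)
    return RegressionModel(kind, float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def half_life(model: RegressionModel, target: float = 0.5) -> float:
    """Sequence distance at which the fitted pGOD model reaches ``target``.

    Logarithmic models solve ``exp((target - b) / a)``, linear models
    ``(target - b) / a``.
    """
    if model.a == 0:
        raise ValueError("zero slope: the model never reaches the target")
    if model.kind == LOGARITHMIC:
        x = float(np.exp((target - model.b) / model.a))
    else:
        x = (target - model.b) / model.a
    if x <= 0:
        raise ValueError(f"half-life {x} is not a positive distance")
    return float(x)


def rate_ratio(model_a: RegressionModel, model_b: RegressionModel) -> float:
    """Ratio of the slopes of two linear dGOD-versus-distance models."""
    if model_b.a == 0:
        raise ValueError("denominator model has zero slope")
    return float(model_a.a / model_b.a)


def compare_groups(groups: list[GroupRates]) -> dict:
    """One-way ANOVA plus Tukey HSD over lineage rate groups.

    Returns ``{"anova_F", "anova_p", "tukey": {(g1, g2): adj_p}}``.
    Identical constant groups (zero variance everywhere) are reported as
    F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g.rates) < 2:
            raise ValueError(f"group {g.group_id!r} has fewer than 2 values")
    samples = [np.asarray(g.rates, dtype=float) for g in groups]
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return {
            "anova_F": 0.0,
            "anova_p": 1.0,
            "tukey": {
                (a.group_id, b.group_id): 1.0
                for i, a in enumerate(groups)
                for b in groups[i + 1 :]
            },
        }
    F, p = sps.f_oneway(*samples)
    labels = np.concatenate(
        [[g.group_id] * len(g.rates) for g in groups]
    )
    hsd = pairwise_tukeyhsd(pooled, labels)
    tukey = {
        (str(r[0]), str(r[1])): float(r[3])
        for r in hsd.summary().data[1:]  # skip header row
    }
    return {"anova_F": float(F), "anova_p": float(p), "tukey": tukey}


def richness_correlation(classes: list[tuple[float, float]]) -> float:
    """Pearson r between described-species counts and median rates."""
    arr = np.asarray(classes, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (species_count, median_rate) classes")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in species counts or rates")
    return float(sps.pearsonr(x, y).statistic)


def ttest_two_sample(x: list[float], y: list[float]) -> float:
    """Two-sided equal-variance Student's t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance with distinct means: p undefined")
    return float(sps.ttest_ind(x, y, equal_var=True).pvalue)
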