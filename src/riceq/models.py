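"""Eating-quality (IVOE) regression models.

The overall panel score (IVOE) is well approximated as a linear function
of a few component traits.  This module provides ordinary least-squares
fitting, exhaustive best-subset selection, application of the four
published prediction models, and calibration-style evaluation of
predictions against observed scores.

The four published models, with their reported fit R²:

* Model 1: IVOE = 0.20·viscosity + 0.35·appearance + 0.59·taste + 0.13 (R² 0.87)
* Model 2: IVOE = 0.27·adhesiveness + 0.40·appearance + 0.67·taste − 0.35 (R² 0.87)
* Model 3: IVOE = 0.27·viscosity − 0.57·yellow_area + 0.76·taste − 0.05 (R² 0.86)
* Model 4: IVOE = 0.37·adhesiveness − 0.71·yellow_area + 0.89·taste − 0.34 (R² 0.85)

Sensory traits (viscosity, appearance, taste) are on the −3..+3 panel
scale.  The source report does not state the scaling of the instrument
predictors; raw adhesiveness (hundreds of gf·s) or percent yellow area
would be dimensionally implausible against coefficients of order one on
a −3..+3 response, so the shipped constants annotate adhesiveness as
standardized (z-score within the measurement batch) and yellow area as a
fraction of the frame (0–1).  The annotations travel with each model so
feature tables can be checked against them before prediction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, InputError

MAX_EXHAUSTIVE_PREDICTORS = 20


@dataclass(frozen=True)
class RegressionModel:
    """A linear model: intercept + named coefficients, optional fit stats."""

    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    r2: float | None = None
    n_fit: int | None = None
    units: Mapping[str, str] = field(default_factory=dict)
    provenance: str | None = None

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.coefficients):
            raise ConfigError("coefficients must align one-to-one with predictors")
        object.__setattr__(self, "units", MappingProxyType(dict(self.units)))

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "r2": self.r2,
            "n_fit": self.n_fit,
            "units": dict(self.units),
            "provenance": self.provenance,
        }


_SENSORY_UNIT = "sensory score (-3..+3)"

MODEL1 = RegressionModel(
    predictors=("viscosity", "appearance", "taste"),
    coefficients=(0.20, 0.35, 0.59),
    intercept=0.13,
    r2=0.87,
    units={
        "viscosity": _SENSORY_UNIT,
        "appearance": _SENSORY_UNIT,
        "taste": _SENSORY_UNIT,
    },
    provenance="published model 1 (sensory predictors only), 322-variety Geng panel",
)

MODEL2 = RegressionModel(
    predictors=("adhesiveness", "appearance", "taste"),
    coefficients=(0.27, 0.40, 0.67),
    intercept=-0.35,
    r2=0.87,
    units={
        "adhesiveness": "standardized (z-score of gf·s within batch)",
        "appearance": _SENSORY_UNIT,
        "taste": _SENSORY_UNIT,
    },
    provenance="published model 2 (instrument adhesiveness), 322-variety Geng panel",
)

MODEL3 = RegressionModel(
    predictors=("viscosity", "yellow_area", "taste"),
    coefficients=(0.27, -0.57, 0.76),
    intercept=-0.05,
    r2=0.86,
    units={
        "viscosity": _SENSORY_UNIT,
        "yellow_area": "fraction of frame (0-1)",
        "taste": _SENSORY_UNIT,
    },
    provenance="published model 3 (image yellow area), 322-variety Geng panel",
)

MODEL4 = RegressionModel(
    predictors=("adhesiveness", "yellow_area", "taste"),
    coefficients=(0.37, -0.71, 0.89),
    intercept=-0.34,
    r2=0.85,
    units={
        "adhesiveness": "standardized (z-score of gf·s within batch)",
        "yellow_area": "fraction of frame (0-1)",
        "taste": _SENSORY_UNIT,
    },
    provenance="published model 4 (fully instrumented except taste), "
    "322-variety Geng panel",
)

MODELS: Mapping[str, RegressionModel] = MappingProxyType(
    {"model1": MODEL1, "model2": MODEL2, "model3": MODEL3, "model4": MODEL4}
)


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = list(X.columns)
    mat = X.to_numpy(float)
    if np.isnan(mat).any():
        raise InputError("predictor table contains missing values")
    return mat, cols


def fit_ols(X: pd.DataFrame, y) -> RegressionModel:
    """Ordinary least squares of y on the columns of X, with intercept.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    mat, cols = _design(X)
    yv = np.asarray(y, float)
    n, p = mat.shape
    if n <= p + 1:
        raise InputError(f"need n > p + 1 observations (n={n}, p={p})")
    const = [c for c in cols if np.ptp(X[c].to_numpy(float)) == 0]
    if const:
        raise InputError(f"constant predictor columns: {const}")
    design = sm.add_constant(mat, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(X)
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(yv, design).fit()
    return RegressionModel(
        predictors=tuple(cols),
        coefficients=tuple(float(b) for b in res.params[1:]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        n_fit=n,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Greedily identify columns that do not add rank."""
    bad = []
    kept: list[np.ndarray] = [np.ones(len(X))]
    for c in X.columns:
        v = X[c].to_numpy(float)
        trial = np.column_stack(kept + [v])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(c)
        else:
            kept.append(v)
    return bad


@dataclass(frozen=True)
class SubsetFit:
    model: RegressionModel
    size: int
    r2: float
    adj_r2: float
    bic: float


@dataclass(frozen=True)
class BestSubsetResult:
    """Best model per subset size plus the overall winner per criterion."""

    by_size: tuple[SubsetFit, ...]
    winner: SubsetFit
    criterion: str


def _fit_subset(mat: np.ndarray, yv: np.ndarray, cols: tuple[int, ...]) -> tuple:
    design = np.column_stack([np.ones(mat.shape[0]), mat[:, cols]])
    beta, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ beta
    rss = float(resid @ resid)
    tss = float(((yv - yv.mean()) ** 2).sum())
    n, k = design.shape
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else np.nan
    # Gaussian log-likelihood BIC, matching the usual regression convention
    bic = n * np.log(rss / n) + k * np.log(n) if rss > 0 else -np.inf
    return beta, r2, adj, bic


def best_subset(
    X: pd.DataFrame,
    y,
    criterion: str = "r2",
    max_size: int | None = None,
) -> BestSubsetResult:
    """Exhaustive best-subset selection over all non-empty predictor sets.

    For each subset size k the subset maximizing in-sample R² is kept
    (R² ranks subsets of equal size identically under any of the three
    criteria); the overall winner is chosen by ``criterion`` — "r2",
    "adj_r2" or "bic".  Note that plain R² is monotone in subset size, so
    its winner is always the full model; the adjusted criteria exist for
    exactly that reason.
    """
    if criterion not in ("r2", "adj_r2", "bic"):
        raise ConfigError(f"unknown criterion {criterion!r}")
    mat, cols = _design(X)
    yv = np.asarray(y, float)
    p = mat.shape[1]
    if p > MAX_EXHAUSTIVE_PREDICTORS:
        raise InputError(
            f"{p} predictors exceeds the exhaustive-enumeration bound of "
            f"{MAX_EXHAUSTIVE_PREDICTORS}"
        )
    max_size = p if max_size is None else min(max_size, p)
    by_size = []
    for k in range(1, max_size + 1):
        best = None
        for combo in itertools.combinations(range(p), k):
            beta, r2, adj, bic = _fit_subset(mat, yv, combo)
            if best is None or r2 > best[1]:
                best = (combo, r2, adj, bic, beta)
        combo, r2, adj, bic, beta = best
        model = RegressionModel(
            predictors=tuple(cols[i] for i in combo),
            coefficients=tuple(float(b) for b in beta[1:]),
            intercept=float(beta[0]),
            r2=float(r2),
            n_fit=mat.shape[0],
        )
        by_size.append(SubsetFit(model=model, size=k, r2=r2, adj_r2=adj, bic=bic))
    if criterion == "r2":
        winner = max(by_size, key=lambda s: s.r2)
    elif criterion == "adj_r2":
        winner = max(by_size, key=lambda s: s.adj_r2)
    else:
        winner = min(by_size, key=lambda s: s.bic)
    return BestSubsetResult(by_size=tuple(by_size), winner=winner, criterion=criterion)


def predict_ivoe(
    model: RegressionModel,
    features: Mapping[str, float] | pd.DataFrame,
    units: Mapping[str, str] | None = None,
):
    """Apply a linear model: intercept + coefficients · features.

    ``features`` may be a mapping (one prediction) or a DataFrame
    (vectorized over rows).  If ``units`` is given it is compared against
    the model's unit annotations and any mismatch is a hard error, so raw
    gf·s or percent values cannot silently meet standardized/fraction
    coefficients.
    """
    if units is not None:
        for name in model.predictors:
            declared = units.get(name)
            expected = model.units.get(name)
            if expected is not None and declared is not None and declared != expected:
                raise ConfigError(
                    f"unit mismatch for {name!r}: features declare {declared!r} "
                    f"but the model expects {expected!r}"
                )
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.predictors if c not in features.columns]
        if missing:
            raise InputError(f"feature table lacks predictor columns: {missing}")
        mat = features[list(model.predictors)].to_numpy(float)
        return pd.Series(
            mat @ np.asarray(model.coefficients) + model.intercept,
            index=features.index,
            name="predicted_ivoe",
        )
    missing = [c for c in model.predictors if c not in features]
    if missing:
        raise InputError(f"missing predictor values: {missing}")
    total = model.intercept
    for name, coef in zip(model.predictors, model.coefficients):
        total += coef * float(features[name])
    return total


@dataclass(frozen=True)
class EvaluationResult:
    """Calibration of predictions against observed scores.

    ``r2`` is the squared Pearson correlation between predicted and
    observed (affine-invariant), distinct from a fit-time coefficient of
    determination; the calibration line observed ≈ slope·predicted +
    intercept is reported alongside.
    """

    r: float | None
    r2: float | None
    slope: float | None
    intercept: float | None
    n: int
    flagged: str | None = None


def evaluate(predicted, observed) -> EvaluationResult:
    """Squared Pearson correlation and calibration line of predictions."""
    pv = np.asarray(predicted, float)
    ov = np.asarray(observed, float)
    if pv.shape != ov.shape or pv.ndim != 1:
        raise InputError("predicted and observed must be equal-length vectors")
    ok = ~(np.isnan(pv) | np.isnan(ov))
    pv, ov = pv[ok], ov[ok]
    n = pv.size
    if n < 3:
        raise InputError(f"need at least 3 pairs, got {n}")
    if np.ptp(pv) == 0 or np.ptp(ov) == 0:
        return EvaluationResult(
            r=None, r2=None, slope=None, intercept=None, n=n, flagged="zero variance"
        )
    r = float(np.corrcoef(pv, ov)[0, 1])
    slope, intercept = np.polyfit(pv, ov, 1)
    return EvaluationResult(
        r=r, r2=r * r, slope=float(slope), intercept=float(intercept), n=n
    )
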