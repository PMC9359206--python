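"""Treatment-response prediction by grid-searched, leave-one-out SVR.

Baseline (t1) variability values on the selected region pairs form the
feature matrix; the target is the per-subject remission ratio of a symptom
subscale.  For every (C, gamma) grid point a full leave-one-out loop is
run — features are z-scored with training-fold statistics only, so no
information about the held-out subject leaks into its prediction — and the
grid point with the smallest LOOCV mean squared error is selected (ties
prefer the smallest C, then the smallest gamma).  The model is evaluated by
the Pearson correlation between held-out predictions and actual values,
with a t-based p.  Target values more than two sample standard deviations
from the mean are excluded before fitting (single pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from dfcvar.group_stats import remission_ratio


@dataclass
class SvrConfig:
    """SVR kernel and hyperparameter search space."""

    kernel: str = "rbf"
    c_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-2, 5))
    gamma_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-4, 2))
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("grids must be nonempty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class PredictionResult:
    """LOOCV predictions and the selected hyperparameters."""

    predicted: np.ndarray
    actual: np.ndarray
    best_c: float
    best_gamma: float
    cv_mse: float
    r: float
    p: float
    subject_ids: list[str] = field(default_factory=list)
    excluded_subject_ids: list[str] = field(default_factory=list)


def exclude_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices kept/excluded by the two-standard-deviation rule.

    Mean and sample SD are computed once on the full vector; entries with
    ``|value - mean| > 2 SD`` are excluded.  No re-iteration.  A zero-SD
    vector excludes nothing.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError("need at least 3 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return np.arange(values.size), np.array([], dtype=int)
    out = np.abs(values - mean) > 2.0 * sd
    return np.flatnonzero(~out), np.flatnonzero(out)


def _loocv_predictions(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float, config: SvrConfig
) -> np.ndarray:
    n = X.shape[0]
    pred = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[train] - mu) / sd
        Xte = (X[i : i + 1] - mu) / sd
        model = SVR(kernel=config.kernel, C=c, gamma=gamma, epsilon=config.epsilon)
        model.fit(Xtr, y[train])
        pred[i] = model.predict(Xte)[0]
    return pred


def loocv_grid_svr(
    features: np.ndarray,
    target: np.ndarray,
    config: SvrConfig | None = None,
    subject_ids: list[str] | None = None,
) -> PredictionResult:
    """Grid-search SVR hyperparameters by leave-one-out cross-validation.

    Every grid point runs the full LOOCV loop; the point minimizing the
    held-out MSE wins (ties broken toward smaller C then smaller gamma, the
    smoother model).  The reported predictions, MSE, and r(predicted,
    actual) all belong to the winning grid point, so ``predicted[i]`` never
    saw subject i during training.
    """
    config = config or SvrConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be [n x q] aligned with target")
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    if np.allclose(y.std(), 0.0):
        raise ValueError("constant target cannot be predicted")
    gamma_grid = config.gamma_grid if config.kernel == "rbf" else (config.gamma_grid[0],)
    best: tuple[float, float, float, np.ndarray] | None = None
    for c in sorted(config.c_grid):
        for gamma in sorted(gamma_grid):
            pred = _loocv_predictions(X, y, c, gamma, config)
            mse = float(np.mean((pred - y) ** 2))
            if best is None or mse < best[0] - 1e-15:
                best = (mse, c, gamma, pred)
    assert best is not None
    mse, c, gamma, pred = best
    if np.std(pred) == 0:
        r, p = 0.0, 1.0
    else:
        rr = stats.pearsonr(pred, y)
        r, p = float(rr.statistic), float(rr.pvalue)
    return PredictionResult(
        predicted=pred,
        actual=y,
        best_c=c,
        best_gamma=gamma,
        cv_mse=mse,
        r=r,
        p=p,
        subject_ids=list(subject_ids or []),
    )


SUBSCALES = ("positive", "negative", "general", "total")


def predict_response_pipeline(
    baseline_features: np.ndarray,
    feature_subject_ids: list[str],
    cohort: pd.DataFrame,
    config: SvrConfig | None = None,
    subscales: tuple[str, ...] = SUBSCALES,
    exclude: bool = True,
) -> dict[str, PredictionResult]:
    """Predict each subscale's remission ratio from baseline variability.

    ``baseline_features`` is [n x q] (t1 variability on the selected pairs,
    one row per subject in ``feature_subject_ids``); remission ratios are
    computed from the cohort table, target outliers beyond 2 SD are excluded
    per subscale, and a grid-searched LOOCV SVR is fit per subscale.
    """
    X = np.asarray(baseline_features, dtype=float)
    results: dict[str, PredictionResult] = {}
    wide = cohort.pivot_table(
        index="subject_id", columns="timepoint", aggfunc="first"
    )
    for subscale in subscales:
        col = f"panss_{subscale}"
        t1 = wide[(col, "t1")].reindex(feature_subject_ids)
        t2 = wide[(col, "t2")].reindex(feature_subject_ids)
        if t1.isna().any() or t2.isna().any():
            raise ValueError(f"missing {col} scores for some feature subjects")
        rr = np.array(
            [remission_ratio(a, b) for a, b in zip(t1.to_numpy(), t2.to_numpy())]
        )
        if exclude:
            kept, dropped = exclude_outliers(rr)
        else:
            kept, dropped = np.arange(rr.size), np.array([], dtype=int)
        if kept.size < 5:
            raise ValueError(
                f"{subscale}: only {kept.size} subjects left after outlier exclusion"
            )
        res = loocv_grid_svr(
            X[kept],
            rr[kept],
            config,
            subject_ids=[feature_subject_ids[i] for i in kept],
        )
        res.excluded_subject_ids = [feature_subject_ids[i] for i in dropped]
        results[subscale] = res
    return results
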