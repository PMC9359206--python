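"""Group-level inference for longitudinal two-group variability outcomes.

The central test is the group x time interaction from a repeated-measures
ANCOVA with two timepoints.  With exactly two timepoints and subject
intercepts, the mixed-model interaction test is algebraically the
change-score GLM: regress the within-subject difference
``d = outcome_t2 - outcome_t1`` on group plus the between-subject
covariates (age, sex, illness duration, education, antipsychotic dosage);
the F-test on the group term is the interaction F.  Post-hoc contrasts are
paired t-tests within group (reported for t1 vs t2, so a decrease gives a
positive t) and two-sample t-tests between groups at each timepoint and
against a healthy reference.

Clinical change is summarized by the remission ratio
``RR = (score_t1 - score_t2) / score_t1`` and the relative variability
change ``(I_t2 - I_t1) / I_t1``; brain-behavior association uses partial
Spearman correlation (rank, residualize on covariates, correlate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dfcvar.variability import VariabilityMatrix

COVARIATE_COLUMNS = [
    "age_years",
    "sex01",
    "illness_duration_months",
    "education_years",
    "cpz_equiv_mg_per_day",
]


class DegenerateTestError(ValueError):
    """A contrast with zero variance cannot produce a t statistic."""


@dataclass(frozen=True)
class InteractionResult:
    """Group x time interaction F-test."""

    f_value: float
    p_value: float
    df: tuple[int, int]


@dataclass(frozen=True)
class TTestResult:
    t_value: float
    p_value: float
    df: float


@dataclass
class PosthocResult:
    """Post-hoc contrasts around a significant interaction."""

    paired_by_group: dict[str, TTestResult]
    between_groups: dict[str, TTestResult]
    vs_reference: dict[str, TTestResult]


def remission_ratio(score_t1: float, score_t2: float) -> float:
    """Normalized symptom improvement ``(t1 - t2) / t1``; positive = better."""
    if score_t1 <= 0:
        raise ValueError("baseline score must be positive")
    return (score_t1 - score_t2) / score_t1


def delta_variability(i_t1: float, i_t2: float) -> float:
    """Relative variability change ``(t2 - t1) / t1``; negative = reduction."""
    if i_t1 <= 0:
        raise ValueError("baseline variability must be positive")
    return (i_t2 - i_t1) / i_t1


def encode_sex(sex: pd.Series | np.ndarray) -> np.ndarray:
    """Code sex as 0 (F) / 1 (M)."""
    arr = np.asarray(sex)
    out = np.where(arr == "M", 1.0, np.where(arr == "F", 0.0, np.nan))
    if np.isnan(out).any():
        raise ValueError("sex must be 'F' or 'M'")
    return out


def _long_to_change(data: pd.DataFrame, use_covariates: bool) -> pd.DataFrame:
    """Pivot a long outcome table to one change-score row per subject."""
    required = {"subject_id", "group", "timepoint", "outcome"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wide = data.pivot_table(
        index="subject_id", columns="timepoint", values="outcome", aggfunc="first"
    )
    if "t1" not in wide.columns or "t2" not in wide.columns or wide.isna().any().any():
        raise ValueError("every subject needs both t1 and t2 outcomes")
    per_subject = data.drop_duplicates("subject_id").set_index("subject_id")
    out = pd.DataFrame(
        {
            "delta": wide["t2"] - wide["t1"],
            "group": per_subject["group"],
        }
    )
    if use_covariates:
        cov = per_subject.copy()
        if "sex01" not in cov.columns:
            cov["sex01"] = encode_sex(cov["sex"])
        for c in COVARIATE_COLUMNS:
            if c not in cov.columns:
                raise ValueError(f"missing covariate column {c}")
            out[c] = cov[c]
    return out


def rm_ancova_interaction(
    data: pd.DataFrame, use_covariates: bool = True
) -> InteractionResult:
    """Group x time interaction F-test for a two-timepoint design.

    ``data`` is long format with columns ``subject_id, group, timepoint,
    outcome`` plus covariates (``age_years, sex``/``sex01``,
    ``illness_duration_months, education_years, cpz_equiv_mg_per_day``)
    constant within subject.  The change score d = t2 - t1 is regressed on
    group and covariates; the group F (1 df in a two-group design) is the
    interaction F.
    """
    change = _long_to_change(data, use_covariates)
    groups = sorted(change["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if (change["group"].value_counts() < 2).any():
        raise ValueError("need at least 2 subjects per group")
    g = (change["group"] == groups[1]).astype(float).to_numpy()
    cols = [g]
    if use_covariates:
        cols += [change[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    fit = sm.OLS(change["delta"].to_numpy(dtype=float), X).fit()
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    ftest = fit.f_test(contrast)
    return InteractionResult(
        f_value=float(ftest.fvalue),
        p_value=float(ftest.pvalue),
        df=(int(ftest.df_num), int(ftest.df_denom)),
    )


def _paired_t_decrease(t1: np.ndarray, t2: np.ndarray) -> TTestResult:
    """Paired t for t1 vs t2: positive t means the value decreased."""
    d = np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)
    if d.size < 2 or np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(t_value=0.0, p_value=1.0, df=d.size - 1)
        raise DegenerateTestError("zero within-pair variance")
    res = stats.ttest_rel(t1, t2)
    return TTestResult(float(res.statistic), float(res.pvalue), float(d.size - 1))


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    res = stats.ttest_ind(a, b)
    return TTestResult(
        float(res.statistic), float(res.pvalue), float(len(a) + len(b) - 2)
    )


def posthoc_tests(
    data: pd.DataFrame, reference: pd.DataFrame | None = None
) -> PosthocResult:
    """Post-hoc contrasts: paired t per group, group differences per
    timepoint, and optional comparison of each group/timepoint against a
    reference sample (column ``outcome``).
    """
    wide = data.pivot_table(
        index=["subject_id", "group"], columns="timepoint", values="outcome"
    ).reset_index()
    if wide[["t1", "t2"]].isna().any().any():
        raise ValueError("every subject needs both timepoints")
    paired = {}
    for grp, sub in wide.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {grp} has fewer than 2 subjects")
        paired[grp] = _paired_t_decrease(sub["t1"].to_numpy(), sub["t2"].to_numpy())
    groups = sorted(wide["group"].unique())
    between = {}
    if len(groups) == 2:
        a = wide[wide["group"] == groups[0]]
        b = wide[wide["group"] == groups[1]]
        for tp in ("t1", "t2"):
            between[tp] = _two_sample_t(a[tp].to_numpy(), b[tp].to_numpy())
    vs_ref = {}
    if reference is not None:
        ref = np.asarray(reference["outcome"], dtype=float)
        for grp, sub in wide.groupby("group"):
            for tp in ("t1", "t2"):
                vs_ref[f"{grp}_{tp}"] = _two_sample_t(sub[tp].to_numpy(), ref)
    return PosthocResult(
        paired_by_group=paired, between_groups=between, vs_reference=vs_ref
    )


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for covariates.

    Both variables are rank-transformed, residualized on an intercept plus
    the covariate columns, and the residuals are Pearson-correlated; the p
    value is t-based on ``n - n_covariates - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1).shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector has no ranks to correlate")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covariates is not None:
        Z = np.column_stack([np.ones(n), np.asarray(covariates, float).reshape(n, -1)])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("degenerate ranks after residualization")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def variability_fc_coupling(
    var_mat: VariabilityMatrix | np.ndarray,
    fc_mat: np.ndarray,
    labels: list[str] | None = None,
) -> tuple[float, float]:
    """Across-pair correlation of group-mean variability I and mean FC.

    Both matrices must share region order; the correlation runs over the
    strict upper triangle.  A negative r means stable (high-FC) pairs
    fluctuate less — the expected coupling direction.
    """
    if isinstance(var_mat, VariabilityMatrix):
        if labels is not None and labels != var_mat.labels:
            raise ValueError("label mismatch between matrices")
        values = var_mat.values
    else:
        values = np.asarray(var_mat, dtype=float)
    fc = np.asarray(fc_mat, dtype=float)
    if fc.shape != values.shape:
        raise ValueError("matrix shapes differ")
    iu = np.triu_indices_from(values, k=1)
    if iu[0].size < 3:
        raise ValueError("need at least 3 region pairs")
    res = stats.pearsonr(values[iu], fc[iu])
    return float(res.statistic), float(res.pvalue)
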