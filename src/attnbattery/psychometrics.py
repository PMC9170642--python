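"""Psychometric analysis toolkit for battery scores.

Pearson correlations, paired t tests, one-way ANOVA, empirical-logit
transforms for proportion scores, hierarchical OLS with nested-model
F-change comparison, a Pillai-trace multivariate group test (with optional
covariate), and a test–retest reliability report.

All p-values are two-sided.  Standardized slopes (beta) are computed on
z-scored outcome and predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "RegressionSpec",
    "ModelFit",
    "ModelComparison",
    "ReliabilityReport",
    "MultivariateGroupTest",
    "pearson_r",
    "paired_t",
    "one_way_anova",
    "logit_percent",
    "fit_ols",
    "compare_nested",
    "pillai_group_test",
    "test_retest",
]


@dataclass(frozen=True)
class PairedSample:
    """Two pair-linked score vectors (same units, same participants)."""

    time1: tuple[float, ...]
    time2: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.time1) != len(self.time2):
            raise ValueError("paired vectors must have equal length")
        if len(self.time1) < 3:
            raise ValueError("need at least 3 pairs")

    @property
    def n(self) -> int:
        return len(self.time1)


@dataclass(frozen=True)
class RegressionSpec:
    """Hierarchical regression layout: block 2 adds predictors to block 1.

    ``transforms`` maps a column name to ``"log"`` (natural log) or
    ``("logit", n_units)`` (empirical logit with eps = 1/(2 n_units)).
    """

    outcome: str
    block1: tuple[str, ...]
    block2_additions: tuple[str, ...]
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.block2_additions:
            raise ValueError("block 2 must add at least one predictor")
        if set(self.block1) & set(self.block2_additions):
            raise ValueError("block 2 additions must be new predictors")

    def predictors(self, block: int) -> tuple[str, ...]:
        if block == 1:
            return self.block1
        if block == 2:
            return self.block1 + self.block2_additions
        raise ValueError(f"block must be 1 or 2, got {block}")


@dataclass(frozen=True)
class PredictorEstimate:
    name: str
    b: float
    se: float
    beta: float
    t: float
    p: float


@dataclass(frozen=True)
class ModelFit:
    outcome: str
    predictors: tuple[str, ...]
    estimates: tuple[PredictorEstimate, ...]
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_model: float
    df_model: int
    df_resid: int
    p_model: float
    rss: float
    n: int


@dataclass(frozen=True)
class ModelComparison:
    f_change: float
    df_num: int
    df_den: int
    p_change: float
    r_squared_change: float


@dataclass(frozen=True)
class DescriptiveRow:
    n: int
    minimum: float
    maximum: float
    median: float
    mean: float
    sd: float


@dataclass(frozen=True)
class ReliabilityReport:
    n: int
    time1: DescriptiveRow
    time2: DescriptiveRow
    t: float
    t_df: int
    t_p: float
    r: float
    r_p: float


@dataclass(frozen=True)
class MultivariateGroupTest:
    pillai_v: float
    f_approx: float
    df_num: float
    df_den: float
    p: float


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p on n-2 df."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def paired_t(sample: PairedSample) -> tuple[float, int, float]:
    """Paired t on within-pair differences, df = n - 1, two-sided p.

    Zero-SD differences are degenerate unless all differences are exactly
    zero, in which case t = 0 (no change at all)."""
    d = _as_array(sample.time1, "time1") - _as_array(sample.time2, "time2")
    df = sample.n - 1
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    t, p = stats.ttest_rel(sample.time1, sample.time2)
    return float(t), df, float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Between/within mean-square F with standard dfs.

    All-equal data yields F = 0 (not an error)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_between == 0:
        return 0.0, df1, df2, 1.0
    if ss_within == 0:
        return math.inf, df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def logit_percent(p: float, n_units: Optional[int] = None) -> float:
    """Empirical logit ln((p + eps)/(1 - p + eps)), eps = 1/(2 n_units).

    With ``n_units`` given, boundary proportions 0 and 1 map to finite
    values; with ``n_units=None`` eps is 0 (plain log-odds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    eps = 0.0 if n_units is None else 1.0 / (2.0 * n_units)
    num, den = p + eps, 1.0 - p + eps
    if num <= 0 or den <= 0:
        raise ValueError("boundary proportion requires n_units for a finite logit")
    return math.log(num / den)


def apply_transforms(data: pd.DataFrame, transforms: dict) -> pd.DataFrame:
    """Return a copy of ``data`` with the spec's column transforms applied."""
    out = data.copy()
    for col, how in transforms.items():
        if how == "log":
            if (out[col] <= 0).any():
                raise ValueError(f"log transform of non-positive values in {col!r}")
            out[col] = np.log(out[col].astype(float))
        elif isinstance(how, (tuple, list)) and len(how) == 2 and how[0] == "logit":
            n_units = int(how[1])
            out[col] = [logit_percent(float(v), n_units) for v in out[col]]
        else:
            raise ValueError(f"unknown transform {how!r} for column {col!r}")
    return out


def _ols_arrays(y: np.ndarray, x: np.ndarray):
    """Least-squares core: coefficients, RSS, standard errors."""
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    resid = y - design @ coef
    rss = float(resid @ resid)
    df_resid = n - p - 1
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return coef, se, rss, df_resid


def fit_ols(spec: RegressionSpec, data: pd.DataFrame, block: int) -> ModelFit:
    """Fit one block of the hierarchical regression with an intercept.

    Raw slopes b come from the untransformed-scale (post-transform) least
    squares fit; beta is the slope after z-scoring outcome and predictors.
    """
    names = spec.predictors(block)
    frame = apply_transforms(data, spec.transforms)
    cols = [spec.outcome, *names]
    frame = frame.loc[:, cols].dropna()
    n = len(frame)
    if n < len(names) + 2:
        raise ValueError(f"need at least {len(names) + 2} complete cases, have {n}")
    y = frame[spec.outcome].to_numpy(dtype=float)
    x = frame.loc[:, list(names)].to_numpy(dtype=float)

    coef, se, rss, df_resid = _ols_arrays(y, x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p_count = len(names)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p_count - 1)
    if rss > 0 and r2 < 1.0:
        f_model = ((tss - rss) / p_count) / (rss / df_resid)
        p_model = float(stats.f.sf(f_model, p_count, df_resid))
    else:
        f_model, p_model = math.inf, 0.0

    sy = y.std(ddof=1)
    estimates = []
    for j, name in enumerate(names):
        b = float(coef[j + 1])
        sx = x[:, j].std(ddof=1)
        beta = b * sx / sy if sy > 0 else math.nan
        if se[j + 1] > 0:
            t = b / se[j + 1]
        else:  # saturated fit: zero residual variance
            t = math.copysign(math.inf, b) if b != 0 else 0.0
        p_val = 2.0 * float(stats.t.sf(abs(t), df_resid))
        estimates.append(
            PredictorEstimate(name=name, b=b, se=float(se[j + 1]), beta=beta, t=float(t), p=p_val)
        )

    return ModelFit(
        outcome=spec.outcome,
        predictors=names,
        estimates=tuple(estimates),
        intercept=float(coef[0]),
        r_squared=r2,
        adj_r_squared=adj_r2,
        f_model=float(f_model),
        df_model=p_count,
        df_resid=df_resid,
        p_model=p_model,
        rss=rss,
        n=n,
    )


def compare_nested(fit1: ModelFit, fit2: ModelFit) -> ModelComparison:
    """F-change test between nested OLS fits.

    F = ((RSS1 - RSS2)/df_num) / (RSS2/df_den) with df_den = n - p2 - 1.
    """
    if fit1.outcome != fit2.outcome or fit1.n != fit2.n:
        raise ValueError("fits must share outcome and sample")
    if not set(fit1.predictors) < set(fit2.predictors):
        raise ValueError("fit1 predictors must be a strict subset of fit2's")
    df_num = len(fit2.predictors) - len(fit1.predictors)
    df_den = fit2.df_resid
    if fit2.rss <= 0:
        raise ValueError("saturated larger model: F-change undefined")
    f_change = ((fit1.rss - fit2.rss) / df_num) / (fit2.rss / df_den)
    f_change = max(0.0, float(f_change))
    p_change = float(stats.f.sf(f_change, df_num, df_den))
    return ModelComparison(
        f_change=f_change,
        df_num=df_num,
        df_den=df_den,
        p_change=p_change,
        r_squared_change=fit2.r_squared - fit1.r_squared,
    )


def _residual_sscp(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    resid = y - design @ coef
    return resid.T @ resid


def pillai_group_test(
    outcomes: pd.DataFrame,
    group: Sequence,
    covariate: Optional[Sequence[float]] = None,
) -> MultivariateGroupTest:
    """Pillai-trace test of a group effect across several outcomes.

    The group term's hypothesis SSCP is the difference between residual
    cross-products of the model without and with the group dummies; the
    covariate, when supplied, is partialled by inclusion in both models.
    The approximate F uses the standard Pillai transformation.
    """
    y = outcomes.to_numpy(dtype=float)
    n, p = y.shape
    labels = pd.Categorical(group)
    if len(labels) != n:
        raise ValueError("group labels must match outcome rows")
    n_groups = len(labels.categories)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    dummies = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
    q = dummies.shape[1]

    base_cols = [np.ones(n)]
    if covariate is not None:
        cov = _as_array(covariate, "covariate")
        if len(cov) != n:
            raise ValueError("covariate length must match outcome rows")
        base_cols.append(cov)
    base = np.column_stack(base_cols)
    full = np.column_stack([base, dummies])
    if n <= full.shape[1] + p - 1:
        raise ValueError("too few observations for the multivariate test")

    e_full = _residual_sscp(y, full)
    e_reduced = _residual_sscp(y, base)
    h = e_reduced - e_full

    try:
        v = float(np.trace(h @ np.linalg.inv(h + e_full)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular error matrix in multivariate test") from exc

    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    df_error = n - full.shape[1]
    n_param = (df_error - p - 1) / 2.0
    df_num = s * (2 * m + s + 1)
    df_den = s * (2 * n_param + s + 1)
    if df_den <= 0 or v >= s:
        raise ValueError("degenerate Pillai configuration")
    f_approx = (df_den / df_num) * (v / (s - v))
    p_val = float(stats.f.sf(f_approx, df_num, df_den))
    return MultivariateGroupTest(
        pillai_v=v, f_approx=float(f_approx), df_num=df_num, df_den=df_den, p=p_val
    )


def _describe(x: np.ndarray) -> DescriptiveRow:
    return DescriptiveRow(
        n=len(x),
        minimum=float(x.min()),
        maximum=float(x.max()),
        median=float(np.median(x)),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
    )


def test_retest(sample: PairedSample) -> ReliabilityReport:
    """Consistency (paired t) and reliability (Pearson r) across two
    administrations, with descriptives per time point."""
    t1 = _as_array(sample.time1, "time1")
    t2 = _as_array(sample.time2, "time2")
    t, df, t_p = paired_t(sample)
    if np.std(t1) == 0 or np.std(t2) == 0:
        r, r_p = math.nan, math.nan
    else:
        r, r_p = pearson_r(t1, t2)
    return ReliabilityReport(
        n=sample.n,
        time1=_describe(t1),
        time2=_describe(t2),
        t=t,
        t_df=df,
        t_p=t_p,
        r=r,
        r_p=r_p,
    )
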