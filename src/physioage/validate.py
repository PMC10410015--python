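"""Comparator biological-age metrics and validation machinery.

Two classical biological-age estimators are fitted on the same imputed
biomarker set as the tree model so the three metrics can be compared on
equal footing:

* **Klemera-Doubal (KDM)** — every biomarker is regressed on age
  (``x_j = q_j + k_j a``); the biological age combines the per-biomarker
  inverse regressions weighted by ``k_j/s_j^2`` plus a chronological-age
  term weighted by ``1/s_BA^2`` (the corrected estimator).
* **Homeostatic dysregulation (HD)** — the Mahalanobis distance of the
  standardized biomarker vector from a young, clinically unremarkable
  reference population.

Validation regresses each metric on mortality (Cox proportional hazards
over metric deciles, 5th decile as reference, adjusted on gender, age,
year of inclusion and the age x year interaction) and on covariates
(linear models adjusted on age and gender), with AIC comparison across
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
import statsmodels.formula.api as smf

from .cohort import AGE, CYCLE, DEATH, FOLLOWUP, ID, SEX, CohortError, biomarker_columns

AGE_MID = 45.5


# --------------------------------------------------------------------------
# Klemera-Doubal
# --------------------------------------------------------------------------
@dataclass
class KDMModel:
    coefficients: pd.DataFrame  # index: biomarker; q (intercept), k (slope), s (residual SD)
    s_ba2: float  # variance of the age-correction term
    included: list[str]
    excluded: dict  # biomarker -> reason


def fit_kdm(train: pd.DataFrame, screen_r: float = 0.1) -> KDMModel:
    """Fit per-biomarker age regressions on an imputed cohort.

    Biomarkers whose absolute Pearson correlation with age falls below
    ``screen_r`` are excluded (a near-zero slope makes the inverse
    regression unstable and uninformative).
    """
    markers = biomarker_columns(train)
    ages = train[AGE].to_numpy(dtype=float)
    rows, included, excluded = [], [], {}
    for m in markers:
        x = train[m].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise CohortError("KDM requires an imputed (complete) cohort")
        r = np.corrcoef(x, ages)[0, 1]
        if abs(r) < screen_r:
            excluded[m] = f"|age correlation| {abs(r):.3f} < {screen_r}"
            continue
        k, q = np.polyfit(ages, x, 1)
        resid = x - (q + k * ages)
        s = float(np.std(resid, ddof=2))
        rows.append((m, q, k, max(s, 1e-12)))
        included.append(m)
    if len(included) < 1:
        raise CohortError("no biomarker passed the age-correlation screen")
    coef = pd.DataFrame(rows, columns=["biomarker", "q", "k", "s"]).set_index("biomarker")

    # first-stage estimate without the chronological-age term, used to
    # calibrate the age-correction variance s_BA^2 on the training data
    ba_e = _kdm_stage1(coef, train)
    s_ba2 = float(np.mean((ba_e - ages) ** 2))
    return KDMModel(coefficients=coef, s_ba2=max(s_ba2, 1e-12), included=included, excluded=excluded)


def _kdm_stage1(coef: pd.DataFrame, data: pd.DataFrame) -> np.ndarray:
    num = np.zeros(len(data))
    den = 0.0
    for m, row in coef.iterrows():
        x = data[m].to_numpy(dtype=float)
        num += (x - row.q) * row.k / row.s**2
        den += (row.k / row.s) ** 2
    return num / den


def score_kdm(model: KDMModel, data: pd.DataFrame) -> pd.Series:
    """Per-individual KDM biological age (years)."""
    missing = [m for m in model.included if m not in data.columns]
    if missing:
        raise CohortError(f"data lacks KDM biomarkers: {missing}")
    ages = data[AGE].to_numpy(dtype=float)
    num = np.zeros(len(data))
    den = 0.0
    for m, row in model.coefficients.iterrows():
        x = data[m].to_numpy(dtype=float)
        num += (x - row.q) * row.k / row.s**2
        den += (row.k / row.s) ** 2
    num += ages / model.s_ba2
    den += 1.0 / model.s_ba2
    return pd.Series(num / den, index=data[ID], name="kdm_age")


# --------------------------------------------------------------------------
# Homeostatic dysregulation
# --------------------------------------------------------------------------
@dataclass
class HDModel:
    mu: pd.Series
    covariance: pd.DataFrame
    log_variables: list[str]
    standardize: tuple[pd.Series, pd.Series]  # reference mean, sd of (possibly logged) values
    reference_description: str
    regularized: bool = False


def default_hd_reference(data: pd.DataFrame) -> pd.Series:
    """Young reference: ages 18-30 with every biomarker inside its
    cohort-wide [1st, 99th] percentile band."""
    mask = (data[AGE] >= 18) & (data[AGE] <= 30)
    for m in biomarker_columns(data):
        lo, hi = np.nanpercentile(data[m], [1, 99])
        mask &= data[m].between(lo, hi)
    return mask


def fit_hd(
    train: pd.DataFrame,
    reference_filter=None,
    skew_log_threshold: float = 2.0,
    ridge: float = 1e-8,
) -> HDModel:
    """Estimate the reference mean and covariance for the HD distance.

    Right-skewed biomarkers (sample skewness above the threshold) are
    log1p-transformed before standardization; a ridge term is added to
    the covariance if it is numerically singular.
    """
    markers = biomarker_columns(train)
    if train[markers].isna().any().any():
        raise CohortError("HD requires an imputed (complete) cohort")
    mask = default_hd_reference(train) if reference_filter is None else reference_filter(train)
    ref = train.loc[mask]
    if len(ref) < 5 * len(markers):
        raise CohortError(
            f"reference subsample ({len(ref)}) smaller than 5 x {len(markers)} biomarkers"
        )
    log_vars = [m for m in markers if stats.skew(train[m]) > skew_log_threshold]
    block = _hd_transform(ref, markers, log_vars)
    mean = block.mean()
    sd = block.std(ddof=1).replace(0.0, 1.0)
    std_block = (block - mean) / sd
    cov = std_block.cov()
    regularized = False
    try:
        np.linalg.cholesky(cov.to_numpy())
    except np.linalg.LinAlgError:
        warnings.warn("singular HD reference covariance; applying ridge regularization")
        cov = cov + ridge * np.eye(len(markers))
        regularized = True
    return HDModel(
        mu=std_block.mean(),
        covariance=cov,
        log_variables=log_vars,
        standardize=(mean, sd),
        reference_description=(
            "ages 18-30 within [1,99] percentiles" if reference_filter is None else "custom filter"
        ),
        regularized=regularized,
    )


def _hd_transform(data: pd.DataFrame, markers: list[str], log_vars: list[str]) -> pd.DataFrame:
    block = data[markers].astype(float).copy()
    for m in log_vars:
        block[m] = np.log1p(block[m] - min(0.0, block[m].min()))
    return block


def score_hd(model: HDModel, data: pd.DataFrame) -> pd.Series:
    """Mahalanobis distance of each individual from the reference mean."""
    markers = list(model.mu.index)
    mean, sd = model.standardize
    block = _hd_transform(data, markers, model.log_variables)
    u = ((block - mean) / sd) - model.mu
    vi = np.linalg.inv(model.covariance.to_numpy())
    d2 = np.einsum("ij,jk,ik->i", u.to_numpy(), vi, u.to_numpy())
    return pd.Series(np.sqrt(np.maximum(d2, 0.0)), index=data[ID], name="hd")


# --------------------------------------------------------------------------
# Survival and covariate validation
# --------------------------------------------------------------------------
@dataclass
class HazardTable:
    deciles: pd.DataFrame  # decile, hr, ci_low, ci_high, n_events, unstable
    covariates: pd.DataFrame  # term, hr, ci_low, ci_high
    aic: float
    reference_decile: int = 5


def metric_deciles(values: pd.Series) -> pd.Series:
    """Decile (1..10) of each value, ties assigned to the lower decile."""
    edges = np.quantile(values.to_numpy(dtype=float), np.linspace(0.1, 0.9, 9))
    dec = 1 + np.searchsorted(edges, values.to_numpy(dtype=float), side="left")
    return pd.Series(dec, index=values.index, name="decile")


def cox_deciles(
    metric: pd.Series,
    cohort: pd.DataFrame,
    reference_decile: int = 5,
    min_age: int = 18,
) -> HazardTable:
    """Adjusted Cox proportional-hazards model over metric deciles.

    Adults only; adjusters are gender, chronological age, year of
    inclusion and the age x year interaction. Hazard ratios are relative
    to the reference (5th) decile; deciles with no events are flagged.
    """
    if not {FOLLOWUP, DEATH} <= set(cohort.columns):
        raise CohortError("cohort lacks survival columns")
    df = cohort.loc[cohort[AGE] >= min_age].copy()
    if df[DEATH].sum() < 10:
        raise CohortError("too few events for survival modelling")
    df["metric"] = metric.reindex(df[ID]).to_numpy()
    df["decile"] = metric_deciles(df["metric"])
    year0 = df[CYCLE].min()
    model_df = pd.DataFrame(
        {
            "T": df[FOLLOWUP].to_numpy(dtype=float),
            "E": df[DEATH].to_numpy(dtype=int),
            "male": (df[SEX].astype(str) == "M").astype(float).to_numpy(),
            "age": df[AGE].to_numpy(dtype=float),
            "year": (df[CYCLE] - year0).to_numpy(dtype=float),
        }
    )
    model_df["age_x_year"] = model_df["age"] * model_df["year"]
    for d in range(1, 11):
        if d != reference_decile:
            model_df[f"decile_{d}"] = (df["decile"].to_numpy() == d).astype(float)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col="T", event_col="E")
    summary = cph.summary
    events_per_decile = df.groupby("decile")[DEATH].sum()

    rows = []
    for d in range(1, 11):
        if d == reference_decile:
            rows.append((d, 1.0, 1.0, 1.0, int(events_per_decile.get(d, 0)), False))
            continue
        s = summary.loc[f"decile_{d}"]
        unstable = int(events_per_decile.get(d, 0)) == 0
        rows.append(
            (
                d,
                float(np.exp(s["coef"])),
                float(np.exp(s["coef lower 95%"])),
                float(np.exp(s["coef upper 95%"])),
                int(events_per_decile.get(d, 0)),
                unstable,
            )
        )
    deciles = pd.DataFrame(
        rows, columns=["decile", "hr", "ci_low", "ci_high", "n_events", "unstable"]
    )
    cov_terms = ["male", "age", "year", "age_x_year"]
    cov = summary.loc[cov_terms, ["coef", "coef lower 95%", "coef upper 95%"]].apply(np.exp)
    cov.columns = ["hr", "ci_low", "ci_high"]
    return HazardTable(
        deciles=deciles,
        covariates=cov.reset_index(names="term"),
        aic=float(cph.AIC_partial_),
        reference_decile=reference_decile,
    )


@dataclass
class AssociationResult:
    covariate: str
    coefficients: pd.DataFrame  # category, coef, p
    aic: float
    n: int
    daic: float | None = None


def associate_covariates(
    metric: pd.Series,
    cohort: pd.DataFrame,
    covariates: dict[str, pd.Series],
    min_age: int = 18,
) -> list[AssociationResult]:
    """Linear model of the metric on each covariate, adjusted on age and
    gender; coefficients are per category against the reference (first)
    category, or per unit for continuous covariates."""
    results = []
    adult = cohort[AGE] >= min_age
    for name, cov in covariates.items():
        df = pd.DataFrame(
            {
                "metric": metric.reindex(cohort[ID]).to_numpy(),
                "age": cohort[AGE].to_numpy(dtype=float),
                "sex": cohort[SEX].astype(str).to_numpy(),
                "cov": np.asarray(cov),
            }
        ).loc[adult.to_numpy()]
        df = df.dropna()
        categorical = not pd.api.types.is_numeric_dtype(df["cov"])
        if categorical and df["cov"].nunique() < 2:
            raise CohortError(f"covariate {name!r} has a single category")
        term = "C(cov)" if categorical else "cov"
        fit = smf.ols(f"metric ~ {term} + age + C(sex)", data=df).fit()
        rows = []
        for pname in fit.params.index:
            if pname.startswith("C(cov)") or pname == "cov":
                label = pname.split("T.")[-1].rstrip("]") if categorical else name
                rows.append((label, float(fit.params[pname]), float(fit.pvalues[pname])))
        results.append(
            AssociationResult(
                covariate=name,
                coefficients=pd.DataFrame(rows, columns=["category", "coef", "p"]),
                aic=float(fit.aic),
                n=int(fit.nobs),
            )
        )
    return results


def compare_aic(results_by_metric: dict[str, AssociationResult]) -> pd.DataFrame:
    """dAIC of each metric's fit of the same covariate vs the best metric."""
    best = min(r.aic for r in results_by_metric.values())
    rows = []
    for metric_name, res in results_by_metric.items():
        res.daic = res.aic - best
        rows.append((metric_name, res.aic, res.daic))
    return pd.DataFrame(rows, columns=["metric", "aic", "daic"]).sort_values("daic").reset_index(drop=True)
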