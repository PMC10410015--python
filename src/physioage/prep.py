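"""Cohort preparation: inclusion filters, imputation, train/test split.

Filtering applies two rules in a fixed order: biomarkers observed on too
small a fraction of the cohort are dropped first, then individuals whose
missing fraction over the *retained* biomarkers exceeds the per-person
cap (strictly more than 10% by default). The tree-ensemble age model
consumes the unimputed table (it routes missing values natively); the
imputed table feeds the comparator metrics and any linear baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .cohort import AGE, ID, SEX, CohortError, biomarker_columns, validate_cohort


@dataclass(frozen=True)
class PrepConfig:
    min_coverage: float = 0.8  # minimum non-missing fraction per variable
    max_individual_missing: float = 0.10  # strict cap on per-person missing fraction
    test_fraction: float = 0.20
    imputer_max_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_coverage", "max_individual_missing", "test_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise CohortError(f"{name} must lie in (0, 1)")


@dataclass
class FilterReport:
    dropped_variables: list[str] = field(default_factory=list)
    dropped_individuals: list = field(default_factory=list)
    n_variables_before: int = 0
    n_variables_after: int = 0
    n_individuals_before: int = 0
    n_individuals_after: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_cohort(cohort: pd.DataFrame, config: PrepConfig | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply coverage filters: variables below ``min_coverage`` first, then
    individuals with strictly more than ``max_individual_missing`` missing
    among the retained variables."""
    config = config or PrepConfig()
    validate_cohort(cohort)
    markers = biomarker_columns(cohort)
    report = FilterReport(
        n_variables_before=len(markers), n_individuals_before=len(cohort)
    )
    coverage = cohort[markers].notna().mean(axis=0)
    keep_vars = [c for c in markers if coverage[c] >= config.min_coverage]
    report.dropped_variables = [c for c in markers if c not in keep_vars]
    if not keep_vars:
        raise CohortError("all biomarker variables fell below min_coverage")
    out = cohort.drop(columns=report.dropped_variables)

    frac = out[keep_vars].isna().mean(axis=1)
    drop_mask = frac > config.max_individual_missing
    report.dropped_individuals = out.loc[drop_mask, ID].tolist()
    out = out.loc[~drop_mask].reset_index(drop=True)
    if out.empty:
        raise CohortError("all individuals were dropped by the missingness rule")
    report.n_variables_after = len(keep_vars)
    report.n_individuals_after = len(out)
    return out, report


def impute(cohort: pd.DataFrame, config: PrepConfig | None = None) -> pd.DataFrame:
    """Round-robin multivariate imputation with a Bayesian ridge estimator.

    Observed cells are returned unchanged (exactly); only missing
    biomarker cells are filled.
    """
    config = config or PrepConfig()
    validate_cohort(cohort)
    markers = biomarker_columns(cohort)
    if len(markers) < 2:
        raise CohortError("imputation needs at least two biomarker variables")
    block = cohort[markers]
    if block.isna().all(axis=0).any():
        raise CohortError("a biomarker column is entirely missing")
    if not block.isna().any().any():
        return cohort.copy()
    imputer = IterativeImputer(
        estimator=BayesianRidge(),
        max_iter=config.imputer_max_iter,
        random_state=config.seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = imputer.fit_transform(block.to_numpy(dtype=float))
    out = cohort.copy()
    observed = block.notna().to_numpy()
    original = block.to_numpy(dtype=float)
    filled[observed] = original[observed]  # never touch an observed cell
    out[markers] = filled
    return out


def split(cohort: pd.DataFrame, config: PrepConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/test split.

    Strata are integer age x sex; test counts per stratum are allocated
    by largest remainder so the overall test size is exactly
    ``round(n * test_fraction)``.
    """
    config = config or PrepConfig()
    validate_cohort(cohort)
    n = len(cohort)
    if n < 5:
        raise CohortError("need at least 5 individuals to split")
    rng = np.random.default_rng(config.seed)
    target_total = int(round(n * config.test_fraction))

    groups = list(cohort.groupby([AGE, SEX], sort=True).groups.items())
    quotas = np.array([len(idx) * config.test_fraction for _, idx in groups])
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = target_total - base.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        for k in order[:short]:
            base[k] += 1

    test_index = []
    for (key, idx), take in zip(groups, base):
        idx = np.asarray(idx)
        take = min(take, len(idx))
        chosen = rng.choice(idx, size=take, replace=False)
        test_index.extend(chosen.tolist())
    test_mask = cohort.index.isin(test_index)
    test = cohort.loc[test_mask].reset_index(drop=True)
    train = cohort.loc[~test_mask].reset_index(drop=True)
    return train, test
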