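"""Recursive feature elimination driven by explanation importance.

At each step the model is (re)fitted on the currently retained
variables, globally explained, and the variable with the smallest mean
|contribution| is dropped, until one variable remains. The minimal
model is the smallest retained set whose test R^2 stays within a
relative tolerance (1% by default) of the full model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortError, biomarker_columns
from .explain import explain_global, rank_importance
from .model import evaluate, fit_age_model, tune_hyperparameters


@dataclass
class RFETrace:
    steps: pd.DataFrame  # step, n_variables, dropped, r2, mae
    retained_sets: list[list[str]]  # variable set *fitted* at each step
    minimal_set: list[str]
    full_r2: float
    aborted: bool = False


def recursive_eliminate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    hyperparameters: dict | None = None,
    objective: str = "age_normalized",
    seed: int = 0,
    retune: bool = False,
    tolerance: float = 0.01,
    background_cap: int | None = 128,
    explain_sample: int | None = 1000,
    tune_budget: int = 6,
) -> RFETrace:
    """Run the elimination loop and locate the minimal performant set.

    ``retune=False`` (default) reuses one hyperparameter configuration
    across steps; ``retune=True`` reruns the randomized search each step.
    Ties in minimal importance drop the lexicographically last variable.
    """
    variables = sorted(biomarker_columns(train))
    if len(variables) < 2:
        raise CohortError("recursive elimination needs at least 2 variables")
    rows = []
    retained_sets: list[list[str]] = []
    current = list(variables)
    full_r2 = None
    aborted = False
    step = 0
    while True:
        hp = hyperparameters
        if retune:
            reserved = [c for c in train.columns if c not in variables]
            hp = tune_hyperparameters(train[reserved + current], budget=tune_budget,
                                      objective=objective, seed=seed)
        model = fit_age_model(train, hp, objective=objective, seed=seed,
                              variables=current, evaluate_train=False)
        metrics = evaluate(model, test)
        if not (np.isfinite(metrics.r2) and np.isfinite(metrics.mae)):
            aborted = True
            break
        if full_r2 is None:
            full_r2 = metrics.r2
        retained_sets.append(list(current))
        if len(current) == 1:
            rows.append((step, len(current), None, metrics.r2, metrics.mae))
            break
        sample = train
        if explain_sample is not None and len(train) > explain_sample:
            sample = train.sample(explain_sample, random_state=seed)
        expl = explain_global(model, sample, background=background_cap, seed=seed)
        imp = rank_importance(expl).table.set_index("variable")["mean_abs_phi"]
        least = imp[imp == imp.min()].index.max()  # lexicographically last on ties
        rows.append((step, len(current), least, metrics.r2, metrics.mae))
        current = [v for v in current if v != least]
        step += 1

    steps = pd.DataFrame(rows, columns=["step", "n_variables", "dropped", "r2", "mae"])
    minimal: list[str] = retained_sets[0] if retained_sets else []
    if full_r2 is not None:
        threshold = (1.0 - tolerance) * full_r2
        for s, kept in zip(steps.itertuples(), retained_sets):
            if s.r2 >= threshold:
                minimal = kept
    return RFETrace(
        steps=steps,
        retained_sets=retained_sets,
        minimal_set=sorted(minimal),
        full_r2=float(full_r2) if full_r2 is not None else float("nan"),
        aborted=aborted,
    )
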