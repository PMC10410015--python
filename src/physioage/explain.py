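"""Additive explanations, PPA, importance rankings and dependence profiles.

Two flavors of tree-Shapley explanation are computed with the same
engine, differing only in the reference population:

* **global** — the whole dataset is the background; the base value is
  the mean model prediction over it, and an individual's personalized
  physiological age (PPA) is the base plus the row sum of contributions.
* **contextualized** — each individual is explained against the
  individuals sharing their chronological age (integer ages, merged with
  neighbors until a minimum group size); the base value is the group's
  mean prediction and the row sum is the *PPA deviation*: how many years
  older or younger the individual's physiology reads than that of their
  same-aged peers.

Partial-dependence profiles plot contextualized contributions against
the raw biomarker value; the value range where the per-bin mean
contribution crosses zero defines an age-specific "normal" threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _treeshap
from .cohort import AGE, ID, CohortError
from .model import TrainedAgeModel

ADDITIVITY_TOL = 1e-4


@dataclass
class ExplanationMatrix:
    """Per-individual, per-variable additive contributions (years)."""

    phi: pd.DataFrame  # index: id, columns: variables
    base_value: float | dict
    flavor: str  # "global" | "contextualized"
    background_description: str
    ages: pd.Series  # id -> chronological age
    predictions: pd.Series  # id -> model prediction
    group_of: pd.Series | None = None  # id -> age-group key (contextualized)

    def base_for(self, individual_id) -> float:
        if self.flavor == "global":
            return float(self.base_value)
        return float(self.base_value[self.group_of.loc[individual_id]])

    def check_additivity(self, tol: float = ADDITIVITY_TOL) -> float:
        """Max |base + sum(phi) - prediction| over individuals."""
        bases = (
            np.full(len(self.phi), float(self.base_value))
            if self.flavor == "global"
            else self.group_of.map(self.base_value).to_numpy(dtype=float)
        )
        gap = np.abs(bases + self.phi.sum(axis=1).to_numpy() - self.predictions.to_numpy())
        worst = float(gap.max())
        if worst > tol:
            raise AssertionError(f"Shapley additivity violated: max gap {worst:.3g} > {tol}")
        return worst


@dataclass
class ImportanceRanking:
    table: pd.DataFrame  # variable, mean_abs_phi, share, cumulative_share

    @property
    def variables(self) -> list[str]:
        return self.table["variable"].tolist()


@dataclass
class DependenceProfile:
    variable: str
    points: pd.DataFrame  # id, value, phi, age
    heatmap: pd.DataFrame  # index: age-bin label, columns: value-bin center, mean phi
    crossings: dict  # age-bin label -> (lo, hi) raw-value interval or None
    value_bin_edges: np.ndarray
    age_bin_edges: np.ndarray


def assign_age_groups(ages: pd.Series, min_size: int = 50) -> pd.Series:
    """Partition integer ages into contiguous groups of at least ``min_size``.

    Ages are scanned in increasing order and accumulated until the group
    reaches the minimum; a too-small trailing group is merged into its
    predecessor. Group keys are "lo-hi" age-range strings.
    """
    counts = ages.value_counts().sort_index()
    groups: list[list[int]] = []
    current: list[int] = []
    size = 0
    for a, c in counts.items():
        current.append(int(a))
        size += int(c)
        if size >= min_size:
            groups.append(current)
            current, size = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    key_of_age = {}
    for g in groups:
        key = f"{min(g)}-{max(g)}"
        for a in g:
            key_of_age[a] = key
    return ages.map(key_of_age)


def _features(model: TrainedAgeModel, data: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.selected_variables if c not in data.columns]
    if missing:
        raise CohortError(f"data lacks model variables: {missing}")
    return data[model.selected_variables].to_numpy(dtype=np.float64)


def _base_score(model: TrainedAgeModel) -> float:
    import json

    cfg = json.loads(model.booster.save_config())
    return float(cfg["learner"]["learner_model_param"]["base_score"])


def explain_global(
    model: TrainedAgeModel,
    data: pd.DataFrame,
    background: int | None = None,
    seed: int = 0,
) -> ExplanationMatrix:
    """Tree-Shapley contributions against the whole dataset.

    ``background`` optionally caps the reference sample size (a uniform
    subsample, drawn with ``seed``); the base value is always the mean
    model prediction over the background actually used.
    """
    X = _features(model, data)
    trees = _treeshap.extract_trees(model.booster, model.selected_variables)
    pred = _treeshap.predict_values(trees, X, _base_score(model))
    if background is not None and background < len(data):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(data), size=background, replace=False))
        Z = X[idx]
        base = float(pred[idx].mean())
        desc = f"uniform subsample of {background} of {len(data)} individuals"
    else:
        Z = X
        base = float(pred.mean())
        desc = f"all {len(data)} individuals"
    phi = _treeshap.shap_values(trees, X, Z)
    ids = data[ID]
    return ExplanationMatrix(
        phi=pd.DataFrame(phi, index=ids, columns=model.selected_variables),
        base_value=base,
        flavor="global",
        background_description=desc,
        ages=pd.Series(data[AGE].to_numpy(), index=ids),
        predictions=pd.Series(pred, index=ids),
    )


def explain_contextualized(
    model: TrainedAgeModel,
    data: pd.DataFrame,
    min_group_size: int = 50,
    background_cap: int | None = None,
    seed: int = 0,
) -> ExplanationMatrix:
    """Tree-Shapley contributions against same-aged peers.

    For each age group the reference population is the group itself
    (optionally capped at ``background_cap`` rows), so contributions are
    centered on the group: the mean PPA deviation within a group is ~0.
    """
    X = _features(model, data)
    trees = _treeshap.extract_trees(model.booster, model.selected_variables)
    ids = data[ID]
    ages = pd.Series(data[AGE].to_numpy(), index=ids)
    group_of = assign_age_groups(ages, min_size=min_group_size)
    pred = pd.Series(_treeshap.predict_values(trees, X, _base_score(model)), index=ids)

    phi = np.zeros_like(X)
    bases: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    pos = pd.Series(np.arange(len(data)), index=ids)
    for key, members in group_of.groupby(group_of).groups.items():
        rows = pos.loc[members].to_numpy()
        if len(rows) < 2:
            raise CohortError(f"age group {key} has fewer than 2 members")
        bg_rows = rows
        if background_cap is not None and len(rows) > background_cap:
            bg_rows = np.sort(rng.choice(rows, size=background_cap, replace=False))
            bases[key] = float(pred.iloc[bg_rows].mean())
        else:
            bases[key] = float(pred.iloc[rows].mean())
        phi[rows] = _treeshap.shap_values(trees, X[rows], X[bg_rows])

    return ExplanationMatrix(
        phi=pd.DataFrame(phi, index=ids, columns=model.selected_variables),
        base_value=bases,
        flavor="contextualized",
        background_description=(
            f"same-age groups (min size {min_group_size}"
            + (f", background capped at {background_cap})" if background_cap else ")")
        ),
        ages=ages,
        predictions=pred,
        group_of=group_of,
    )


def compute_ppa(global_expl: ExplanationMatrix, ctx_expl: ExplanationMatrix) -> pd.DataFrame:
    """Per-individual PPA (predicted age) and PPA deviation (years).

    PPA is the global base plus the global contribution row sum; the PPA
    deviation is the contextualized row sum — predicted age minus the
    mean prediction of same-aged peers.
    """
    if not global_expl.phi.index.equals(ctx_expl.phi.index):
        raise CohortError("explanation matrices cover different individuals")
    ppa = float(global_expl.base_value) + global_expl.phi.sum(axis=1)
    deviation = ctx_expl.phi.sum(axis=1)
    return pd.DataFrame(
        {
            ID: global_expl.phi.index,
            AGE: global_expl.ages.to_numpy(),
            "ppa": ppa.to_numpy(),
            "ppa_deviation": deviation.to_numpy(),
        }
    )


def rank_importance(expl: ExplanationMatrix, top_k: int | None = None) -> ImportanceRanking:
    """Variables ordered by mean |contribution|, with contribution shares.

    Ties break lexicographically; an all-zero matrix yields uniform
    shares. ``top_k`` beyond the variable count clamps with a warning.
    """
    if expl.phi.empty:
        raise CohortError("explanation matrix is empty")
    mean_abs = expl.phi.abs().mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        shares = pd.Series(1.0 / len(mean_abs), index=mean_abs.index)
    else:
        shares = mean_abs / total
    order = sorted(mean_abs.index, key=lambda v: (-mean_abs[v], v))
    table = pd.DataFrame(
        {
            "variable": order,
            "mean_abs_phi": mean_abs.loc[order].to_numpy(),
            "share": shares.loc[order].to_numpy(),
        }
    )
    table["cumulative_share"] = table["share"].cumsum()
    if top_k is not None:
        if top_k > len(table):
            warnings.warn(f"top_k={top_k} exceeds {len(table)} variables; clamping")
            top_k = len(table)
        table = table.head(top_k).reset_index(drop=True)
    return ImportanceRanking(table)


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-bin moving average, NaN-aware, edges padded by reflection."""
    out = np.full_like(values, np.nan, dtype=float)
    for i in range(len(values)):
        window = values[max(0, i - 1): i + 2]
        window = window[~np.isnan(window)]
        if window.size:
            out[i] = window.mean()
    return out


def _crossing_interval(smoothed: np.ndarray, centers: np.ndarray, min_amplitude: float = 0.2):
    """Raw-value bracket where the smoothed mean contribution changes sign.

    Bins whose |mean contribution| stays below ``min_amplitude`` years are
    treated as zero: a variable that never materially departs from zero
    has no meaningful threshold.
    """
    sign = np.sign(smoothed)
    sign[np.abs(smoothed) < min_amplitude] = 0.0
    valid = ~np.isnan(smoothed)
    neg = np.where(valid & (sign < 0))[0]
    pos = np.where(valid & (sign > 0))[0]
    if neg.size == 0 or pos.size == 0:
        return None
    last_neg, first_pos = neg.max(), pos.min()
    if last_neg < first_pos:  # monotone crossing
        return (float(centers[last_neg]), float(centers[first_pos]))
    # non-monotone: widest adjacent sign-change bracket
    idx = np.where(valid)[0]
    best = None
    for i, j in zip(idx[:-1], idx[1:]):
        if sign[i] != 0 and sign[j] != 0 and sign[i] != sign[j]:
            bracket = (float(centers[i]), float(centers[j]))
            if best is None or bracket[1] - bracket[0] > best[1] - best[0]:
                best = bracket
    return best


def dependence_profile(
    expl: ExplanationMatrix,
    data: pd.DataFrame,
    variable: str,
    age_bins: int | np.ndarray = 6,
    value_bins: int = 40,
    min_amplitude: float = 0.2,
) -> DependenceProfile:
    """Heatmap of mean contextualized contribution per (age bin, value bin)
    and the per-age-bin zero-crossing interval.

    Value bins are equal-frequency over the observed (non-missing)
    values; per-bin means are smoothed with a 3-bin moving average
    before sign detection, and bins below ``min_amplitude`` years in
    magnitude are treated as zero.
    """
    if variable not in expl.phi.columns:
        raise CohortError(f"unknown variable {variable!r}")
    if expl.flavor != "contextualized":
        raise CohortError("dependence profiles require contextualized explanations")
    values = pd.Series(data[variable].to_numpy(), index=data[ID])
    points = pd.DataFrame(
        {
            ID: expl.phi.index,
            "value": values.loc[expl.phi.index].to_numpy(),
            "phi": expl.phi[variable].to_numpy(),
            AGE: expl.ages.to_numpy(),
        }
    ).dropna(subset=["value"])

    qs = np.linspace(0, 1, (value_bins if np.isscalar(value_bins) else len(value_bins)) + 1)
    edges = np.unique(np.quantile(points["value"], qs))
    if len(edges) < 3:
        raise CohortError(f"variable {variable!r} has too few distinct values")
    centers = 0.5 * (edges[:-1] + edges[1:])
    vbin = np.clip(np.searchsorted(edges, points["value"], side="right") - 1, 0, len(centers) - 1)

    if np.isscalar(age_bins):
        a_edges = np.quantile(points[AGE], np.linspace(0, 1, int(age_bins) + 1))
        a_edges = np.unique(a_edges)
    else:
        a_edges = np.asarray(age_bins, dtype=float)
    abin = np.clip(np.searchsorted(a_edges, points[AGE], side="right") - 1, 0, len(a_edges) - 2)
    labels = [f"{a_edges[i]:.0f}-{a_edges[i+1]:.0f}" for i in range(len(a_edges) - 1)]

    grid = np.full((len(labels), len(centers)), np.nan)
    tmp = pd.DataFrame({"a": abin, "v": vbin, "phi": points["phi"].to_numpy()})
    means = tmp.groupby(["a", "v"])["phi"].mean()
    for (i, j), m in means.items():
        grid[int(i), int(j)] = m

    crossings = {}
    for i, label in enumerate(labels):
        crossings[label] = _crossing_interval(_smooth3(grid[i]), centers, min_amplitude)
    heatmap = pd.DataFrame(grid, index=labels, columns=np.round(centers, 6))
    return DependenceProfile(
        variable=variable,
        points=points.reset_index(drop=True),
        heatmap=heatmap,
        crossings=crossings,
        value_bin_edges=edges,
        age_bin_edges=a_edges,
    )
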