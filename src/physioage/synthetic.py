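"""Synthetic cohorts with known physiological-age structure.

The generator emulates a survey-style laboratory panel: ~48 continuous
biomarkers on individuals aged 12-79, with heterogeneous age-dependence
shapes, near-zero missingness, and mortality driven by each individual's
latent physiological deviation. Because the deviation each variable
carries is written down explicitly (in years), every downstream stage of
the pipeline — the age model, the additive explanations, threshold
extraction, clustering, and the survival validation — can be checked
against ground truth.

Generative model
----------------
Each variable ``v`` draws, per individual ``i``, a standard-normal latent
deviation ``z_iv`` (the individual's stable physiological state on that
axis) and independent measurement noise. The raw value is

    x_iv = M_v(a_i) + baseline_sd * z_iv + noise_sd * eps_iv

where ``M_v(a)`` is the age profile of the population mean. The
``amplitude`` of an effect is the standardized drift of that profile —
how many baseline standard deviations the mean moves across the active
age range — so it controls how much chronological-age signal the
variable carries. The age-years implied by a deviation follow from
inverting the local profile slope: a one-SD deviation on a variable that
drifts ``A`` SDs over the 67-year span reads as ``67 / A`` years.

The per-variable *true contribution* is that implied displacement scaled
by the variable's share of the panel's total age information (inverse
implied-years variance) — the attribution an efficient combined estimate
of the latent physiological state would assign. The row sum of the
contributions is the individual's true physiological-age deviation; its
spread is a few years for information-rich panels, mirroring how a
model's same-age-referenced prediction deviates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE, AGE_MAX, AGE_MIN, CYCLE, DEATH, FOLLOWUP, ID, SEX, biomarker_columns

AGE_MID = (AGE_MIN + AGE_MAX) / 2.0  # 45.5
AGE_SPAN = float(AGE_MAX - AGE_MIN)  # 67 years

_SHAPES = ("linear", "sigmoid", "window", "null")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class EffectSpec:
    """Age-dependence of one biomarker.

    Parameters
    ----------
    variable_name:
        Column name of the biomarker.
    shape:
        ``linear`` (steady drift across the whole age span), ``sigmoid``
        (drifting mean with threshold-saturating deviations, e.g. an
        HbA1c-like marker), ``window`` (drift confined to an age window,
        e.g. a puberty-linked enzyme), or ``null`` (no age signal).
    amplitude:
        Standardized age drift: baseline SDs the population mean moves
        across the active age range. Zero for ``null`` effects.
    center:
        Sigmoid zero-contribution raw value at the cohort mid-age, or a
        triple ``(x0_young, x0_old, break_age)`` for an age-stepped
        threshold; for ``window``, the ``(a_lo, a_hi)`` bounds in years.
    width:
        Sigmoid saturation width in units of ``baseline_sd``.
    noise_sd:
        Measurement noise SD (raw units); carries no physiological signal.
    baseline_mean, baseline_sd:
        Raw-value location and physiological spread at the reference
        (mid-cohort) age.
    """

    variable_name: str
    shape: str = "linear"
    amplitude: float = 5.0
    center: float | tuple = 0.0
    width: float = 1.0
    noise_sd: float = 0.0
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigError(f"unknown effect shape {self.shape!r}")
        if not np.isfinite(self.amplitude):
            raise ConfigError("amplitude must be finite")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline_sd <= 0:
            raise ConfigError("baseline_sd must be > 0")
        if self.shape == "null" and self.amplitude != 0:
            raise ConfigError("null effects must have amplitude 0")
        if self.shape == "window":
            lo, hi = self.center
            if not (AGE_MIN <= lo < hi <= AGE_MAX):
                raise ConfigError(f"window bounds must satisfy {AGE_MIN} <= lo < hi <= {AGE_MAX}")

    # --- profile pieces -------------------------------------------------
    def profile(self, ages: np.ndarray) -> np.ndarray:
        """Population mean raw value at each age."""
        a = np.asarray(ages, dtype=float)
        if self.shape == "null":
            drift = np.zeros_like(a)
        elif self.shape == "window":
            lo, hi = self.center
            drift = self.amplitude * (np.clip(a, lo, hi) - (lo + hi) / 2.0) / (hi - lo)
        else:
            drift = self.amplitude * (a - AGE_MID) / AGE_SPAN
        if self.shape == "sigmoid":
            base = self._midpoint(a)
        else:
            base = np.full_like(a, self.baseline_mean)
        return base + self.baseline_sd * drift

    def _midpoint(self, ages: np.ndarray) -> np.ndarray:
        """Sigmoid zero-contribution raw value as a function of age."""
        if self.shape != "sigmoid":
            return np.zeros_like(np.asarray(ages, dtype=float))
        if np.isscalar(self.center) or isinstance(self.center, (int, float)):
            return np.full_like(np.asarray(ages, dtype=float), float(self.center))
        x0_young, x0_old, brk = self.center
        return np.where(np.asarray(ages, dtype=float) < brk, x0_young, x0_old)

    @property
    def active_span(self) -> float:
        """Age span (years) over which the profile drifts."""
        if self.shape == "window":
            lo, hi = self.center
            return float(hi - lo)
        return AGE_SPAN

    @property
    def precision(self) -> float:
        """Age information carried by the variable: inverse variance of
        the age displacement a one-SD deviation implies."""
        if self.shape == "null" or self.amplitude == 0:
            return 0.0
        return (self.amplitude / self.active_span) ** 2

    def implied_years(self, ages: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Age displacement read off this variable alone for deviation ``z``:
        the horizontal shift of the age profile matching a ``z``-SD move."""
        a = np.asarray(ages, dtype=float)
        if self.shape == "null" or self.amplitude == 0:
            return np.zeros_like(a)
        if self.shape == "linear":
            return z * AGE_SPAN / self.amplitude
        if self.shape == "window":
            lo, hi = self.center
            inside = (a >= lo) & (a <= hi)
            return np.where(inside, z * (hi - lo) / self.amplitude, 0.0)
        # sigmoid: deviations saturate; linearizes to the linear case at z=0
        sat = 2.0 * self.width * AGE_SPAN / self.amplitude
        return sat * (2.0 / (1.0 + np.exp(-z / self.width)) - 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort draw."""

    n_individuals: int
    effects: tuple[EffectSpec, ...] = ()
    age_distribution: np.ndarray | None = None  # weights over integer ages 12..79
    sex_ratio: float = 0.5  # proportion of females
    missing_rate: float = 0.006
    mortality_beta: float = 0.05  # log-hazard per year of true deviation
    baseline_hazard: float = 0.004  # events per person-year at reference
    max_followup: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not self.effects:
            object.__setattr__(self, "effects", tuple(default_effect_panel()))
        if self.age_distribution is not None:
            w = np.asarray(self.age_distribution, dtype=float)
            if w.shape != (AGE_MAX - AGE_MIN + 1,) or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("age_distribution must be non-negative weights over ages 12..79")
            object.__setattr__(self, "age_distribution", w)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    cohort: pd.DataFrame
    true_contribution: pd.DataFrame  # individuals x variables, years
    true_deviation: pd.Series  # row sums, years


def default_age_weights() -> np.ndarray:
    """Survey-like age histogram: adolescents over-sampled roughly twofold,
    with a ~25% fall-off in the oldest decade."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    w = np.ones_like(ages, dtype=float)
    w[ages <= 20] = 2.0
    w[ages >= 70] = 0.75
    return w


def default_effect_panel() -> list[EffectSpec]:
    """A 48-variable panel loosely shaped after a routine laboratory battery.

    Units and locations are plausible rather than calibrated; what matters
    downstream is the mixture of age-dependence shapes: steady drifts,
    threshold-like markers, age-window effects, and tightly regulated
    (age-null) electrolytes.
    """
    specs: list[EffectSpec] = [
        EffectSpec("hba1c", "sigmoid", 9.0, center=5.5, width=1.0, noise_sd=0.05,
                   baseline_mean=5.5, baseline_sd=0.35),
        EffectSpec("glucose_serum", "sigmoid", 4.0, center=95.0, width=1.2, noise_sd=3.0,
                   baseline_mean=95.0, baseline_sd=12.0),
        EffectSpec("alp", "window", 8.0, center=(12, 20), noise_sd=4.0,
                   baseline_mean=90.0, baseline_sd=30.0),
        EffectSpec("alt", "window", 4.0, center=(20, 40), noise_sd=2.0,
                   baseline_mean=25.0, baseline_sd=10.0),
        EffectSpec("folate_serum", "window", 4.0, center=(60, 79), noise_sd=1.0,
                   baseline_mean=12.0, baseline_sd=5.0),
        EffectSpec("lymphocyte_n", "window", 3.0, center=(55, 79), noise_sd=0.2,
                   baseline_mean=2.1, baseline_sd=0.6),
    ]
    linear = [
        # (name, amplitude, mean, sd, noise)
        ("creatinine_urine", 6.0, 120.0, 60.0, 5.0),
        ("bun", 6.0, 13.0, 4.5, 0.5),
        ("mcv", 6.0, 89.0, 5.0, 0.5),
        ("creatinine_serum", 5.0, 0.9, 0.22, 0.02),
        ("triglycerides", 5.0, 130.0, 80.0, 8.0),
        ("cholesterol_total", 5.0, 190.0, 40.0, 4.0),
        ("albumin", 5.0, 4.3, 0.33, 0.05),
        ("uric_acid", 4.5, 5.4, 1.3, 0.1),
        ("ggt", 4.5, 26.0, 20.0, 2.0),
        ("rdw", 4.5, 12.9, 1.1, 0.1),
        ("hematocrit", 4.0, 41.0, 4.0, 0.4),
        ("crp", 4.0, 0.4, 0.55, 0.05),
        ("hdl", 3.5, 53.0, 15.0, 1.5),
        ("ldl", 3.5, 115.0, 33.0, 3.5),
        ("ast", 3.5, 24.0, 9.0, 1.0),
        ("globulin", 3.5, 2.9, 0.45, 0.05),
        ("protein_total", 3.0, 7.2, 0.45, 0.05),
        ("bilirubin_total", 3.0, 0.7, 0.3, 0.03),
        ("phosphorus", 3.0, 3.8, 0.55, 0.05),
        ("calcium", 3.0, 9.5, 0.38, 0.04),
        ("rbc", 3.0, 4.7, 0.45, 0.04),
        ("hemoglobin", 3.0, 14.2, 1.4, 0.15),
        ("platelets", 2.5, 255.0, 60.0, 6.0),
        ("wbc", 2.5, 7.2, 2.0, 0.2),
        ("ferritin", 2.5, 110.0, 90.0, 9.0),
        ("iron_serum", 2.5, 95.0, 35.0, 3.5),
        ("transferrin_sat", 2.5, 25.0, 9.0, 1.0),
        ("vitamin_b12", 2.0, 520.0, 210.0, 20.0),
        ("osmolality", 2.0, 278.0, 5.0, 0.5),
        ("ldh", 2.0, 135.0, 28.0, 3.0),
        ("ck", 2.0, 120.0, 80.0, 8.0),
        ("insulin", 2.0, 11.0, 7.0, 0.7),
        ("homocysteine", 2.0, 8.0, 2.6, 0.3),
        ("cystatin_c", 2.0, 0.9, 0.16, 0.02),
        ("apolipoprotein_b", 2.0, 92.0, 24.0, 2.5),
        ("monocyte_pct", 1.5, 7.8, 2.0, 0.2),
        ("lymphocyte_pct", 1.5, 30.0, 7.5, 0.8),
        ("eosinophil_pct", 1.5, 2.8, 1.9, 0.2),
        ("basophil_pct", 1.0, 0.6, 0.35, 0.05),
        ("neutrophil_pct", 1.0, 58.0, 9.0, 1.0),
    ]
    specs += [
        EffectSpec(name, "linear", amp, noise_sd=noise, baseline_mean=mean, baseline_sd=sd)
        for name, amp, mean, sd, noise in linear
    ]
    specs += [
        EffectSpec(name, "null", 0.0, noise_sd=noise, baseline_mean=mean, baseline_sd=sd)
        for name, mean, sd, noise in [
            ("sodium", 139.0, 2.2, 0.5),
            ("potassium", 4.0, 0.33, 0.05),
        ]
    ]
    return specs


def expected_age_correlation(effect: EffectSpec, age_weights: np.ndarray | None = None) -> float:
    """Closed-form Pearson correlation between a linear-effect biomarker
    and age under the generating model.

    With standardized drift ``A`` over the span, the age part of the
    value has SD ``baseline_sd * A * sd(age) / span``, against a total of
    that plus ``baseline_sd^2 + noise_sd^2``.
    """
    if effect.shape != "linear":
        raise ValueError("closed form only defined for linear effects")
    w = default_age_weights() if age_weights is None else np.asarray(age_weights, float)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    p = w / w.sum()
    mu = (p * ages).sum()
    var_age = (p * (ages - mu) ** 2).sum()
    drift_sd = effect.baseline_sd * effect.amplitude * np.sqrt(var_age) / AGE_SPAN
    total = np.sqrt(drift_sd**2 + effect.baseline_sd**2 + effect.noise_sd**2)
    return float(drift_sd / total)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort with its ground-truth contribution matrix.

    Deterministic for a fixed config (seed included). Missingness and
    mortality are *not* applied here; compose with
    :func:`inject_missingness` and :func:`simulate_mortality`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ages_grid = np.arange(AGE_MIN, AGE_MAX + 1)
    w = config.age_distribution if config.age_distribution is not None else default_age_weights()
    ages = rng.choice(ages_grid, size=n, p=w / w.sum())
    sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    cycles = rng.choice(np.arange(1999, 2018, 2), size=n)

    cols: dict[str, np.ndarray] = {
        ID: np.arange(1, n + 1),
        AGE: ages.astype(int),
        SEX: sexes,
        CYCLE: cycles,
    }
    # Each variable's ground-truth contribution is its implied age
    # displacement weighted by its share of the panel's total age
    # information — the attribution an efficient combined estimate of the
    # latent physiological deviation would assign.
    total_precision = sum(e.precision for e in config.effects)
    contrib: dict[str, np.ndarray] = {}
    for eff in config.effects:
        z = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        x = eff.profile(ages) + eff.baseline_sd * z + eff.noise_sd * eps
        cols[eff.variable_name] = x
        weight = eff.precision / total_precision if total_precision > 0 else 0.0
        contrib[eff.variable_name] = weight * eff.implied_years(ages, z)

    cohort = pd.DataFrame(cols)
    true_contribution = pd.DataFrame(contrib, index=cohort[ID])
    true_deviation = true_contribution.sum(axis=1)
    true_deviation.name = "true_deviation"
    return SyntheticCohort(cohort, true_contribution, true_deviation)


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Mask biomarker cells missing-completely-at-random.

    Identity, age, sex and survival columns are never masked; the
    realized missing fraction is binomial around ``rate``.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("missing rate must be in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = biomarker_columns(out)
    mask = rng.random((len(out), len(cols))) < rate
    block = out[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    out[cols] = block
    return out


def simulate_mortality(
    synthetic: SyntheticCohort,
    beta: float | None = None,
    baseline: float | None = None,
    max_followup: float | None = None,
    seed: int = 0,
    age_log_hazard: float = 0.085,
) -> pd.DataFrame:
    """Attach exponential proportional-hazards survival columns.

    The hazard for individual ``i`` is
    ``baseline * exp(beta * true_deviation_i + age_log_hazard * (age_i - 45.5))``
    — a Gompertz-like age gradient plus the deviation effect — with
    administrative censoring at ``max_followup`` years.
    """
    if synthetic.true_deviation is None:
        raise ConfigError("true_deviation is required to simulate mortality")
    beta = 0.05 if beta is None else beta
    baseline = 0.004 if baseline is None else baseline
    max_followup = 16.0 if max_followup is None else max_followup
    if baseline <= 0:
        raise ConfigError("baseline hazard must be > 0")
    rng = np.random.default_rng(seed)
    cohort = synthetic.cohort.copy()
    dev = synthetic.true_deviation.to_numpy(dtype=float)
    ages = cohort[AGE].to_numpy(dtype=float)
    hazard = baseline * np.exp(beta * dev + age_log_hazard * (ages - AGE_MID))
    t = rng.exponential(1.0 / hazard)
    cohort[FOLLOWUP] = np.minimum(t, max_followup)
    cohort[DEATH] = (t <= max_followup).astype(int)
    return cohort
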