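"""Seeded synthetic cohorts for the picture-rating / vaccine-uptake study design.

The generator emulates the structure of the survey this package analyzes:
48 pictures in 6 affective categories rated twice on a 7-point Likert scale
(-3 "dislike very much" .. +3 "like very much"), a demographic block whose
marginals resemble a large US online panel, four binary COVID-precaution
responses, and a binary vaccine-uptake outcome drawn from a logistic model
over judgment and demographic features.

Three independent standard-normal latent factors drive each participant's
rating behaviour:

``g``  negative-overweighting factor — sets the asymmetry ``kappa`` with which
       negative categories are amplified relative to positive ones (loss
       aversion and the other value-function features are monotone in it);
``u``  dispersion factor — scales rating noise, driving sigma/entropy and the
       limit-function (risk) features;
``t``  valence-shift factor — shifts all ratings up or down, tilting the
       balance of approach vs avoidance entropy (trade-off features).

Mediation structure is embedded by generating age, income and education
partially from ``g`` (correlation = ``mediation_strength``), so the product
of the ``g``->mediator path and the mediator->uptake logistic coefficient is
a known ground-truth indirect effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

CATEGORIES: tuple[str, ...] = (
    "sports",
    "disasters",
    "cute_animals",
    "aggressive_animals",
    "nature",
    "people",
)

N_PICTURES_PER_CATEGORY = 8
N_PRESENTATIONS = 2
RATINGS_PER_CATEGORY = N_PICTURES_PER_CATEGORY * N_PRESENTATIONS  # 16
RATINGS_PER_PARTICIPANT = RATINGS_PER_CATEGORY * len(CATEGORIES)  # 96

# Mean-rating targets per category.  The study never reports per-category
# rating distributions, so these are package defaults chosen to span the
# scale with three pleasant and three unpleasant categories (balanced limbs
# give every participant usable approach and avoidance value-function fits).
DEFAULT_CATEGORY_VALENCE: dict[str, float] = {
    "sports": 0.8,
    "disasters": -2.4,
    "cute_animals": 2.4,
    "aggressive_animals": -1.4,
    "nature": 1.5,
    "people": -0.7,
}

JUDGMENT_FEATURE_NAMES: tuple[str, ...] = (
    "loss_aversion",
    "risk_aversion",
    "loss_resilience",
    "ante",
    "insurance",
    "peak_positive_risk",
    "peak_negative_risk",
    "reward_tipping_point",
    "aversion_tipping_point",
    "total_reward_risk",
    "total_aversion_risk",
    "reward_aversion_tradeoff",
    "tradeoff_range",
    "reward_aversion_consistency",
    "consistency_range",
)

# Which latent factor proxies each judgment feature at generation time, with
# the (approximate) sign of the realized association.
_FEATURE_LATENT: dict[str, tuple[str, float]] = {
    "loss_aversion": ("g", +1.0),
    "risk_aversion": ("g", -1.0),
    "loss_resilience": ("g", -1.0),
    "ante": ("g", +1.0),
    "insurance": ("g", -1.0),
    "peak_positive_risk": ("u", +1.0),
    "peak_negative_risk": ("u", +1.0),
    "reward_tipping_point": ("u", +1.0),
    "aversion_tipping_point": ("u", +1.0),
    "total_reward_risk": ("u", +1.0),
    "total_aversion_risk": ("u", +1.0),
    "reward_aversion_tradeoff": ("t", -1.0),
    "tradeoff_range": ("t", +1.0),
    "reward_aversion_consistency": ("t", +1.0),
    "consistency_range": ("t", +1.0),
}

DEMO_FEATURE_NAMES: tuple[str, ...] = (
    "age",
    "income",
    "education",
    "sex",
    "ethnicity",
    "marital",
    "employment",
)

PRECAUTION_NAMES: tuple[str, ...] = (
    "mask_wearing",
    "social_distancing",
    "hand_hygiene",
    "no_large_gatherings",
)

# Categorical marginals for the demographic block (proportions of a large US
# online cohort, N=3476).  Order matters: integer codes are positions here.
SEX_LEVELS = ("male", "female", "prefer_not")
SEX_PROPS = np.array([1324, 2138, 14]) / 3476.0
ETHNICITY_LEVELS = (
    "asian_pacific",
    "black",
    "hispanic",
    "native",
    "white",
    "mixed",
    "other",
    "prefer_not",
)
ETHNICITY_PROPS = np.array([122, 227, 123, 26, 2908, 30, 16, 24]) / 3476.0
MARITAL_LEVELS = (
    "single",
    "married",
    "divorced",
    "separated",
    "widowed",
    "partner",
    "other",
)
MARITAL_PROPS = np.array([766, 1788, 416, 64, 152, 269, 21]) / 3476.0
EMPLOYMENT_LEVELS = (
    "unemployed",
    "full_time",
    "part_time",
    "self_employed",
    "multiple_jobs",
    "retired",
    "prefer_not",
)
EMPLOYMENT_PROPS = np.array([481, 1244, 312, 165, 7, 1079, 188]) / 3476.0
INCOME_PROPS = np.array([626, 906, 694, 526, 445, 230, 49]) / 3476.0
EDUCATION_PROPS = np.array([101, 734, 1030, 777, 176, 564, 94]) / 3476.0

AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 51.40, 14.92, 18.0, 70.0


@dataclass(frozen=True)
class ParticipantParams:
    """Latent rating parameters for one simulated participant."""

    kappa: float  # negative-overweighting asymmetry
    dispersion: float  # multiplicative rating-noise scale (>0)
    shift: float  # additive valence shift


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    All coefficients are on the standardized scale (per SD of the feature).
    """

    n_participants: int = 1000
    uptake_base_rate: float = 0.7264
    category_valence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_VALENCE)
    )
    judgment_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "loss_aversion": -0.6,
            "peak_positive_risk": -0.4,
            "tradeoff_range": 0.3,
        }
    )
    demo_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.8,
            "income": 0.5,
            "education": 0.5,
            "sex": -0.15,
            "ethnicity": 0.0,
            "marital": -0.1,
            "employment": 0.1,
        }
    )
    mediation_strength: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0
    # secondary shape parameters of the rating model
    neg_overweight_mean: float = 0.25
    neg_overweight_sd: float = 0.2
    dispersion_sd: float = 0.1
    shift_sd: float = 0.2
    sigma_base: float = 2.0  # rating SD at a neutral category mean
    sigma_curvature: float = 0.2  # quadratic fall of SD with the category mean
    sigma_floor: float = 0.15
    age_weight: float = 0.3  # weight of age in the income/education models
    precaution_coupling: float = 0.8

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 < self.uptake_base_rate < 1.0:
            raise ValueError("uptake_base_rate must be in (0, 1)")
        if set(self.category_valence) != set(CATEGORIES) or len(self.category_valence) != 6:
            raise ValueError(f"category_valence must map exactly the 6 labels {CATEGORIES}")
        for name in self.judgment_effects:
            if name not in JUDGMENT_FEATURE_NAMES:
                raise ValueError(f"unknown judgment feature {name!r}")
        for name in self.demo_effects:
            if name not in DEMO_FEATURE_NAMES:
                raise ValueError(f"unknown demographic feature {name!r}")
        for m in (self.judgment_effects, self.demo_effects):
            vals = np.asarray(list(m.values()), dtype=float)
            if vals.size and not np.all(np.isfinite(vals)):
                raise ValueError("coefficients must be finite")
        if not -1.0 <= self.mediation_strength <= 1.0:
            raise ValueError("mediation_strength must be in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Generative quantities recorded for recovery tests.

    ``a_paths[m]`` is the latent-factor -> mediator slope (standardized) and
    ``b_paths[m]`` the mediator's logistic coefficient, so ``indirect[m] =
    a_paths[m] * b_paths[m]`` is the embedded indirect effect through
    mediator ``m``.
    """

    seed: int
    latent: pd.DataFrame  # columns g, u, t indexed by participant_id
    intercept: float
    coefficients: dict[str, float]
    logit: np.ndarray
    prob: np.ndarray
    a_paths: dict[str, float]
    b_paths: dict[str, float]
    indirect: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "a_paths": self.a_paths,
            "b_paths": self.b_paths,
            "indirect": self.indirect,
            "latent": {c: self.latent[c].tolist() for c in self.latent.columns},
            "logit": self.logit.tolist(),
            "prob": self.prob.tolist(),
        }
        return json.dumps(payload, sort_keys=True)


def category_mean(valence: float, kappa: float, shift: float = 0.0) -> float:
    """Target mean rating for one category.

    The asymmetry acts multiplicatively, ``v * exp(-kappa * sign(v))``:
    positive ``kappa`` amplifies negative valences and damps positive ones
    (negative overweighting).  Negating both valence and kappa exactly
    mirrors the mean, which is the symmetry the feature extractor must
    respect.
    """
    return valence * float(np.exp(-kappa * np.sign(valence))) + shift


def category_sd(
    mu: float,
    params: ParticipantParams,
    noise_sd: float = 1.0,
    sigma_base: float = 2.0,
    sigma_curvature: float = 0.2,
    sigma_floor: float = 0.15,
) -> float:
    """Rating SD for one category: a quadratic fall with the category mean.

    ``sd = noise_sd * dispersion * max(sigma_base - sigma_curvature * mu^2,
    sigma_floor)``.  Dispersion shrinking as the mean grows extreme embeds
    the two regularities real raters show: sigma is an inverted-U in K
    (limit function) and entropy falls with ln|K| (value function).
    """
    return (
        noise_sd
        * params.dispersion
        * max(sigma_base - sigma_curvature * mu * mu, sigma_floor)
    )


def _draw_ratings(mu: np.ndarray, sd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(loc=mu, scale=sd)
    return np.clip(np.rint(raw), -3, 3).astype(int)


def generate_ratings(
    params: ParticipantParams,
    category_label: str,
    n_ratings: int,
    seed: int,
    *,
    category_valence: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    sigma_base: float = 2.0,
    sigma_curvature: float = 0.2,
    sigma_floor: float = 0.15,
) -> np.ndarray:
    """Draw ``n_ratings`` integer ratings in [-3, 3] for one category.

    Ratings are normal draws around the participant x category mean, rounded
    to the nearest level and clipped to the scale.
    """
    if n_ratings < 1:
        raise ValueError("n_ratings must be >= 1")
    valences = dict(category_valence or DEFAULT_CATEGORY_VALENCE)
    if category_label not in valences:
        raise ValueError(f"unknown category {category_label!r}")
    mu = category_mean(valences[category_label], params.kappa, params.shift)
    sd = category_sd(mu, params, noise_sd, sigma_base, sigma_curvature, sigma_floor)
    rng = np.random.default_rng(seed)
    return _draw_ratings(np.full(n_ratings, mu), np.full(n_ratings, max(sd, 1e-12)), rng)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Bisection for the intercept making the mean uptake probability equal
    the configured base rate."""

    def gap(b0: float) -> float:
        return float(np.mean(special.expit(b0 + eta))) - target

    return float(optimize.brentq(gap, -30.0, 30.0, xtol=1e-12))


def assign_uptake(
    features: np.ndarray,
    coefficients: np.ndarray,
    intercept: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli labels from a logistic model over standardized features.

    Returns ``(labels, probabilities)`` so oracle AUROC checks can reuse the
    exact generating probabilities.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    beta = np.asarray(coefficients, dtype=float)
    prob = special.expit(intercept + X @ beta)
    rng = np.random.default_rng(seed)
    labels = (rng.random(prob.shape) < prob).astype(int)
    return labels, prob


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _categorical(rng: np.random.Generator, props: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(len(props), size=n, p=props / props.sum())


def _ordinal_from_z(z: np.ndarray, props: np.ndarray) -> np.ndarray:
    """Map a ~standard-normal score to ordinal levels 1..k with the given
    target marginal via normal-quantile cuts."""
    cuts = stats.norm.ppf(np.cumsum(props)[:-1])
    return np.searchsorted(cuts, z) + 1


def generate_cohort(
    config: CohortConfig, *, include_ratings: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns ``(participants, ratings, ground_truth)``.  ``participants`` has
    one row per participant (demographics, precautions, uptake); ``ratings``
    is long format with exactly 96 rows per participant (48 pictures x 2
    presentations, 16 per category).  Bit-for-bit reproducible from
    ``(config, config.seed)``.
    """
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    # --- latent factors -------------------------------------------------
    g = rng.normal(size=n)
    u = rng.normal(size=n)
    t = rng.normal(size=n)
    kappa = config.neg_overweight_mean + config.neg_overweight_sd * g
    dispersion = np.exp(config.dispersion_sd * u)
    shift = config.shift_sd * t

    # --- demographics ---------------------------------------------------
    ms, aw = config.mediation_strength, config.age_weight
    z_age_raw = ms * g + np.sqrt(max(0.0, 1.0 - ms**2)) * rng.normal(size=n)
    age = np.clip(AGE_MEAN + AGE_SD * z_age_raw, AGE_MIN, AGE_MAX)
    z_age = (age - AGE_MEAN) / AGE_SD
    resid = np.sqrt(max(0.0, 1.0 - ms**2 - aw**2))
    income_z = ms * g + aw * z_age + resid * rng.normal(size=n)
    education_z = ms * g + aw * z_age + resid * rng.normal(size=n)
    income = _ordinal_from_z(income_z, INCOME_PROPS)
    education = _ordinal_from_z(education_z, EDUCATION_PROPS)
    sex = _categorical(rng, SEX_PROPS, n)
    ethnicity = _categorical(rng, ETHNICITY_PROPS, n)
    marital = _categorical(rng, MARITAL_PROPS, n)
    employment = _categorical(rng, EMPLOYMENT_PROPS, n)

    demo_values = {
        "age": age,
        "income": income.astype(float),
        "education": education.astype(float),
        "sex": sex.astype(float),
        "ethnicity": ethnicity.astype(float),
        "marital": marital.astype(float),
        "employment": employment.astype(float),
    }
    latents = {"g": g, "u": u, "t": t}

    # --- uptake ---------------------------------------------------------
    cols: list[np.ndarray] = []
    beta: list[float] = []
    names: list[str] = []
    for name, coef in config.judgment_effects.items():
        latent_name, sign = _FEATURE_LATENT[name]
        cols.append(sign * latents[latent_name])
        beta.append(float(coef))
        names.append(name)
    for name, coef in config.demo_effects.items():
        cols.append(_standardize(demo_values[name]))
        beta.append(float(coef))
        names.append(name)
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    beta_arr = np.asarray(beta)
    eta = X @ beta_arr if cols else np.zeros(n)
    intercept = _solve_intercept(eta, config.uptake_base_rate)
    uptake, prob = assign_uptake(X, beta_arr, intercept, seed=int(rng.integers(2**31)))

    # --- COVID precaution behaviours ------------------------------------
    eta_std = _standardize(eta) if eta.std() > 0 else np.zeros(n)
    precautions = {}
    for j, pname in enumerate(PRECAUTION_NAMES):
        base = (1.2, 0.6, 1.0, 0.4)[j]  # ~77/64/73/60% yes at zero coupling
        p = special.expit(base + config.precaution_coupling * eta_std)
        precautions[pname] = (rng.random(n) < p).astype(int)

    participant_id = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    participants = pd.DataFrame(
        {
            "participant_id": participant_id,
            "age": np.round(age, 2),
            "income": income,
            "education": education,
            "sex": sex,
            "ethnicity": ethnicity,
            "marital": marital,
            "employment": employment,
            **precautions,
            "uptake": uptake,
        }
    )

    # --- ratings --------------------------------------------------------
    if include_ratings:
        valence = np.array([config.category_valence[c] for c in CATEGORIES])
        mu = valence[None, :] * np.exp(-kappa[:, None] * np.sign(valence)[None, :])
        mu = mu + shift[:, None]
        sd = (
            config.noise_sd
            * dispersion[:, None]
            * np.maximum(config.sigma_base - config.sigma_curvature * mu**2, config.sigma_floor)
        )
        draws = _draw_ratings(
            np.repeat(mu[:, :, None], RATINGS_PER_CATEGORY, axis=2),
            np.maximum(np.repeat(sd[:, :, None], RATINGS_PER_CATEGORY, axis=2), 1e-12),
            rng,
        )
        pic_idx = np.tile(np.arange(N_PICTURES_PER_CATEGORY), N_PRESENTATIONS)
        pres = np.repeat([1, 2], N_PICTURES_PER_CATEGORY)
        ratings = pd.DataFrame(
            {
                "participant_id": np.repeat(participant_id, RATINGS_PER_PARTICIPANT),
                "picture_id": np.tile(
                    [f"{c}_{k + 1}" for c in CATEGORIES for k in pic_idx], n
                ),
                "category": np.tile(np.repeat(list(CATEGORIES), RATINGS_PER_CATEGORY), n),
                "presentation": np.tile(np.tile(pres, len(CATEGORIES)), n),
                "rating": draws.reshape(-1),
            }
        )
    else:
        ratings = pd.DataFrame(
            columns=["participant_id", "picture_id", "category", "presentation", "rating"]
        )

    a_paths = {m: float(config.mediation_strength) for m in ("age", "income", "education")}
    b_paths = {m: float(config.demo_effects.get(m, 0.0)) for m in ("age", "income", "education")}
    truth = GroundTruth(
        seed=config.seed,
        latent=pd.DataFrame(latents, index=participant_id),
        intercept=intercept,
        coefficients=dict(zip(names, beta_arr.tolist())),
        logit=intercept + eta,
        prob=prob,
        a_paths=a_paths,
        b_paths=b_paths,
        indirect={m: a_paths[m] * b_paths[m] for m in a_paths},
    )
    return participants, ratings, truth


def participant_params(config: CohortConfig) -> list[ParticipantParams]:
    """The per-participant rating parameters implied by (config, seed).

    Reproduces the same latent draws as :func:`generate_cohort`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    g = rng.normal(size=n)
    u = rng.normal(size=n)
    t = rng.normal(size=n)
    return [
        ParticipantParams(
            kappa=float(config.neg_overweight_mean + config.neg_overweight_sd * gi),
            dispersion=float(np.exp(config.dispersion_sd * ui)),
            shift=float(config.shift_sd * ti),
        )
        for gi, ui, ti in zip(g, u, t)
    ]


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["category_valence"] = dict(config.category_valence)
    d["judgment_effects"] = dict(config.judgment_effects)
    d["demo_effects"] = dict(config.demo_effects)
    return d
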