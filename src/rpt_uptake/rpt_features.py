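"""Relative-preference-theory (RPT) judgment features from picture ratings.

For each participant, ratings are pooled per category (both presentations,
16 ratings) into one point carrying the category mean ``K``, sample SD
``sigma``, Shannon entropy ``H`` of the 7-level rating distribution, and the
conditional entropies ``H_plus`` / ``H_minus`` over the positive / negative
levels.  Three function spaces are then fitted per participant:

value function
    OLS of ``H`` on ``ln|K|`` in two limbs (approach ``K>0``, avoidance
    ``K<0``).  Intercepts and slopes yield ante, insurance, risk aversion,
    loss resilience and loss aversion.
limit function
    one quadratic ``sigma(K) = q0 + q1*K + q2*K^2`` over all category
    points; its shape on each half-axis yields peak risks, tipping points
    and total (integrated) risks.
trade-off function
    polar summary of the ``(H_plus, H_minus)`` cloud; the angle measures the
    bias of judgment information toward avoidance, the radius the amount of
    reward-aversion conflict.

Quality-assurance filters reproduce the survey's exclusion rules: flat or
near-flat raters, incomplete feature sets, low-R^2 fits, robust-z feature
outliers, and (optionally) questionnaire speeders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RATING_LEVELS = np.arange(-3, 4)
POSITIVE_LEVELS = np.array([1, 2, 3])
NEGATIVE_LEVELS = np.array([-1, -2, -3])
SCALE_MAX = 3.0

JUDGMENT_VARIABLES: tuple[str, ...] = (
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

#: feature swap map under rating negation (mirror symmetry)
MIRROR_SWAP: dict[str, str] = {
    "risk_aversion": "loss_resilience",
    "loss_resilience": "risk_aversion",
    "ante": "insurance",
    "insurance": "ante",
    "peak_positive_risk": "peak_negative_risk",
    "peak_negative_risk": "peak_positive_risk",
    "reward_tipping_point": "aversion_tipping_point",
    "aversion_tipping_point": "reward_tipping_point",
    "total_reward_risk": "total_aversion_risk",
    "total_aversion_risk": "total_reward_risk",
    "tradeoff_range": "tradeoff_range",
    "reward_aversion_consistency": "reward_aversion_consistency",
    "consistency_range": "consistency_range",
}


class IncompleteLimb(ValueError):
    """A value-function limb has fewer than 2 usable (K != 0) points."""


class DegenerateTradeoff(ValueError):
    """All (H+, H-) points sit at the origin; no angle is defined."""


# ---------------------------------------------------------------------------
# per-category statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingRecord:
    participant_id: str
    picture_id: str
    category: str
    presentation: int
    rating: int


@dataclass(frozen=True)
class CategoryStats:
    category: str
    n: int
    K: float
    sigma: float
    H: float
    H_plus: float
    H_minus: float


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def compute_category_stats(
    ratings: Sequence[int] | np.ndarray, category: str = ""
) -> CategoryStats:
    """K, sigma and the three entropies for one participant x category.

    ``sigma`` uses the n-1 divisor (0 for a single rating); entropies are in
    bits with the 0*log0 := 0 convention.  ``H_plus`` (``H_minus``) is the
    entropy of the rating distribution restricted to the positive (negative)
    levels, 0 when no rating of that sign occurs.
    """
    r = np.asarray(ratings, dtype=int)
    if r.size == 0:
        raise ValueError("at least one rating is required")
    if r.min() < -3 or r.max() > 3:
        raise ValueError("ratings must lie in [-3, 3]")
    counts = np.array([(r == lv).sum() for lv in RATING_LEVELS])
    return CategoryStats(
        category=category,
        n=int(r.size),
        K=float(r.mean()),
        sigma=float(r.std(ddof=1)) if r.size > 1 else 0.0,
        H=_entropy_bits(counts),
        H_plus=_entropy_bits(np.array([(r == lv).sum() for lv in POSITIVE_LEVELS])),
        H_minus=_entropy_bits(np.array([(r == lv).sum() for lv in NEGATIVE_LEVELS])),
    )


# ---------------------------------------------------------------------------
# function fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValueFunctionFit:
    limb: str  # "approach" or "avoidance"
    a: float  # intercept of H on ln|K|
    b: float  # slope
    r2: float
    adj_r2: float
    F: float
    n_points: int


@dataclass(frozen=True)
class LimitFunctionFit:
    q0: float
    q1: float
    q2: float
    r2: float
    adj_r2: float
    F: float
    n_points: int

    def __call__(self, K: np.ndarray | float) -> np.ndarray | float:
        return self.q0 + self.q1 * np.asarray(K) + self.q2 * np.asarray(K) ** 2


@dataclass(frozen=True)
class TradeoffFit:
    theta: tuple[float, ...]  # degrees, radius > 0 points only
    radius: tuple[float, ...]  # all points
    mean_theta: float
    theta_range: float
    mean_radius: float
    radius_range: float
    n_points: int


def _ols_fit_stats(y: np.ndarray, yhat: np.ndarray, n: int, p: int) -> tuple[float, float, float]:
    ssr = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst > 0:
        r2 = 1.0 - ssr / sst
    else:
        r2 = 1.0 if ssr < 1e-12 else 0.0
    dof = n - p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    if dof > 0 and r2 < 1.0:
        F = (r2 / p) / ((1.0 - r2) / dof)
    else:
        F = np.inf if r2 >= 1.0 else np.nan
    return r2, adj, F


def _fit_limb(K: np.ndarray, H: np.ndarray, limb: str) -> ValueFunctionFit:
    if K.size < 2:
        raise IncompleteLimb(f"{limb} limb needs >= 2 points with K != 0, got {K.size}")
    x = np.log(np.abs(K))
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, H, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    r2, adj, F = _ols_fit_stats(H, X @ coef, K.size, p=1)
    return ValueFunctionFit(limb=limb, a=a, b=b, r2=r2, adj_r2=adj, F=F, n_points=int(K.size))


def fit_value_function(
    points: Iterable[tuple[float, float]],
) -> tuple[ValueFunctionFit, ValueFunctionFit]:
    """Two-limb logarithmic value function: OLS of H on ln|K| per sign of K.

    Points with K == 0 are unusable (ln|K| undefined) and dropped.  Raises
    :class:`IncompleteLimb` when either limb has fewer than 2 usable points.
    """
    pts = np.asarray(list(points), dtype=float)
    K, H = pts[:, 0], pts[:, 1]
    usable = K != 0
    K, H = K[usable], H[usable]
    approach = _fit_limb(K[K > 0], H[K > 0], "approach")
    avoidance = _fit_limb(K[K < 0], H[K < 0], "avoidance")
    return approach, avoidance


def fit_limit_function(points: Iterable[tuple[float, float]]) -> LimitFunctionFit:
    """Quadratic least squares of sigma on K over all category points."""
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("limit function needs >= 3 points")
    K, s = pts[:, 0], pts[:, 1]
    X = np.column_stack([np.ones_like(K), K, K**2])
    coef, _, rank, _ = np.linalg.lstsq(X, s, rcond=None)
    if rank < 3:
        raise ValueError("collinear design: need >= 3 distinct K values")
    r2, adj, F = _ols_fit_stats(s, X @ coef, K.size, p=2)
    return LimitFunctionFit(
        q0=float(coef[0]), q1=float(coef[1]), q2=float(coef[2]),
        r2=r2, adj_r2=adj, F=F, n_points=int(K.size),
    )


def fit_tradeoff_function(points: Iterable[tuple[float, float]]) -> TradeoffFit:
    """Polar summary of the (H+, H-) cloud.

    Each point maps to radius sqrt(H+^2 + H-^2) and angle atan2(H-, H+) in
    degrees.  Zero-radius points carry no directional information and are
    excluded from the angle aggregates but kept in the radius aggregates.
    """
    pts = np.asarray(list(points), dtype=float)
    hp, hm = pts[:, 0], pts[:, 1]
    radius = np.hypot(hp, hm)
    if not np.any(radius > 0):
        raise DegenerateTradeoff("all points at the origin")
    pos = radius > 0
    theta = np.degrees(np.arctan2(hm[pos], hp[pos]))
    return TradeoffFit(
        theta=tuple(float(v) for v in theta),
        radius=tuple(float(v) for v in radius),
        mean_theta=float(theta.mean()),
        theta_range=float(theta.max() - theta.min()),
        mean_radius=float(radius.mean()),
        radius_range=float(radius.max() - radius.min()),
        n_points=int(pts.shape[0]),
    )


# ---------------------------------------------------------------------------
# judgment profile
# ---------------------------------------------------------------------------


def _quad_roots(q0: float, q1: float, q2: float) -> list[float]:
    if abs(q2) > 1e-14:
        disc = q1 * q1 - 4.0 * q2 * q0
        if disc < 0:
            return []
        rt = math.sqrt(disc)
        return [(-q1 - rt) / (2 * q2), (-q1 + rt) / (2 * q2)]
    if abs(q1) > 1e-14:
        return [-q0 / q1]
    return []


def _quad_max(fit: LimitFunctionFit, lo: float, hi: float) -> float:
    cand = [lo, hi]
    if abs(fit.q2) > 1e-14:
        vertex = -fit.q1 / (2.0 * fit.q2)
        if lo < vertex < hi:
            cand.append(vertex)
    return float(max(fit(np.array(cand))))


def _integral_positive(fit: LimitFunctionFit, lo: float, hi: float) -> float:
    """Exact integral of max(sigma(K), 0) over [lo, hi]."""
    if hi <= lo:
        return 0.0
    breaks = sorted({lo, hi, *[r for r in _quad_roots(fit.q0, fit.q1, fit.q2) if lo < r < hi]})

    def antideriv(x: float) -> float:
        return fit.q0 * x + fit.q1 * x**2 / 2.0 + fit.q2 * x**3 / 3.0

    total = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        if fit((a + b) / 2.0) > 0:
            total += antideriv(b) - antideriv(a)
    return total


def _tipping_point(fit: LimitFunctionFit, side: int) -> float:
    """Smallest |K| > 0 on the given half-axis where sigma(K) = 0; the scale
    boundary 3 when the quadratic has no root there (total-function default)."""
    roots = _quad_roots(fit.q0, fit.q1, fit.q2)
    if side > 0:
        hits = [r for r in roots if 0.0 < r <= SCALE_MAX]
        return min(hits) if hits else SCALE_MAX
    hits = [r for r in roots if -SCALE_MAX <= r < 0.0]
    return abs(max(hits)) if hits else SCALE_MAX


@dataclass
class JudgmentProfile:
    """The 15 judgment variables plus fit diagnostics and QA flags."""

    loss_aversion: float
    risk_aversion: float
    loss_resilience: float
    ante: float
    insurance: float
    peak_positive_risk: float
    peak_negative_risk: float
    reward_tipping_point: float
    aversion_tipping_point: float
    total_reward_risk: float
    total_aversion_risk: float
    reward_aversion_tradeoff: float
    tradeoff_range: float
    reward_aversion_consistency: float
    consistency_range: float
    value_approach: ValueFunctionFit | None = None
    value_avoidance: ValueFunctionFit | None = None
    limit: LimitFunctionFit | None = None
    tradeoff: TradeoffFit | None = None
    qa_flags: list[str] = field(default_factory=list)

    def features(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in JUDGMENT_VARIABLES}


def extract_judgment_profile(
    value_fits: tuple[ValueFunctionFit, ValueFunctionFit],
    limit_fit: LimitFunctionFit,
    tradeoff_fit: TradeoffFit,
) -> JudgmentProfile:
    """Read the 15 judgment variables off the three fitted functions.

    Value limbs: risk aversion / loss resilience are the negated slopes of
    the approach / avoidance limb (entropy falling faster with ln|K| means a
    stronger preference for certainty); ante / insurance are the limb
    intercepts (information committed at |K| = 1); loss aversion is the
    avoidance/approach slope-magnitude ratio.  Limit-function features are
    the maxima, zero crossings and positive-part integrals of the fitted
    quadratic on each half of the rating scale.  Trade-off features are the
    polar-angle and radius aggregates.
    """
    approach, avoidance = value_fits
    b_plus, b_minus = approach.b, avoidance.b
    loss_aversion = abs(b_minus) / abs(b_plus) if abs(b_plus) > 1e-12 else np.inf

    reward_tip = _tipping_point(limit_fit, +1)
    aversion_tip = _tipping_point(limit_fit, -1)
    return JudgmentProfile(
        loss_aversion=loss_aversion,
        risk_aversion=-b_plus,
        loss_resilience=-b_minus,
        ante=approach.a,
        insurance=avoidance.a,
        peak_positive_risk=_quad_max(limit_fit, 0.0, SCALE_MAX),
        peak_negative_risk=_quad_max(limit_fit, -SCALE_MAX, 0.0),
        reward_tipping_point=reward_tip,
        aversion_tipping_point=aversion_tip,
        total_reward_risk=_integral_positive(limit_fit, 0.0, reward_tip),
        total_aversion_risk=_integral_positive(limit_fit, -aversion_tip, 0.0),
        reward_aversion_tradeoff=tradeoff_fit.mean_theta,
        tradeoff_range=tradeoff_fit.theta_range,
        reward_aversion_consistency=tradeoff_fit.mean_radius,
        consistency_range=tradeoff_fit.radius_range,
        value_approach=approach,
        value_avoidance=avoidance,
        limit=limit_fit,
        tradeoff=tradeoff_fit,
    )


# ---------------------------------------------------------------------------
# cohort-level extraction
# ---------------------------------------------------------------------------

_DIAG_COLUMNS = (
    "r2_value_approach",
    "r2_value_avoidance",
    "adj_r2_value_approach",
    "adj_r2_value_avoidance",
    "F_value_approach",
    "F_value_avoidance",
    "r2_limit",
    "adj_r2_limit",
    "F_limit",
)


def category_stats_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-(participant, category) K/sigma/H/H+/H- table."""
    g = ratings.groupby(["participant_id", "category"], sort=True)["rating"]
    out = pd.DataFrame({"n": g.size(), "K": g.mean(), "sigma": g.std(ddof=1).fillna(0.0)})
    counts = (
        ratings.pivot_table(
            index=["participant_id", "category"],
            columns="rating",
            values="picture_id",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=RATING_LEVELS, fill_value=0)
        .to_numpy(dtype=float)
    )

    def entropy_rows(c: np.ndarray) -> np.ndarray:
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, c / np.maximum(tot, 1), 0.0)
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    out["H"] = entropy_rows(counts)
    out["H_plus"] = entropy_rows(counts[:, 4:7])
    out["H_minus"] = entropy_rows(counts[:, 0:3][:, ::-1])
    return out.reset_index()


def profile_from_stats(stats: pd.DataFrame) -> JudgmentProfile:
    """Fit all three functions for one participant's category-stats rows."""
    value = fit_value_function(stats[["K", "H"]].to_numpy())
    limit = fit_limit_function(stats[["K", "sigma"]].to_numpy())
    tradeoff = fit_tradeoff_function(stats[["H_plus", "H_minus"]].to_numpy())
    return extract_judgment_profile(value, limit, tradeoff)


def compute_profiles(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant judgment profiles for a long-format rating table.

    Returns a DataFrame indexed by participant_id with the 15 feature
    columns, fit diagnostics, the rating count, and an ``incomplete`` flag
    for participants whose fits failed (too few usable points on a limb or a
    degenerate trade-off cloud).
    """
    stats = category_stats_table(ratings)
    n_ratings = ratings.groupby("participant_id").size()
    rows: dict[str, dict[str, float]] = {}
    for pid, sub in stats.groupby("participant_id", sort=True):
        row: dict[str, float] = {}
        try:
            prof = profile_from_stats(sub)
            row.update(prof.features())
            row.update(
                {
                    "r2_value_approach": prof.value_approach.r2,
                    "r2_value_avoidance": prof.value_avoidance.r2,
                    "adj_r2_value_approach": prof.value_approach.adj_r2,
                    "adj_r2_value_avoidance": prof.value_avoidance.adj_r2,
                    "F_value_approach": prof.value_approach.F,
                    "F_value_avoidance": prof.value_avoidance.F,
                    "r2_limit": prof.limit.r2,
                    "adj_r2_limit": prof.limit.adj_r2,
                    "F_limit": prof.limit.F,
                    "incomplete": False,
                }
            )
        except (IncompleteLimb, DegenerateTradeoff, ValueError):
            row.update({name: np.nan for name in JUDGMENT_VARIABLES})
            row.update({c: np.nan for c in _DIAG_COLUMNS})
            row["incomplete"] = True
        row["n_ratings"] = float(n_ratings.get(pid, 0))
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out


# ---------------------------------------------------------------------------
# quality assurance
# ---------------------------------------------------------------------------


def robust_z(x: float, median: float, mad: float) -> float:
    """0.6745 * |x - median| / MAD — the modified z-score."""
    if mad <= 0:
        return 0.0
    return 0.6745 * abs(x - median) / mad


def apply_qa_filters(
    ratings: Sequence[int] | np.ndarray,
    profile_row: Mapping[str, float] | pd.Series,
    completion_time: float | None = None,
    *,
    outlier_context: Mapping[str, tuple[float, float]] | None = None,
    expected_n: int = 96,
    r2_min: float = 0.8,
    outlier_threshold: float = 4.0,
    speeder_min_seconds: float = 800.0,
) -> tuple[bool, list[str]]:
    """Keep/drop decision for one participant, with the list of drop reasons.

    Reasons: FLAT (all ratings identical), NEAR_FLAT (ratings span <= 1
    point), INCOMPLETE (missing ratings, failed fit, or a non-finite
    feature), OUTLIER (any feature with modified z above the threshold,
    given cohort medians/MADs), LOW_FIT (any value/limit R^2 below the
    minimum), SPEEDER (completion below the time floor, only when a time is
    supplied).
    """
    reasons: list[str] = []
    r = np.asarray(ratings, dtype=float)
    if r.size < expected_n or bool(profile_row.get("incomplete", False)):
        reasons.append("INCOMPLETE")
    if r.size:
        if np.ptp(r) == 0:
            reasons.append("FLAT")
        elif np.ptp(r) <= 1:
            reasons.append("NEAR_FLAT")
    feats = np.array([float(profile_row.get(n, np.nan)) for n in JUDGMENT_VARIABLES])
    if "INCOMPLETE" not in reasons and not np.all(np.isfinite(feats)):
        reasons.append("INCOMPLETE")
    if "INCOMPLETE" not in reasons:
        r2s = [
            float(profile_row.get(k, np.nan))
            for k in ("r2_value_approach", "r2_value_avoidance", "r2_limit")
        ]
        if any(np.isfinite(v) and v < r2_min for v in r2s):
            reasons.append("LOW_FIT")
        if outlier_context:
            for name in JUDGMENT_VARIABLES:
                if name in outlier_context:
                    med, mad = outlier_context[name]
                    if robust_z(float(profile_row[name]), med, mad) > outlier_threshold:
                        reasons.append("OUTLIER")
                        break
    if completion_time is not None and completion_time < speeder_min_seconds:
        reasons.append("SPEEDER")
    return (len(reasons) == 0), reasons


def outlier_context_from_profiles(profiles: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Cohort medians and MADs per feature, from complete profiles only."""
    ok = profiles.loc[~profiles["incomplete"].astype(bool)]
    ctx = {}
    for name in JUDGMENT_VARIABLES:
        x = ok[name].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size:
            med = float(np.median(x))
            ctx[name] = (med, float(np.median(np.abs(x - med))))
    return ctx


def apply_qa(
    ratings: pd.DataFrame,
    profiles: pd.DataFrame,
    completion_times: Mapping[str, float] | None = None,
    *,
    r2_min: float = 0.8,
    outlier_threshold: float = 4.0,
    speeder_min_seconds: float = 800.0,
) -> pd.DataFrame:
    """Cohort-level QA: returns profiles plus ``keep`` and ``reasons`` columns."""
    ctx = outlier_context_from_profiles(profiles)
    by_pid = dict(tuple(ratings.groupby("participant_id")["rating"]))
    keep_flags, reason_lists = [], []
    for pid, row in profiles.iterrows():
        r = by_pid.get(pid, pd.Series(dtype=int)).to_numpy()
        ct = completion_times.get(pid) if completion_times else None
        keep, reasons = apply_qa_filters(
            r,
            row,
            ct,
            outlier_context=ctx,
            r2_min=r2_min,
            outlier_threshold=outlier_threshold,
            speeder_min_seconds=speeder_min_seconds,
        )
        keep_flags.append(keep)
        reason_lists.append(";".join(reasons))
    out = profiles.copy()
    out["keep"] = keep_flags
    out["reasons"] = reason_lists
    return out
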