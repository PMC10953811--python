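"""Group-difference statistics between vaccine-uptake groups.

Ordinal and continuous variables use the Wilcoxon rank sum test with the
expected rank sum ``n_g (N + 1) / 2`` reported per group alongside the
actual rank sum, a tie-corrected normal approximation for the two-sided p
value, and a Higher/Lower direction flag.  Nominal variables use the Pearson
chi-square test without continuity correction.  Families of p values are
adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: largest per-group size at which the rank-sum p value is computed by
#: exhaustive permutation instead of the normal approximation
EXACT_MAX_GROUP = 8


@dataclass(frozen=True)
class RankSumResult:
    variable: str
    n_a: int
    n_b: int
    rank_sum_a: float
    rank_sum_b: float
    expected_a: float
    expected_b: float
    direction_a: str  # "Higher" | "Lower" | "N/A" (exactly expected)
    direction_b: str
    z: float
    p: float


def rank_sum_test(
    group_a: np.ndarray, group_b: np.ndarray, variable: str = ""
) -> RankSumResult:
    """Wilcoxon rank sum test with midranks and tie-corrected variance.

    Under H0 each group's rank sum has expectation ``n_g (N + 1) / 2``; the
    z statistic uses variance ``n_a n_b / (N (N - 1)) * (S - N (N+1)^2 / 4)``
    with ``S`` the sum of squared midranks (equivalent to the usual
    tie-correction factor), and the p value is the two-sided normal tail.
    When both groups have at most :data:`EXACT_MAX_GROUP` observations the p
    value comes from exhaustive enumeration of all group assignments
    instead (the normal approximation is poor at such sizes).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_a = float(ranks[:n_a].sum())
    w_b = float(ranks[n_a:].sum())
    e_a = n_a * (N + 1) / 2.0
    e_b = n_b * (N + 1) / 2.0
    # tie-corrected variance of the rank sum
    sum_sq = float((ranks**2).sum())
    var = n_a * n_b / (N * (N - 1.0)) * (sum_sq - N * (N + 1.0) ** 2 / 4.0) if N > 1 else 0.0
    z = (w_a - e_a) / np.sqrt(var) if var > 0 else 0.0
    if n_a <= EXACT_MAX_GROUP and n_b <= EXACT_MAX_GROUP:
        obs_dev = abs(w_a - e_a)
        hits = total = 0
        for combo in combinations(range(N), n_a):
            total += 1
            if abs(ranks[list(combo)].sum() - e_a) >= obs_dev - 1e-9:
                hits += 1
        p = hits / total
    else:
        p = 2.0 * stats.norm.sf(abs(z)) if var > 0 else 1.0

    def direction(actual: float, expected: float) -> str:
        if actual > expected:
            return "Higher"
        if actual < expected:
            return "Lower"
        return "N/A"

    return RankSumResult(
        variable=variable,
        n_a=n_a,
        n_b=n_b,
        rank_sum_a=w_a,
        rank_sum_b=w_b,
        expected_a=e_a,
        expected_b=e_b,
        direction_a=direction(w_a, e_a),
        direction_b=direction(w_b, e_b),
        z=float(z),
        p=float(min(p, 1.0)),
    )


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c contingency table (no continuity
    correction).  Rows/columns with zero margins are dropped with a warning."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        obs = obs[keep_r][:, keep_c]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need >= 2 rows and columns with positive margins")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def bh_adjust(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, mapped back to the
    input order.  ``m`` defaults to the number of p values (the family is
    normally all tests performed, e.g. all 15 judgment variables).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_ordinal(
    data: pd.DataFrame,
    variables: list[str],
    group_col: str = "uptake",
    *,
    family_m: int | None = None,
    significant_only: bool = False,
) -> pd.DataFrame:
    """Rank-sum comparison table for a list of ordinal/continuous variables.

    One pair of rows per variable (group 0 then group 1) shaped like the
    published comparison tables: actual and expected rank sums, direction,
    two-sided p, and BH q.  ``significant_only`` restricts the BH family to
    nominally significant tests (p < .05), a nonstandard correction family
    some survey reports use; the default corrects over the full family.
    """
    g0 = data[data[group_col] == 0]
    g1 = data[data[group_col] == 1]
    results = [
        rank_sum_test(g0[v].to_numpy(), g1[v].to_numpy(), variable=v) for v in variables
    ]
    p = np.array([r.p for r in results])
    q = np.full_like(p, np.nan)
    if significant_only:
        sig = p < 0.05
        if sig.any():
            q[sig] = bh_adjust(p[sig])
    else:
        q = bh_adjust(p, m=family_m)
    rows = []
    for r, pv, qv in zip(results, p, q):
        for grp, w, e, d in (
            ("no", r.rank_sum_a, r.expected_a, r.direction_a),
            ("yes", r.rank_sum_b, r.expected_b, r.direction_b),
        ):
            rows.append(
                {
                    "variable": r.variable,
                    "group": grp,
                    "rank_sum": w,
                    "expected": e,
                    "direction": d if pv < 0.05 else "N/A",
                    "p": pv,
                    "q": qv,
                }
            )
    return pd.DataFrame(rows)


def compare_nominal(
    data: pd.DataFrame, variables: list[str], group_col: str = "uptake"
) -> pd.DataFrame:
    """Chi-square comparison table for nominal variables."""
    rows = []
    for v in variables:
        table = pd.crosstab(data[v], data[group_col]).to_numpy()
        chi2, dof, p = chi_square_test(table)
        rows.append({"variable": v, "chi2": chi2, "df": dof, "p": p})
    return pd.DataFrame(rows)
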