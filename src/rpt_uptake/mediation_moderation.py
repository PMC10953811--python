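"""Bootstrap mediation and moderation for a binary outcome.

Mediation follows the product-of-coefficients scheme: the ``a`` path is the
OLS slope of the mediator on the (standardized) independent variable, the
``b`` path is the mediator's logistic coefficient predicting the binary
outcome adjusting for the IV, and the indirect effect ``a * b`` gets a
nonparametric case-resampling percentile bootstrap CI and two-sided p value.
The total effect ``c`` (IV-only logistic) and direct effect ``c'`` are
reported for context; with a binary outcome they live on different latent
scales across models, which is why ``a * b`` is the estimand.  A Sobel z is
included as a secondary, analytic check.

Moderation fits ``DV ~ IV + moderator + IV x moderator`` (inputs
mean-centered before forming the product) and Wald-tests the product term.

Logistic fits inside the bootstrap use a small Newton-Raphson (IRLS) solver;
it is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from rpt_uptake.rpt_features import JUDGMENT_VARIABLES


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson maximum likelihood for logistic regression.

    Returns ``(beta, cov)`` where ``cov`` is the inverse observed
    information.  A tiny ridge keeps the information matrix invertible on
    degenerate resamples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    eye = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X + ridge * eye
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        if np.max(np.abs(beta)) > 50:
            raise SeparationError("logistic fit diverged (separation?)")
    eta = X @ beta
    w = special.expit(eta) * (1.0 - special.expit(eta))
    cov = np.linalg.inv((X * w[:, None]).T @ X + ridge * np.eye(k))
    return beta, cov


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"{name} is constant")
    return (x - x.mean()) / sd


@dataclass
class MediationResult:
    iv: str
    mediator: str
    dv: str
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p: float
    sobel_z: float
    sobel_p: float
    n_boot: int
    seed: int


def _paths(iv: np.ndarray, med: np.ndarray, dv: np.ndarray) -> tuple[float, float, float]:
    """(a, b, c_prime) for one sample: OLS a-path, logistic b and c'."""
    with np.errstate(invalid="ignore", divide="ignore"):
        # iv is centered/standardized; a degenerate (constant) resample
        # yields nan here and is discarded by the bootstrap caller
        a = float(np.dot(iv, med) / np.dot(iv, iv))
    ones = np.ones_like(iv)
    beta, _ = logit_irls(np.column_stack([ones, iv, med]), dv)
    return a, float(beta[2]), float(beta[1])


def mediate(
    iv: np.ndarray,
    mediator: np.ndarray,
    dv_binary: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    iv_name: str = "iv",
    mediator_name: str = "mediator",
    dv_name: str = "dv",
) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap.

    IV and mediator are standardized before fitting; the DV must be binary.
    ``p = 2 * min(frac(boot <= 0), frac(boot >= 0))`` over the bootstrap
    distribution of ``a * b``.
    """
    x = _zscore(iv, "iv")
    m = _zscore(mediator, "mediator")
    y = np.asarray(dv_binary, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("dv must be binary 0/1")
    a, b, c_prime = _paths(x, m, y)
    ones = np.ones_like(x)
    beta_c, _ = logit_irls(np.column_stack([ones, x]), y)
    c = float(beta_c[1])
    # Sobel z from the analytic SEs of a and b
    resid = m - a * x
    se_a = float(np.sqrt((resid @ resid) / (x.size - 2) / (x @ x)))
    _, cov = logit_irls(np.column_stack([ones, x, m]), y)
    se_b = float(np.sqrt(cov[2, 2]))
    sobel_se = np.sqrt(a * a * se_b**2 + b * b * se_a**2)
    sobel_z = a * b / sobel_se if sobel_se > 0 else 0.0
    sobel_p = 2.0 * stats.norm.sf(abs(sobel_z))

    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, _ = _paths(x[idx] - x[idx].mean(), m[idx] - m[idx].mean(), y[idx])
            boots[i] = ab * bb
        except (SeparationError, ZeroDivisionError):
            boots[i] = np.nan
    boots = boots[np.isfinite(boots)]
    if boots.size < max(0.5 * n_boot, 2):
        raise SeparationError("too many failed bootstrap fits")
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    return MediationResult(
        iv=iv_name,
        mediator=mediator_name,
        dv=dv_name,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=a * b,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(min(p, 1.0)),
        sobel_z=float(sobel_z),
        sobel_p=float(sobel_p),
        n_boot=int(n_boot),
        seed=int(seed),
    )


@dataclass
class ModerationResult:
    iv: str
    moderator: str
    dv: str
    interaction: float
    se: float
    p: float


def moderate(
    iv: np.ndarray,
    moderator: np.ndarray,
    dv_binary: np.ndarray,
    iv_name: str = "iv",
    moderator_name: str = "moderator",
    dv_name: str = "dv",
) -> ModerationResult:
    """Wald test of the IV x moderator interaction in a logistic model.

    IV and moderator are standardized (hence mean-centered) before the
    product term is formed, so main effects and interaction are identified.
    """
    x = _zscore(iv, "iv")
    w = _zscore(moderator, "moderator")
    y = np.asarray(dv_binary, dtype=float)
    X = np.column_stack([np.ones_like(x), x, w, x * w])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (constant or duplicated regressor)")
    beta, cov = logit_irls(X, y)
    se = float(np.sqrt(cov[3, 3]))
    z = beta[3] / se if se > 0 else 0.0
    return ModerationResult(
        iv=iv_name,
        moderator=moderator_name,
        dv=dv_name,
        interaction=float(beta[3]),
        se=se,
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


MEDIATOR_DEMOGRAPHICS: tuple[str, ...] = ("age", "income", "education")


def mediation_sweep(
    data: pd.DataFrame,
    dv: str = "uptake",
    judgment_vars: tuple[str, ...] = JUDGMENT_VARIABLES,
    demographics: tuple[str, ...] = MEDIATOR_DEMOGRAPHICS,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full 15 x 3 sweep: 45 primary mediations (judgment IV, demographic
    mediator), 45 secondary mediations (roles swapped), and 45 moderations.

    Per-cell failures (separation, constant columns) are recorded and the
    sweep continues.  No multiple-testing correction is applied.
    """
    rows = []
    y = data[dv].to_numpy()
    rng = np.random.default_rng(seed)
    for j in judgment_vars:
        for d in demographics:
            jv = data[j].to_numpy(dtype=float)
            dvv = data[d].to_numpy(dtype=float)
            for kind, iv_arr, med_arr, iv_n, med_n in (
                ("primary_mediation", jv, dvv, j, d),
                ("secondary_mediation", dvv, jv, d, j),
            ):
                cell = {
                    "analysis": kind,
                    "iv": iv_n,
                    "mediator_or_moderator": med_n,
                    "dv": dv,
                }
                try:
                    res = mediate(
                        iv_arr, med_arr, y, n_boot=n_boot, seed=int(rng.integers(2**31))
                    )
                    cell.update(
                        {
                            "estimate": res.indirect,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p": res.p,
                            "significant": res.p < 0.05,
                            "error": "",
                        }
                    )
                except (ValueError, SeparationError) as exc:
                    cell.update(
                        {
                            "estimate": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "significant": False,
                            "error": str(exc),
                        }
                    )
                rows.append(cell)
            cell = {
                "analysis": "moderation",
                "iv": j,
                "mediator_or_moderator": d,
                "dv": dv,
            }
            try:
                mod = moderate(jv, dvv, y)
                cell.update(
                    {
                        "estimate": mod.interaction,
                        "ci_low": mod.interaction - 1.96 * mod.se,
                        "ci_high": mod.interaction + 1.96 * mod.se,
                        "p": mod.p,
                        "significant": mod.p < 0.05,
                        "error": "",
                    }
                )
            except (ValueError, SeparationError) as exc:
                cell.update(
                    {
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "significant": False,
                        "error": str(exc),
                    }
                )
            rows.append(cell)
    return pd.DataFrame(rows)
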