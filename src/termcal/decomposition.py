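"""Tentative separation of terminations into induced and spontaneous.

Only a minority of surveys record whether a termination was induced (IA) or
spontaneous (ST).  In those that do, the induced share of terminations rises
steeply with the overall termination probability ``T``, so a fractional
logit fitted on (T, IA-share) observations — two per type-reporting survey,
one per contraceptive-use group — lets us impute a tentative split for every
other survey:

    P(IA) = expit(b0 + b1 * T) * T,      P(ST) = T - P(IA).

The likelihood is the Bernoulli-form quasi-likelihood on proportions
(unweighted observations), maximized by Newton-Raphson; standard errors come
from the observed information matrix.  With b1 > 0 the implied P(ST) rises
and then falls in ``T`` — the competing-risks signature: women undergoing an
induced abortion are no longer at risk of spontaneous loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Frozen default coefficients (intercept, slope on T) from a pooled fit to
#: 16 type-reporting DHS surveys (32 use-group observations); used to
#: decompose surveys when no type-reporting data are available to refit.
FROZEN_COEFS = (-1.632, 6.733)


class SeparationError(RuntimeError):
    """Likelihood unbounded: a covariate separates the response perfectly."""


class ConvergenceError(RuntimeError):
    def __init__(self, trace):
        self.trace = trace
        super().__init__(f"Newton iterations did not converge "
                         f"(last gradient norms: {trace[-3:]})")


@dataclass
class SplitModel:
    """Fitted fractional-logit split model."""

    params: np.ndarray
    names: list
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_iter: int
    converged: bool

    @property
    def b0(self) -> float:
        return float(self.params[0])

    @property
    def b1(self) -> float:
        return float(self.params[1])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }, index=self.names)


def information_criteria(loglik: float, n_params: int,
                         n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a log-likelihood."""
    aic = 2.0 * n_params - 2.0 * loglik
    bic = n_params * float(np.log(n_obs)) - 2.0 * loglik
    return aic, bic


def build_split_dataset(by_type: pd.DataFrame) -> pd.DataFrame:
    """One observation per survey x use group from per-type estimates.

    ``by_type`` must carry columns survey, use_at_pregnancy, T_IA, T_ST
    (output of per-type estimation grouped by survey and use).  The
    response is the induced share of terminations, ``T_IA / (T_IA + T_ST)``;
    cells with no terminations are dropped with a warning since the share
    is undefined there.
    """
    df = by_type.copy()
    df["T"] = df["T_IA"] + df["T_ST"]
    zero = df["T"] <= 0
    if zero.any():
        logger.warning("dropping %d cell(s) with T = 0 (IA share undefined)",
                       int(zero.sum()))
        df = df[~zero]
    df["ia_share"] = df["T_IA"] / df["T"]
    cols = ["survey", "use_at_pregnancy", "T", "ia_share"]
    if "n_pt_unweighted" in df:
        cols.append("n_pt_unweighted")
    return df[cols].reset_index(drop=True)


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(xlogy(y, mu) + xlogy(1.0 - y, 1.0 - mu)))


def fit_split_model(obs: pd.DataFrame, include_use: bool = False,
                    conf: float = 0.95, tol: float = 1e-10,
                    max_iter: int = 100) -> SplitModel:
    """Maximum-quasi-likelihood fractional logit of the IA share on ``T``.

    ``obs`` needs columns ``T`` and ``ia_share`` (plus ``use_at_pregnancy``
    when ``include_use``).  Newton-Raphson is iterated until the gradient's
    max-norm falls below ``tol``.  Wald intervals use the information
    matrix; the quasi-likelihood nature of the standard errors on
    proportion-valued data is a documented caveat.
    """
    y = obs["ia_share"].to_numpy(dtype=float)
    cols = [np.ones(len(obs)), obs["T"].to_numpy(dtype=float)]
    names = ["intercept", "T"]
    if include_use:
        cols.append(obs["use_at_pregnancy"].to_numpy(dtype=float))
        names.append("use")
    X = np.column_stack(cols)
    p = X.shape[1]
    if len(obs) < p + 1:
        raise ValueError("too few observations for the requested model")
    if np.isclose(X[:, 1].std(), 0.0):
        raise ValueError("degenerate spread in T")

    beta = np.zeros(p)
    trace = []
    converged = False
    for it in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu)
        gnorm = float(np.max(np.abs(grad)))
        trace.append(gnorm)
        if gnorm < tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (perfect separation?)") from exc
        # dampen huge steps; divergence indicates separation
        step_norm = float(np.max(np.abs(step)))
        if step_norm > 10.0:
            step *= 10.0 / step_norm
        beta = beta + step
        if float(np.max(np.abs(beta))) > 50.0:
            raise SeparationError(
                "coefficients diverging; response is perfectly separated")
    if not converged:
        raise ConvergenceError(trace)

    mu = expit(X @ beta)
    W = mu * (1.0 - mu)
    H = X.T @ (X * W[:, None])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = norm.ppf(0.5 + conf / 2.0)
    ll = _bernoulli_loglik(y, mu)
    aic, bic = information_criteria(ll, p, len(obs))
    return SplitModel(
        params=beta, names=names, se=se,
        ci_low=beta - z * se, ci_high=beta + z * se,
        loglik=ll, aic=aic, bic=bic, n_obs=len(obs),
        n_iter=it + 1, converged=converged,
    )


def decompose(T, coefs=FROZEN_COEFS) -> pd.DataFrame:
    """Split ``T`` into tentative induced and spontaneous components.

    ``coefs`` is a fitted :class:`SplitModel` or an (intercept, slope)
    pair; the default is the frozen pooled fit.  Vectorized over strata or
    surveys; ``P_IA + P_ST = T`` holds exactly for every input.
    """
    if isinstance(coefs, SplitModel):
        b0, b1 = coefs.b0, coefs.b1
    else:
        b0, b1 = coefs
    t = np.atleast_1d(np.asarray(T, dtype=float))
    if ((t < 0) | (t > 1)).any():
        raise ValueError("T must lie in [0, 1]")
    p_ia = expit(b0 + b1 * t) * t
    return pd.DataFrame({"T": t, "P_IA": p_ia, "P_ST": t - p_ia})
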