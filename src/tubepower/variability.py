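"""Variance-component estimation for tube-level mortality data.

The model behind the simulator's variability assumptions is an
intercept-only binomial GLMM on the logit scale with two independent
Normal random intercepts: one per testing day (between-day) and one per
tube (within-day, an observation-level intercept)::

    logit(p_i) = beta + a_{day(i)} + b_i
    a_d ~ Normal(0, between_day_sd**2)
    b_i ~ Normal(0, within_day_sd**2)
    dead_i ~ Binomial(exposed_i, p_i)

The marginal likelihood integrates both random effects out. Tubes are
conditionally independent given the day effect, so the tube intercept is
removed by one-dimensional Gauss-Hermite quadrature per tube, and the
day effect by *adaptive* Gauss-Hermite quadrature per day (nodes centred
at the conditional mode and scaled by the conditional curvature, which
matters because a day's posterior is far narrower than its prior once it
holds several tubes of 25 mosquitoes). Maximisation is by quasi-Newton
with the SDs bounded at zero; estimates at the boundary are reported as
0, never negative.

``TubeVarianceModel`` / ``TubeVarianceResults`` follow the
model-object/results-object convention: build the model from data, call
``fit()``, read estimates, standard errors and ``summary()`` off the
results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import norm

from .design import TubeObservation

_SQRT2 = np.sqrt(2.0)
_LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0  # logistic distribution variance

__all__ = [
    "TubeVarianceModel",
    "TubeVarianceResults",
    "ConvergenceError",
    "coefficient_of_variation",
    "conditional_r_squared",
]


class ConvergenceError(RuntimeError):
    """Marginal-likelihood maximisation failed; carries optimizer output."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


def _log_expit(x):
    """log(sigmoid(x)), numerically stable."""
    return -np.logaddexp(0.0, -x)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp over the last axis (hot path, no scipy dispatch)."""
    m = np.max(a, axis=-1, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=-1, keepdims=True)))[..., 0]


class TubeVarianceModel:
    """Intercept-only binomial GLMM with day and tube random intercepts.

    Parameters
    ----------
    n_dead, n_exposed : array-like of int
        Per-tube 24 h death counts and exposure counts.
    day : array-like
        Day label of each tube (any hashable values).
    """

    def __init__(self, n_dead, n_exposed, day):
        self.n_dead = np.asarray(n_dead, dtype=float)
        self.n_exposed = np.asarray(n_exposed, dtype=float)
        day = np.asarray(day)
        if not (len(self.n_dead) == len(self.n_exposed) == len(day)):
            raise ValueError("n_dead, n_exposed and day must have equal length")
        if np.any(self.n_dead < 0) or np.any(self.n_dead > self.n_exposed):
            raise ValueError("counts must satisfy 0 <= n_dead <= n_exposed")
        if np.any(self.n_exposed < 1):
            raise ValueError("n_exposed must be >= 1")
        self.day_labels, self.day_index = np.unique(day, return_inverse=True)
        self.n_days = len(self.day_labels)
        self.n_tubes = len(self.n_dead)
        if self.n_days < 2:
            raise ValueError(
                "between-day SD is undefined with a single testing day; "
                "at least 2 days are required"
            )
        if not np.any(np.bincount(self.day_index) >= 2):
            raise ValueError("at least one day must hold >= 2 tubes")
        self._ll_const = float(
            np.sum(
                gammaln(self.n_exposed + 1)
                - gammaln(self.n_dead + 1)
                - gammaln(self.n_exposed - self.n_dead + 1)
            )
        )

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_observations(cls, observations: Iterable[TubeObservation]) -> "TubeVarianceModel":
        obs = list(observations)
        return cls(
            [o.n_dead for o in obs],
            [o.n_exposed for o in obs],
            [o.day_id for o in obs],
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        dead_col: str = "n_dead",
        exposed_col: str = "n_exposed",
        day_col: str = "day_id",
    ) -> "TubeVarianceModel":
        return cls(data[dead_col], data[exposed_col], data[day_col])

    # ---- likelihood ---------------------------------------------------
    def _log_h(self, a_tube: np.ndarray, beta: float, sigma_w: float, nodes) -> np.ndarray:
        """log of each tube's likelihood with its intercept integrated out.

        ``a_tube`` is the day effect mapped to tubes (shape (tubes,)).
        """
        x, logw = nodes
        if sigma_w < 1e-8:
            eta = beta + a_tube
            return self.n_dead * _log_expit(eta) + (self.n_exposed - self.n_dead) * _log_expit(-eta)
        eta = beta + a_tube[:, None] + _SQRT2 * sigma_w * x[None, :]
        ll = (
            self.n_dead[:, None] * _log_expit(eta)
            + (self.n_exposed - self.n_dead)[:, None] * _log_expit(-eta)
        )
        return _logsumexp_rows(ll + logw[None, :])

    def _day_logpost(self, a_day: np.ndarray, beta, sigma_w, sigma_b, nodes) -> np.ndarray:
        """Per-day unnormalised log posterior of the day effect, F_d(a_d)."""
        log_h = self._log_h(a_day[self.day_index], beta, sigma_w, nodes)
        per_day = np.bincount(self.day_index, weights=log_h, minlength=self.n_days)
        return per_day + norm.logpdf(a_day, scale=sigma_b)

    def loglike(
        self,
        params: Sequence[float],
        inner_nodes: int = 31,
        outer_nodes: int = 21,
    ) -> float:
        """Marginal log-likelihood at ``params = (beta, sigma_w, sigma_b)``.

        Includes the binomial combinatorial constant, so values are
        comparable across software.
        """
        beta, sigma_w, sigma_b = (float(p) for p in params)
        if sigma_w < 0 or sigma_b < 0:
            raise ValueError("standard deviations must be >= 0")
        x_in, w_in = np.polynomial.hermite.hermgauss(inner_nodes)
        nodes = (x_in, np.log(w_in) - 0.5 * np.log(np.pi))

        if sigma_b < 1e-8:
            total = float(np.sum(self._log_h(np.zeros(self.n_tubes), beta, sigma_w, nodes)))
            return total + self._ll_const

        # adaptive GH over the day effect: damped Newton to the per-day mode
        a = np.zeros(self.n_days)
        h = 1e-4
        prior_curv = -1.0 / sigma_b**2
        for _ in range(40):
            f0 = self._day_logpost(a, beta, sigma_w, sigma_b, nodes)
            fp = self._day_logpost(a + h, beta, sigma_w, sigma_b, nodes)
            fm = self._day_logpost(a - h, beta, sigma_w, sigma_b, nodes)
            grad = (fp - fm) / (2 * h)
            curv = (fp - 2 * f0 + fm) / h**2
            curv = np.where(curv < -1e-12, curv, prior_curv)  # keep Newton descending
            step = np.clip(-grad / curv, -2.0, 2.0)
            a = a + step
            if np.max(np.abs(step)) < 1e-8:
                break
        f0 = self._day_logpost(a, beta, sigma_w, sigma_b, nodes)
        fp = self._day_logpost(a + h, beta, sigma_w, sigma_b, nodes)
        fm = self._day_logpost(a - h, beta, sigma_w, sigma_b, nodes)
        curv = (fp - 2 * f0 + fm) / h**2
        scale = 1.0 / np.sqrt(np.maximum(-curv, 1e-12))

        x_out, w_out = np.polynomial.hermite.hermgauss(outer_nodes)
        contrib = np.empty((outer_nodes, self.n_days))
        for j in range(outer_nodes):
            t = a + _SQRT2 * scale * x_out[j]
            contrib[j] = (
                np.log(w_out[j]) + x_out[j] ** 2 + self._day_logpost(t, beta, sigma_w, sigma_b, nodes)
            )
        log_l_day = np.log(_SQRT2 * scale) + _logsumexp_rows(contrib.T)
        return float(np.sum(log_l_day)) + self._ll_const

    # ---- fitting ------------------------------------------------------
    def fit(
        self,
        start_params: Sequence[float] | None = None,
        inner_nodes: int = 31,
        outer_nodes: int = 21,
        maxiter: int = 300,
    ) -> "TubeVarianceResults":
        """Maximise the marginal likelihood; returns a results object."""
        if start_params is None:
            p_bar = np.clip(self.n_dead.sum() / self.n_exposed.sum(), 1e-3, 1 - 1e-3)
            start_params = (float(np.log(p_bar / (1 - p_bar))), 0.3, 0.5)

        # Optimise on the variance scale: the marginal likelihood is even in
        # each SD around zero, so its SD-scale gradient vanishes at the
        # boundary and a gradient-based optimizer can stall in the zero
        # corner; on the variance scale the boundary gradient is finite.
        def objective(theta):
            beta, v_w, v_b = theta
            return -self.loglike(
                (beta, np.sqrt(max(v_w, 0.0)), np.sqrt(max(v_b, 0.0))),
                inner_nodes,
                outer_nodes,
            )

        beta0, sw0, sb0 = start_params
        res = optimize.minimize(
            objective,
            np.array([beta0, sw0**2, sb0**2]),
            method="L-BFGS-B",
            bounds=[(-15.0, 15.0), (0.0, 64.0), (0.0, 64.0)],
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise ConvergenceError(
                f"marginal likelihood maximisation failed: {res.message}", res
            )
        beta, sigma_w, sigma_b = res.x[0], np.sqrt(res.x[1]), np.sqrt(res.x[2])
        bse = self._bse(np.array([beta, sigma_w, sigma_b]), inner_nodes, outer_nodes)
        return TubeVarianceResults(
            model=self,
            intercept=float(beta),
            within_day_sd=float(max(sigma_w, 0.0)),
            between_day_sd=float(max(sigma_b, 0.0)),
            llf=float(-res.fun),
            bse=bse,
            converged=bool(res.success),
            optimizer_result=res,
        )

    def _bse(self, theta, inner_nodes, outer_nodes) -> np.ndarray:
        """Delta-method SEs from a central-difference Hessian; NaN on failure
        (routine at a variance boundary)."""
        h = 1e-3
        k = len(theta)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = np.empty((k, k))
                f = lambda t: self.loglike(t, inner_nodes, outer_nodes)
                for i in range(k):
                    for j in range(i, k):
                        ei = np.eye(k)[i] * h
                        ej = np.eye(k)[j] * h
                        lo_i = max(theta[i] - h, 0) if i > 0 else theta[i] - h
                        if (i > 0 and theta[i] < 2 * h) or (j > 0 and theta[j] < 2 * h):
                            hess[i, j] = hess[j, i] = np.nan
                            continue
                        hess[i, j] = hess[j, i] = (
                            f(theta + ei + ej)
                            - f(theta + ei - ej)
                            - f(theta - ei + ej)
                            + f(theta - ei - ej)
                        ) / (4 * h * h)
                if np.any(np.isnan(hess)):
                    return np.full(k, np.nan)
                cov = np.linalg.inv(-hess)
                d = np.diag(cov)
                return np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
        except Exception:
            return np.full(k, np.nan)


@dataclass
class TubeVarianceResults:
    """Fitted variance components of the tube-mortality GLMM."""

    model: TubeVarianceModel
    intercept: float
    within_day_sd: float
    between_day_sd: float
    llf: float
    bse: np.ndarray
    converged: bool
    optimizer_result: object = None

    @property
    def within_day_variance(self) -> float:
        return self.within_day_sd**2

    @property
    def between_day_variance(self) -> float:
        return self.between_day_sd**2

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.within_day_sd, self.between_day_sd])

    @property
    def n_tubes(self) -> int:
        return self.model.n_tubes

    @property
    def n_days(self) -> int:
        return self.model.n_days

    def conditional_r_squared(self, fixed_effect_variance: float = 0.0) -> float:
        """Conditional R² of the fitted model (fixed + random effects)."""
        return conditional_r_squared(
            fixed_effect_variance, [self.within_day_variance, self.between_day_variance]
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "within_day_sd": self.within_day_sd,
            "between_day_sd": self.between_day_sd,
            "within_day_variance": self.within_day_variance,
            "between_day_variance": self.between_day_variance,
            "log_likelihood": self.llf,
            "conditional_r_squared": self.conditional_r_squared(),
            "n_tubes": self.n_tubes,
            "n_days": self.n_days,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Tube mortality variance components (binomial GLMM, logit link)",
            "=" * 62,
            f"{'tubes':<28}{self.n_tubes:>10}",
            f"{'testing days':<28}{self.n_days:>10}",
            f"{'log-likelihood':<28}{self.llf:>10.3f}",
            f"{'converged':<28}{str(self.converged):>10}",
            "-" * 62,
            f"{'':<22}{'estimate':>10}{'std err':>10}",
        ]
        names = ["intercept (logit)", "within-day SD", "between-day SD"]
        for name, est, se in zip(names, self.params, self.bse):
            se_s = f"{se:>10.4f}" if np.isfinite(se) else f"{'--':>10}"
            lines.append(f"{name:<22}{est:>10.4f}{se_s}")
        lines += [
            "-" * 62,
            f"{'within-day variance':<28}{self.within_day_variance:>10.4f}",
            f"{'between-day variance':<28}{self.between_day_variance:>10.4f}",
            f"{'conditional R2 (random)':<28}{self.conditional_r_squared():>10.4f}",
        ]
        return "\n".join(lines)


def conditional_r_squared(
    fixed_effect_variance: float, random_effect_variances: Sequence[float]
) -> float:
    """Conditional R² for a binomial-logit mixed model.

    ``(var_fixed + sum(var_random)) / (var_fixed + sum(var_random) + pi^2/3)``
    with the logistic distribution-specific residual variance pi^2/3.
    """
    if fixed_effect_variance < 0 or any(v < 0 for v in random_effect_variances):
        raise ValueError("variances must be >= 0")
    explained = fixed_effect_variance + float(np.sum(random_effect_variances))
    return explained / (explained + _LOGIT_RESIDUAL_VARIANCE)


def coefficient_of_variation(
    data,
    dead_col: str = "n_dead",
    exposed_col: str = "n_exposed",
    day_col: str = "day_id",
    overall: str = "daily_means",
) -> tuple[pd.Series, float]:
    """Per-day and overall coefficients of variation of tube mortality.

    The per-day CoV (intra-assay precision) is the SD of that day's tube
    mortality proportions divided by their mean. The overall CoV
    (inter-assay precision) is, by default, the SD of the daily mean
    mortalities divided by the grand mean of the daily means; pass
    ``overall="pooled_tubes"`` to compute it across all tubes pooled.
    Sample SDs (ddof=1) throughout. Days with a zero mean mortality have
    an undefined CoV and raise.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(
            {
                day_col: [o.day_id for o in data],
                dead_col: [o.n_dead for o in data],
                exposed_col: [o.n_exposed for o in data],
            }
        )
    if overall not in ("daily_means", "pooled_tubes"):
        raise ValueError("overall must be 'daily_means' or 'pooled_tubes'")
    mortality = data[dead_col] / data[exposed_col]
    groups = mortality.groupby(data[day_col])
    per_day = {}
    for day, values in groups:
        if len(values) < 2:
            continue
        mean = values.mean()
        if mean == 0:
            raise ValueError(f"day {day!r}: zero mean mortality, CoV undefined")
        per_day[day] = values.std(ddof=1) / mean
    per_day = pd.Series(per_day, name="cov", dtype=float)

    daily_means = groups.mean()
    if len(daily_means) < 2:
        raise ValueError("overall CoV requires >= 2 testing days")
    if overall == "daily_means":
        grand = daily_means.mean()
        if grand == 0:
            raise ValueError("zero grand mean mortality, CoV undefined")
        overall_cov = float(daily_means.std(ddof=1) / grand)
    else:
        grand = mortality.mean()
        if grand == 0:
            raise ValueError("zero mean mortality, CoV undefined")
        overall_cov = float(mortality.std(ddof=1) / grand)
    return per_day, overall_cov
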