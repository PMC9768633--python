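"""Epidemiological linkage analyses for deprivation scores.

Three analysis families link the index to aggregated health-outcome
tables (events and person-years by region, year, sex and 5-year age
group):

* direct age standardization with the 2013 European Standard Population,
* rate trajectories by deprivation group (quintile 1 / 2-4 / 5),
* multilevel Poisson rate ratios across quintiles with a log-population
  offset and a district-level random intercept,
* a linear deprivation-gradient regression (slope over the [0, 1] index
  range and adjusted R-squared).

The random-intercept Poisson likelihood is integrated by adaptive
Gauss-Hermite quadrature; with the random effect disabled the model
reduces to an ordinary Poisson GLM fitted by statsmodels.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .index import quintile_group

__all__ = [
    "ESP_2013",
    "age_standardize",
    "standardized_rates",
    "quintile_group_rates",
    "PoissonRateRatio",
    "poisson_rate_ratios",
    "gradient_regression",
    "EpiError",
]


class EpiError(ValueError):
    pass


# 2013 European Standard Population, per 100,000, 5-year groups with the
# infant group (0) merged into 0-4 and ages 90-94/95+ merged into 90+ to
# match the age grouping of typical aggregated outcome tables.
ESP_2013 = pd.Series(
    {
        "0-4": 5000, "5-9": 5500, "10-14": 5500, "15-19": 5500,
        "20-24": 6000, "25-29": 6000, "30-34": 6500, "35-39": 7000,
        "40-44": 7000, "45-49": 7000, "50-54": 7000, "55-59": 6500,
        "60-64": 6000, "65-69": 5500, "70-74": 5000, "75-79": 4000,
        "80-84": 2500, "85-89": 1500, "90+": 1000,
    },
    name="esp2013",
)
assert int(ESP_2013.sum()) == 100_000


def age_standardize(events: Mapping[str, float] | pd.Series,
                    population: Mapping[str, float] | pd.Series,
                    standard: pd.Series | None = None) -> float:
    """Directly age-standardized rate per 100,000.

    ``rate = 100000 * sum_a w_a (events_a / pop_a) / sum_a w_a`` over the
    age groups shared with the standard.  An age cell with zero
    population and nonzero events is an error; with zero events the cell
    is dropped and the standard weights renormalize over the remaining
    groups.
    """
    std = ESP_2013 if standard is None else standard
    ev = pd.Series(events, dtype=float)
    po = pd.Series(population, dtype=float)
    common = std.index.intersection(ev.index)
    if len(common) == 0:
        raise EpiError("no age groups shared with the standard population")
    ev, po, w = ev[common], po[common], std[common].astype(float)
    zero_pop = po == 0
    if (zero_pop & (ev > 0)).any():
        bad = ev.index[zero_pop & (ev > 0)][0]
        raise EpiError(f"zero population but {ev[bad]:g} events in age "
                       f"group {bad!r}")
    if zero_pop.any():
        warnings.warn(f"dropping empty age groups {list(ev.index[zero_pop])}"
                      "; standard weights renormalized", stacklevel=2)
        ev, po, w = ev[~zero_pop], po[~zero_pop], w[~zero_pop]
    return float(100_000 * (w * ev / po).sum() / w.sum())


def standardized_rates(outcomes: pd.DataFrame,
                       by: Sequence[str] = ("sex", "year"),
                       standard: pd.Series | None = None) -> pd.DataFrame:
    """Age-standardized rate per 100,000 for each group of *by* columns.

    ``outcomes`` columns: age_group, events, population, plus the *by*
    columns.  Events and populations are summed within age groups first.
    """
    rows = []
    for key, sub in outcomes.groupby(list(by)):
        agg = sub.groupby("age_group")[["events", "population"]].sum()
        rate = age_standardize(agg["events"], agg["population"], standard)
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, rate))
    return pd.DataFrame(rows, columns=[*by, "rate"])


def quintile_group_rates(outcomes: pd.DataFrame,
                         district_scores: pd.DataFrame,
                         standard: pd.Series | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rate trajectories for the low / mid / high deprivation groups.

    ``district_scores`` must carry region_id, year and quintile (per
    year).  Returns ``(rates, declines)``: standardized rates per group,
    sex and year, and per group and sex the absolute decline (first
    minus last year) and the relative decline (fraction of the
    first-year rate).
    """
    q = district_scores[["region_id", "year", "quintile"]].copy()
    q["group"] = quintile_group(q["quintile"])
    d = outcomes.merge(q, left_on=["district_id", "year"],
                       right_on=["region_id", "year"], how="left")
    missing = d["group"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} outcome rows without a "
                      "quintile assignment dropped", stacklevel=2)
        d = d[~missing]
    rates = standardized_rates(d, by=("group", "sex", "year"),
                               standard=standard)
    rows = []
    for (grp, sex), sub in rates.groupby(["group", "sex"]):
        sub = sub.sort_values("year")
        first, last = sub["rate"].iloc[0], sub["rate"].iloc[-1]
        rows.append((grp, sex, first, last, first - last,
                     (first - last) / first if first else np.nan))
    declines = pd.DataFrame(rows, columns=[
        "group", "sex", "first_rate", "last_rate", "absolute_decline",
        "relative_decline"])
    return rates, declines


# ---------------------------------------------------------------------------
# multilevel Poisson rate ratios

class PoissonRateRatio(BaseEstimator):
    """Quintile rate ratios from a (multilevel) Poisson count model.

    Model: ``events ~ Poisson(exp(age effects + quintile effects
    + log population + u_district))`` with ``u ~ N(0, sigma^2)`` when
    ``district_re`` is on.  Quintile 1 (lowest deprivation) is the
    reference; exponentiated coefficients are returned with Wald
    intervals.  The marginal likelihood is integrated with
    Gauss-Hermite quadrature; ``district_re=False`` drops the random
    intercept and delegates to a statsmodels Poisson GLM (then the
    single-age-group, two-district rate ratio is exact).
    """

    def __init__(self, district_re: bool = True, alpha: float = 0.05,
                 n_quad: int = 25) -> None:
        self.district_re = district_re
        self.alpha = alpha
        self.n_quad = n_quad

    def _design(self, df: pd.DataFrame):
        ages = sorted(df["age_group"].unique())
        quints = sorted(df["quintile"].unique())
        X = [np.ones(len(df))]
        names = ["intercept"]
        for a in ages[1:]:
            X.append((df["age_group"] == a).to_numpy(float))
            names.append(f"age[{a}]")
        for q in quints[1:]:
            X.append((df["quintile"] == q).to_numpy(float))
            names.append(f"quintile[{q}]")
        return np.column_stack(X), names, quints

    def fit(self, df: pd.DataFrame) -> "PoissonRateRatio":
        """``df`` columns: events, population, age_group, district_id,
        quintile.  Sexes are modelled separately by the caller."""
        d = df.reset_index(drop=True)
        ev = d["events"].to_numpy()
        if not np.allclose(ev, np.round(ev)):
            raise EpiError("event counts must be integers")
        if (d["population"] <= 0).any():
            raise EpiError("non-positive population")
        y = ev.astype(float)
        off = np.log(d["population"].to_numpy(float))
        X, names, quints = self._design(d)

        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        if self.district_re:
            codes, _ = pd.factorize(d["district_id"])
            nodes, wts = np.polynomial.hermite_e.hermegauss(self.n_quad)
            logw = np.log(wts) - 0.5 * np.log(2 * np.pi)
            const = float(gammaln(y + 1).sum())

            n_dist = int(codes.max()) + 1

            def nll_grad(theta):
                beta, log_sig = theta[:-1], theta[-1]
                sig = np.exp(log_sig)
                eta = X @ beta + off
                lam = eta[:, None] + sig * nodes[None, :]  # (n, K)
                mu = np.exp(lam)
                cell = y[:, None] * lam - mu
                per = np.zeros((n_dist, len(nodes)))
                np.add.at(per, codes, cell)
                per += logw[None, :]
                ll_d = logsumexp(per, axis=1)
                p = np.exp(per - ll_d[:, None])  # posterior node weights
                resid = (y[:, None] - mu) * p[codes]  # (n, K)
                g_beta = -X.T @ resid.sum(axis=1)
                g_sig = -float((resid * (sig * nodes[None, :])).sum())
                return (-(ll_d.sum() - const),
                        np.append(g_beta, g_sig))

            x0 = np.append(glm.params, np.log(0.1))
            res = optimize.minimize(nll_grad, x0, method="BFGS", jac=True,
                                    options={"maxiter": 500, "gtol": 1e-6})
            gnorm = float(np.max(np.abs(res.jac)))
            # BFGS reports precision loss near flat optima; accept when the
            # gradient is numerically at zero relative to the deviance scale
            self.converged_ = bool(res.success
                                   or gnorm < 1e-4 * (1 + abs(res.fun)))
            if not self.converged_:
                warnings.warn("random-intercept Poisson fit did not "
                              "converge; estimates flagged", stacklevel=2)
            nll = lambda th: nll_grad(th)[0]
            theta = res.x
            # covariance from the numerical inverse Hessian
            try:
                from statsmodels.tools.numdiff import approx_hess
                H = approx_hess(theta, nll)
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = res.hess_inv
            params = theta[:-1]
            se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
            self.sigma_ = float(np.exp(theta[-1]))
            self.loglike_ = -float(res.fun)
        else:
            params = np.asarray(glm.params)
            se = np.asarray(glm.bse)
            self.sigma_ = 0.0
            self.converged_ = True
            self.loglike_ = float(glm.llf)

        self.param_names_ = names
        self.params_ = pd.Series(params, index=names)
        self.bse_ = pd.Series(se, index=names)
        from scipy.stats import norm
        zq = norm.ppf(1 - self.alpha / 2)
        rows = [(quints[0], 1.0, np.nan, np.nan)]
        for q in quints[1:]:
            b = self.params_[f"quintile[{q}]"]
            s = self.bse_[f"quintile[{q}]"]
            rows.append((q, float(np.exp(b)), float(np.exp(b - zq * s)),
                         float(np.exp(b + zq * s))))
        self.rate_ratios_ = pd.DataFrame(
            rows, columns=["quintile", "rr", "ci_low", "ci_high"])
        return self


def poisson_rate_ratios(df: pd.DataFrame, district_re: bool = True,
                        **kwargs) -> pd.DataFrame:
    """Fit :class:`PoissonRateRatio` and return the rate-ratio table."""
    return PoissonRateRatio(district_re=district_re,
                            **kwargs).fit(df).rate_ratios_


# ---------------------------------------------------------------------------
# deprivation gradient

def gradient_regression(outcome: pd.Series | np.ndarray,
                        gisd: pd.Series | np.ndarray) -> dict[str, float]:
    """Least-squares gradient of a district outcome on the 0-1 index.

    Returns the slope (= predicted difference between the most and least
    deprived district, since the index spans [0, 1]), its standard error
    and confidence bounds, and the adjusted R-squared.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(gisd, float)
    if len(y) < 3:
        raise EpiError("gradient regression needs >= 3 districts")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    return {
        "slope": float(fit.params[1]),
        "slope_se": float(fit.bse[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "range_estimate": float(fit.params[1]),
        "adj_r2": float(fit.rsquared_adj),
        "intercept": float(fit.params[0]),
    }
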