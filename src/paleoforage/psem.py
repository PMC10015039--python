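"""Piecewise structural equation models over the CTU summary table.

A piecewise SEM is estimated as a set of local regressions, one per
causal path, rather than a single covariance model.  Every component here
is a quasibinomial logistic regression: binomial variance with logit
link, a dispersion multiplier phi estimated from the Pearson chi-square,
and t-based inference on n-k residual degrees of freedom -- appropriate
for proportion responses (NISP shares, habitat suitabilities, a
rescaled population proxy) observed on a handful of aggregated units.

Two model structures are provided:

- the species model: population ~ climate; suitability ~ climate;
  zooarchaeological share ~ suitability + population;
- the red-deer mediation model: population ~ climate;
  combined share of the two top-ranked species ~ population;
  red-deer share ~ combined share.

Coefficients are reported raw (logit scale) and standardized with the
latent-variable convention for logistic models,
std_beta = b * sd(x) / sqrt(var(eta) + pi^2 / 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import (
    ConvergenceError,
    DegenerateModelError,
    InsufficientDataError,
)

__all__ = [
    "PathFit",
    "PSEMResult",
    "fit_quasibinomial",
    "standardize_path",
    "squeeze_proportions",
    "fit_species_psem",
    "fit_reddeer_psem",
]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass
class PathFit:
    """One fitted path: coefficients with dispersion-corrected inference.

    Arrays are aligned with ``terms`` (intercept first). ``std_beta`` /
    ``std_se`` cover the non-intercept terms only (NaN for the
    intercept).
    """

    response: str
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    std_beta: np.ndarray
    std_se: np.ndarray
    phi: float
    df_resid: int
    n_iter: int
    converged: bool
    eta: np.ndarray = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "response": self.response,
                "term": self.terms,
                "b": self.coef,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "std_beta": self.std_beta,
                "std_se": self.std_se,
                "phi": self.phi,
                "df_resid": self.df_resid,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "b": float(self.coef[i]),
            "se": float(self.se[i]),
            "t": float(self.t[i]),
            "p": float(self.p[i]),
            "std_beta": float(self.std_beta[i]),
            "std_se": float(self.std_se[i]),
        }


def squeeze_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Pull boundary proportions off 0/1: (y (n-1) + 0.5) / n.

    ``n`` defaults to the number of observations. Applied only when a
    boundary value is present, so strictly interior data pass unchanged.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise DegenerateModelError("proportions must lie in [0, 1]")
    if np.any((y == 0) | (y == 1)):
        n = n or len(y)
        y = (y * (n - 1) + 0.5) / n
    return y


def fit_quasibinomial(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
    response: str = "y",
) -> PathFit:
    """Quasibinomial logistic regression by IRLS with unit prior weights.

    Iteratively reweighted least squares with binomial variance
    mu (1 - mu) and logit link, run to a relative deviance change below
    1e-8 or 100 iterations. The dispersion phi is the Pearson chi-square
    over n - k; standard errors are sqrt(phi) times the binomial-model
    SEs and p-values are two-sided t on n - k degrees of freedom --
    matching the standard quasibinomial GLM.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[0] == 1 and len(y) > 1:
            Xm = Xm.T
        names = [f"x{i + 1}" for i in range(Xm.shape[1])]
    if np.any((y <= 0) | (y >= 1)):
        raise DegenerateModelError("response must be strictly inside (0, 1); squeeze first")
    for j, name in enumerate(names):
        if Xm.shape[1] and np.std(Xm[:, j]) == 0:
            raise DegenerateModelError(f"zero-variance predictor {name!r}")
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["(Intercept)"] + names
    n, k = Xm.shape
    if n <= k:
        raise InsufficientDataError(f"need more observations ({n}) than parameters ({k})")
    if n < 10:
        warnings.warn(
            f"quasibinomial fit on only n={n} units: inference is fragile", stacklevel=2
        )
    beta = np.zeros(k)
    # standard logistic-regression starting value
    mu = np.full(n, y.mean())
    eta = np.full(n, logit(y.mean()))
    dev_old = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        w = mu * (1.0 - mu)
        if np.any(w < 1e-12):
            raise ConvergenceError("fitted probabilities collapsed to 0/1 (separation)")
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xm * sw[:, None], z * sw, rcond=None)
        eta = Xm @ beta
        mu = expit(eta)
        dev = float(np.sum(w_dev(y, mu)))
        if abs(dev - dev_old) < IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {IRLS_MAX_ITER} iterations")
    w = mu * (1.0 - mu)
    pearson = float(np.sum((y - mu) ** 2 / w))
    df_resid = n - k
    phi = pearson / df_resid
    XtWX = (Xm * w[:, None]).T @ Xm
    cov = phi * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    std_beta, std_se = _standardize(beta, se, Xm, eta, names)
    return PathFit(
        response=response,
        terms=tuple(names),
        coef=beta,
        se=se,
        t=tvals,
        p=pvals,
        std_beta=std_beta,
        std_se=std_se,
        phi=phi,
        df_resid=df_resid,
        n_iter=n_iter,
        converged=converged,
        eta=eta,
    )


def w_dev(y, mu):
    """Quasibinomial deviance contributions for unit weights."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * (term1 + term2)


def _standardize(beta, se, Xm, eta, names):
    """Latent-theoretic standardization for logit-link models."""
    denom = np.sqrt(np.var(eta) + np.pi**2 / 3.0)
    std_beta = np.full(len(beta), np.nan)
    std_se = np.full(len(beta), np.nan)
    for i, name in enumerate(names):
        if name == "(Intercept)":
            continue
        sd_x = float(np.std(Xm[:, i]))
        if sd_x == 0:
            raise DegenerateModelError(f"zero-variance predictor {name!r}")
        factor = sd_x / denom
        std_beta[i] = beta[i] * factor
        std_se[i] = se[i] * factor
    return std_beta, std_se


def standardize_path(fit: PathFit, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recompute standardized betas/SEs of a fit from its design matrix.

    Exposed mainly so independently obtained fits (or alternative design
    matrices) can be put on the standardized scale; identical to the
    values stored on the fit when given the fit's own design.
    """
    Xm = np.column_stack([np.ones(len(X)), np.atleast_2d(np.asarray(X, float).T).T])
    return _standardize(fit.coef, fit.se, Xm, fit.eta, list(fit.terms))


@dataclass
class PSEMResult:
    """A named set of fitted paths keyed by (response, predictor)."""

    name: str
    paths: dict[str, PathFit]

    def table(self) -> pd.DataFrame:
        return pd.concat([f.table() for f in self.paths.values()], ignore_index=True)

    def path(self, response: str, term: str) -> dict:
        return self.paths[response][term]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        raise DegenerateModelError("zero-variance predictor")
    return (x - np.mean(x)) / sd


def _minmax_unit(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise DegenerateModelError("constant variable cannot be scaled to (0, 1)")
    return (x - lo) / (hi - lo)


def _population_response(summary: pd.DataFrame) -> np.ndarray:
    """Mean SPD rescaled to (0, 1) so it can serve as a quasibinomial
    response (min-max then boundary squeeze)."""
    return squeeze_proportions(_minmax_unit(summary["mean_spd"].to_numpy(float)))


def fit_species_psem(summary: pd.DataFrame, species: str) -> PSEMResult:
    """Species-specific pSEM on the CTU summary table.

    Paths: population ~ climate; suitability(species) ~ climate;
    zooarch(species) ~ suitability(species) + population. Climate is the
    mean maximum temperature of the warmest month; population the mean
    SPD. Predictors are z-scored before fitting; proportion responses are
    squeezed off the boundary.
    """
    df = summary.dropna(
        subset=["mean_spd", "mean_warm_t", f"suit_{species}", f"nisp_{species}"]
    ).reset_index(drop=True)
    if len(df) < 4:
        raise InsufficientDataError(f"need >= 4 complete CTU rows, got {len(df)}")
    climate = _zscore(df["mean_warm_t"].to_numpy(float))
    pop_resp = _population_response(df)
    suit = squeeze_proportions(df[f"suit_{species}"].to_numpy(float))
    nisp = squeeze_proportions(df[f"nisp_{species}"].to_numpy(float))
    paths = {}
    paths["population"] = fit_quasibinomial(
        pop_resp, pd.DataFrame({"climate": climate}), response="population"
    )
    paths["suitability"] = fit_quasibinomial(
        suit, pd.DataFrame({"climate": climate}), response="suitability"
    )
    paths["zooarch"] = fit_quasibinomial(
        nisp,
        pd.DataFrame(
            {"suitability": _zscore(df[f"suit_{species}"].to_numpy(float)), "population": _zscore(df["mean_spd"].to_numpy(float))}
        ),
        response="zooarch",
    )
    return PSEMResult(name=species, paths=paths)


def fit_reddeer_psem(summary: pd.DataFrame) -> PSEMResult:
    """Red-deer mediation pSEM.

    Paths: population ~ climate; combined zooarchaeological share of the
    two top-ranked species (reindeer + boar) ~ population; red-deer share
    ~ combined share. Tests whether red deer enters assemblages where the
    higher-ranked species' share declines, and whether that decline is
    itself driven by population.
    """
    from .ctu import zooarch_share_combined

    df = summary.dropna(subset=["mean_spd", "mean_warm_t", "nisp_reindeer", "nisp_boar", "nisp_red_deer"]).reset_index(drop=True)
    if len(df) < 4:
        raise InsufficientDataError(f"need >= 4 complete CTU rows, got {len(df)}")
    climate = _zscore(df["mean_warm_t"].to_numpy(float))
    pop_resp = _population_response(df)
    combined = zooarch_share_combined(df, ("reindeer", "boar")).to_numpy(float)
    reddeer = squeeze_proportions(df["nisp_red_deer"].to_numpy(float))
    paths = {}
    paths["population"] = fit_quasibinomial(
        pop_resp, pd.DataFrame({"climate": climate}), response="population"
    )
    paths["combined"] = fit_quasibinomial(
        squeeze_proportions(combined),
        pd.DataFrame({"population": _zscore(df["mean_spd"].to_numpy(float))}),
        response="combined",
    )
    paths["red_deer"] = fit_quasibinomial(
        reddeer, pd.DataFrame({"combined": _zscore(combined)}), response="red_deer"
    )
    return PSEMResult(name="red deer mediation", paths=paths)
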