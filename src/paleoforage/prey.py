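"""Prey-choice model with pursuit failure.

The classical prey (diet-breadth) model ranks prey types by their
post-encounter return rate (PERR), the energy gained per unit of handling
time once an animal has been encountered, and predicts that a forager
pursues a ranked prey type on encounter exactly when its PERR exceeds the
overall return rate attainable from the higher-ranked part of the diet.

This module extends PERR with the probability ``p`` that a pursuit fails:
the forager always pays the post-encounter pre-acquisition (pursuit) cost
``c``, but the energy ``e`` and the post-acquisition handling cost ``h``
are only realised with probability ``1 - p``::

    PERR = e (1 - p) / ((1 - p) h + c)        [kcal / h]

Because per-species energetic parameters are rarely observed directly for
extinct or extirpated populations, the module also fits simple allometric
regressions of each parameter on body weight from a reference fauna and
predicts the parameters for a target species list from body weight alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateModelError, InsufficientDataError, InvalidParameterError

__all__ = [
    "PERR_PARAMS",
    "PARAM_COLUMNS",
    "DEFAULT_TRANSFORMS",
    "AllometricFit",
    "AllometricFits",
    "DietBreadth",
    "perr",
    "effective_energy",
    "effective_handling",
    "fit_allometry",
    "predict_parameters",
    "rank_prey",
    "overall_return_rate",
    "diet_breadth",
]

#: the four per-species energetic parameters, keyed by their conventional symbol
PERR_PARAMS = ("e", "h", "c", "p")

#: CSV column carrying each parameter
PARAM_COLUMNS = {"e": "e_kcal", "h": "h_hr", "c": "c_hr", "p": "p_fail"}

#: default regression transform per parameter.  Energy and handling follow
#: the usual power-law allometry (log-log); pursuit cost and failure
#: probability are modelled linear in log body weight.
DEFAULT_TRANSFORMS = {"e": "log-log", "h": "log-log", "c": "linear-log", "p": "linear-log"}

_TRANSFORMS = ("linear", "log-log", "linear-log")

#: floor applied to predicted e/h/c so PERR stays finite and positive
PRED_EPS = 1e-9


def perr(e, p, h, c):
    """Post-encounter return rate under pursuit failure, in kcal/h.

    Parameters may be scalars or aligned arrays. ``e`` is the energy gained
    on a successful acquisition (kcal), ``p`` the probability the pursuit
    fails, ``h`` the post-acquisition handling time (h) and ``c`` the
    post-encounter pre-acquisition (pursuit) time (h), paid win or lose.
    """
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(e)) or np.any(~np.isfinite(p)) or np.any(~np.isfinite(h)) or np.any(~np.isfinite(c)):
        raise InvalidParameterError("perr parameters must be finite")
    if np.any(e <= 0):
        raise InvalidParameterError("energy e must be positive")
    if np.any(h <= 0):
        raise InvalidParameterError("handling time h must be positive")
    if np.any(c < 0):
        raise InvalidParameterError("pursuit cost c must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("failure probability p must lie in [0, 1]")
    denom = (1.0 - p) * h + c
    if np.any(denom <= 0):
        raise DegenerateModelError("certain failure (p=1) with zero pursuit cost leaves PERR undefined")
    out = e * (1.0 - p) / denom
    return out if out.ndim else float(out)


def effective_energy(e, p):
    """Expected energy per encounter, ``e (1 - p)``."""
    return np.asarray(e, dtype=float) * (1.0 - np.asarray(p, dtype=float))


def effective_handling(h, c, p):
    """Expected time per pursued encounter, ``(1 - p) h + c``."""
    p = np.asarray(p, dtype=float)
    return (1.0 - p) * np.asarray(h, dtype=float) + np.asarray(c, dtype=float)


@dataclass(frozen=True)
class AllometricFit:
    """One OLS regression of a PERR parameter on body weight."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    transform: str

    def predict(self, weight_kg):
        w = np.asarray(weight_kg, dtype=float)
        if self.transform == "log-log":
            return np.exp(self.intercept + self.slope * np.log(w))
        if self.transform == "linear-log":
            return self.intercept + self.slope * np.log(w)
        return self.intercept + self.slope * w


@dataclass(frozen=True)
class AllometricFits:
    """Per-parameter allometric fits plus the reference sample size."""

    fits: dict[str, AllometricFit]
    n_reference: int

    def __getitem__(self, param: str) -> AllometricFit:
        return self.fits[param]

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "fits": {k: vars(v) for k, v in self.fits.items()},
        }


def fit_allometry(reference: pd.DataFrame, transforms: dict[str, str] | None = None) -> AllometricFits:
    """Fit one OLS line per PERR parameter against body weight.

    ``reference`` must carry columns ``species, weight_kg, e_kcal, h_hr,
    c_hr, p_fail``. The regression transform per parameter defaults to
    :data:`DEFAULT_TRANSFORMS` and may be overridden per parameter.
    Reports the two-sided p-value on the slope and R-squared.
    """
    if len(reference) < 4:
        raise InsufficientDataError(f"need >= 4 reference records, got {len(reference)}")
    w = reference["weight_kg"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise InvalidParameterError("reference body weights must be positive")
    if np.allclose(w, w[0]):
        raise DegenerateModelError("all reference weights equal: slope unidentifiable")
    transforms = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    fits: dict[str, AllometricFit] = {}
    for param in PERR_PARAMS:
        tr = transforms[param]
        if tr not in _TRANSFORMS:
            raise InvalidParameterError(f"unknown transform {tr!r}")
        y = reference[PARAM_COLUMNS[param]].to_numpy(dtype=float)
        x = np.log(w) if tr in ("log-log", "linear-log") else w
        if tr == "log-log":
            if np.any(y <= 0):
                raise InvalidParameterError(f"{param}: log-log transform requires positive values")
            y = np.log(y)
        res = stats.linregress(x, y)
        fits[param] = AllometricFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            p_value=float(res.pvalue),
            r_squared=float(res.rvalue**2),
            transform=tr,
        )
    return AllometricFits(fits=fits, n_reference=len(reference))


def predict_parameters(fits: AllometricFits, species: pd.DataFrame) -> pd.DataFrame:
    """Predict PERR parameters for a target species list from body weight.

    ``species`` needs columns ``species`` and ``weight_kg``. The predicted
    failure probability is clamped into [0, 1]; predicted e/h are floored
    at a small positive epsilon and c at zero, so PERR stays defined.
    """
    w = species["weight_kg"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise InvalidParameterError("species body weights must be positive and finite")
    out = pd.DataFrame({"species": species["species"].to_numpy(), "weight_kg": w})
    for param in PERR_PARAMS:
        pred = np.asarray(fits[param].predict(w), dtype=float)
        if param == "p":
            pred = np.clip(pred, 0.0, 1.0)
        elif param == "c":
            pred = np.maximum(pred, 0.0)
        else:
            pred = np.maximum(pred, PRED_EPS)
        out[PARAM_COLUMNS[param]] = pred
    out["provenance"] = "predicted"
    return out


def rank_prey(params: pd.DataFrame) -> pd.DataFrame:
    """Rank species by PERR (descending).

    Ties break by descending body weight, then species name, so the
    ordering is deterministic. Returns a copy of ``params`` with ``perr``
    and ``rank`` (1..n) columns, sorted by rank.
    """
    if len(params) == 0:
        raise InsufficientDataError("need at least one species to rank")
    df = params.copy()
    df["perr"] = perr(
        df["e_kcal"].to_numpy(), df["p_fail"].to_numpy(), df["h_hr"].to_numpy(), df["c_hr"].to_numpy()
    )
    df = df.sort_values(
        ["perr", "weight_kg", "species"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass(frozen=True)
class DietBreadth:
    """Optimal diet: the included prefix of the ranking and its return rate."""

    included_species: tuple[str, ...]
    overall_return_rate: float
    cutoff_rank: int
    per_rank_rates: tuple[float, ...] = field(default=(), repr=False)


def overall_return_rate(diet: pd.DataFrame, encounter_rates: dict[str, float]) -> float:
    """Overall (search-inclusive) return rate of a candidate diet, kcal/h.

    Implements the diet-model rate sum(lam_i e*_i) / (1 + sum(lam_i h*_i))
    over the rows of ``diet`` (a ranked parameter table), where the
    effective values e* = e(1-p) and h* = (1-p)h + c fold pursuit failure
    into the classical two-parameter form. ``encounter_rates`` maps species
    name to encounters per search hour.
    """
    if len(diet) == 0:
        raise InsufficientDataError("diet must contain at least one species")
    try:
        lam = np.array([encounter_rates[s] for s in diet["species"]], dtype=float)
    except KeyError as exc:
        raise InvalidParameterError(f"missing encounter rate for species {exc.args[0]!r}") from None
    if np.any(lam < 0):
        raise InvalidParameterError("encounter rates must be non-negative")
    e_eff = effective_energy(diet["e_kcal"].to_numpy(), diet["p_fail"].to_numpy())
    h_eff = effective_handling(diet["h_hr"].to_numpy(), diet["c_hr"].to_numpy(), diet["p_fail"].to_numpy())
    return float(np.sum(lam * e_eff) / (1.0 + np.sum(lam * h_eff)))


def diet_breadth(ranking: pd.DataFrame, encounter_rates: dict[str, float]) -> DietBreadth:
    """Solve the diet-breadth model over a ranked parameter table.

    Species are added in rank order; species k enters the diet iff its
    PERR exceeds the overall return rate of the diet restricted to ranks
    1..k-1. The top-ranked species is always included. The resulting
    prefix also maximises the overall return rate over all rank-prefixes,
    and whether a species is included never depends on its own encounter
    rate.
    """
    if len(ranking) == 0:
        raise InsufficientDataError("empty ranking")
    ranking = ranking.sort_values("rank").reset_index(drop=True)
    rates = []
    j = 0
    for k in range(len(ranking)):
        if k == 0:
            rate_before = 0.0
        else:
            rate_before = overall_return_rate(ranking.iloc[: k], encounter_rates)
        if k == 0 or ranking["perr"].iloc[k] > rate_before:
            j = k + 1
            rates.append(overall_return_rate(ranking.iloc[: j], encounter_rates))
        else:
            break
    included = tuple(ranking["species"].iloc[:j])
    return DietBreadth(
        included_species=included,
        overall_return_rate=rates[-1],
        cutoff_rank=j,
        per_rank_rates=tuple(rates),
    )


def reproduce_prey_ranking(
    reference: pd.DataFrame,
    species_list: pd.DataFrame,
    transforms: dict[str, str] | None = None,
) -> tuple[AllometricFits, pd.DataFrame]:
    """End-to-end prey ranking from a reference fauna and a species list.

    Fits the allometries on the reference table, predicts the PERR
    parameters for every target species from body weight, and returns the
    fits plus the ranked table (columns ``rank, species, perr, weight_kg``
    first). This is the path used to rebuild the study-style ranked prey
    table when the observed reference fauna and target list are supplied.
    """
    fits = fit_allometry(reference, transforms=transforms)
    params = predict_parameters(fits, species_list)
    ranked = rank_prey(params)
    cols = ["rank", "species", "perr", "weight_kg"]
    return fits, ranked[cols + [c for c in ranked.columns if c not in cols]]
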