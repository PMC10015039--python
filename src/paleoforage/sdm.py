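"""Maximum-entropy climate-envelope species distribution model.

Fits a presence/background (pseudo-absence) maxent model on four climate
variables -- mean, low and high temperature and annual precipitation --
with the feature expansion limited to linear and quadratic terms of the
standardized variables (8 features), L1-regularized with per-feature
penalty scales in the usual maxent default shape.  The fitted envelope is
hindcast over past climate slices (one grid per century) and evaluated at
archaeological sites by their median calibrated age rounded to the
nearest century and their containing grid cell.

The model gives cell x a probability proportional to exp(w . f(x)); the
penalized log-loss over presences is convex, so the L-BFGS fit (with the
positive/negative weight split handling the L1 term exactly) finds the
global optimum.  Suitability is reported on the complementary log-log
scale, calibrated so the mean output at the training presences is 0.5;
the raw linear score is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .errors import (
    ConvergenceError,
    ExtentError,
    InsufficientDataError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CLIMATE_VARS",
    "ClimateSlice",
    "OccurrenceSet",
    "FeatureScaling",
    "EnvelopeModel",
    "SuitabilitySurface",
    "build_features",
    "fit_envelope",
    "auc",
    "select_regularization",
    "hindcast",
    "extract_at_sites",
    "round_to_century",
]

#: climate variables in fixed feature order
CLIMATE_VARS = ("tmean", "tlow", "thigh", "precip")

MIN_PRESENCES = 20


@dataclass
class ClimateSlice:
    """One century's climate grid: 4 variables on a regular lattice.

    ``x0, y0`` is the outer corner of the top-left (row 0, col 0) cell and
    ``cellsize`` its edge length, with rows increasing southwards (the
    usual north-up raster layout). ``valid`` masks land/data cells.
    """

    century: int
    variables: dict[str, np.ndarray]
    x0: float
    y0: float
    cellsize: float
    valid: np.ndarray

    def __post_init__(self):
        shp = self.valid.shape
        for v in CLIMATE_VARS:
            if v not in self.variables:
                raise InvalidParameterError(f"climate slice missing variable {v!r}")
            if self.variables[v].shape != shp:
                raise InvalidParameterError("climate variable grids must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def cell_index(self, lon, lat):
        """Row/col of the cell containing each point; no interpolation."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x0) / self.cellsize).astype(int)
        row = np.floor((self.y0 - lat) / self.cellsize).astype(int)
        return row, col

    def values_at(self, lon, lat) -> np.ndarray:
        """(n, 4) climate values at point locations; ExtentError if any
        point is off-grid or on a nodata cell."""
        row, col = self.cell_index(np.atleast_1d(lon), np.atleast_1d(lat))
        nr, nc = self.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ExtentError("point outside climate grid extent")
        if not np.all(self.valid[row, col]):
            raise ExtentError("point on a nodata cell")
        return np.stack([self.variables[v][row, col] for v in CLIMATE_VARS], axis=-1)

    def valid_cell_values(self) -> np.ndarray:
        """(n_valid, 4) climate values of all valid cells, row-major."""
        return np.stack([self.variables[v][self.valid] for v in CLIMATE_VARS], axis=-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (century,row,col,lon,lat,tmean,...) of valid cells."""
        rows, cols = np.nonzero(self.valid)
        lon = self.x0 + (cols + 0.5) * self.cellsize
        lat = self.y0 - (rows + 0.5) * self.cellsize
        data = {"century": self.century, "row": rows, "col": cols, "lon": lon, "lat": lat}
        for v in CLIMATE_VARS:
            data[v] = self.variables[v][rows, cols]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, shape, x0, y0, cellsize) -> "ClimateSlice":
        valid = np.zeros(shape, dtype=bool)
        variables = {v: np.full(shape, np.nan) for v in CLIMATE_VARS}
        r = df["row"].to_numpy(int)
        c = df["col"].to_numpy(int)
        valid[r, c] = True
        for v in CLIMATE_VARS:
            variables[v][r, c] = df[v].to_numpy(float)
        return cls(int(df["century"].iloc[0]), variables, x0, y0, cellsize, valid)


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence and background (pseudo-absence) points, lon/lat arrays (n, 2)."""

    presence: np.ndarray
    background: np.ndarray


@dataclass(frozen=True)
class FeatureScaling:
    """Per-variable mean/sd taken over the training background."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        if np.any(self.sds <= 0):
            raise InvalidParameterError("feature scaling sds must be positive")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FeatureScaling":
        return cls(means=values.mean(axis=0), sds=values.std(axis=0))


def build_features(values, scaling: FeatureScaling) -> np.ndarray:
    """Linear + quadratic feature vector(s) from raw climate values.

    Standardizes the four variables with the training-background scaling,
    then appends their squares: order (tmean, tlow, thigh, precip,
    tmean^2, tlow^2, thigh^2, precip^2).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("climate values must be finite")
    z = (values - scaling.means) / scaling.sds
    return np.concatenate([z, z**2], axis=-1)


@dataclass
class EnvelopeModel:
    """Fitted maxent envelope: weights, scaling, normalizer, output link."""

    weights: np.ndarray
    scaling: FeatureScaling
    reg_multiplier: float
    log_normalizer: float
    cloglog_offset: float
    output: str = "cloglog"
    converged: bool = True
    penalty_scales: np.ndarray | None = None
    train_info: dict = field(default_factory=dict)

    def penalty_weighted_norm(self) -> float:
        """sum_f lam_f |w_f| -- the quantity the regularization
        multiplier directly controls (non-increasing in the multiplier
        at the exact optimum)."""
        return float(self.penalty_scales @ np.abs(self.weights))

    def raw_score(self, values) -> np.ndarray:
        return build_features(values, self.scaling) @ self.weights

    def suitability(self, values, output: str | None = None) -> np.ndarray:
        eta = self.raw_score(values)
        if (output or self.output) == "raw":
            return eta
        return 1.0 - np.exp(-np.exp(eta + self.cloglog_offset))

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.scaling.means.tolist(),
            "sds": self.scaling.sds.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "log_normalizer": self.log_normalizer,
            "cloglog_offset": self.cloglog_offset,
            "output": self.output,
        }


def _penalized_objective(F_pres, F_bg, reg, lam):
    n = len(F_pres)
    m = len(F_bg)

    def fun(uv):
        # w = u - v with u, v >= 0; the penalty is written reg * lam.(u+v),
        # which equals reg * lam.|w| at any optimum (u and v are never
        # both active) and keeps the objective smooth in (u, v)
        w = uv[:8] - uv[8:]
        eta_bg = F_bg @ w
        log_z = logsumexp(eta_bg) - np.log(m)
        nll = -(F_pres @ w).mean() + log_z
        grad_w = -F_pres.mean(axis=0) + (
            np.exp(eta_bg - logsumexp(eta_bg)) @ F_bg
        )
        pen = reg * float(lam @ (uv[:8] + uv[8:]))
        g = np.concatenate([grad_w + reg * lam, -grad_w + reg * lam])
        return nll + pen, g

    return fun


def fit_envelope(
    occ: OccurrenceSet,
    climate: ClimateSlice,
    reg_multiplier: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-13,
) -> EnvelopeModel:
    """Fit the L1-penalized maxent envelope on one climate slice.

    Minimizes  -(1/n) sum_presence w.f(x) + log Z_bg
               + reg_multiplier * sum_f lam_f |w_f|
    where Z_bg is the mean of exp(w.f) over the background and the
    per-feature penalty scale is lam_f = sd_presence(f) / sqrt(n_presence)
    (the maxent default-regularization shape). Deterministic given its
    inputs; the objective is convex so the optimum is global.
    """
    if reg_multiplier <= 0:
        raise InvalidParameterError("reg_multiplier must be positive")
    # exact-duplicate presence records carry no extra information (the
    # usual maxent convention); dropping them keeps the fit invariant to
    # duplication of the presence file
    presence = np.unique(np.asarray(occ.presence, dtype=float), axis=0)
    if len(presence) < MIN_PRESENCES:
        raise InsufficientDataError(
            f"need >= {MIN_PRESENCES} distinct presences, got {len(presence)}"
        )
    bg_values = climate.values_at(occ.background[:, 0], occ.background[:, 1])
    pres_values = climate.values_at(presence[:, 0], presence[:, 1])
    scaling = FeatureScaling.from_values(bg_values)
    F_bg = build_features(bg_values, scaling)
    F_pres = build_features(pres_values, scaling)
    lam = F_pres.std(axis=0) / np.sqrt(len(F_pres))
    lam = np.maximum(lam, 1e-6)
    fun = _penalized_objective(F_pres, F_bg, reg_multiplier, lam)
    x0 = np.zeros(16)
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * 16,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and res.status != 2:  # status 2: ftol reached early
        raise ConvergenceError(f"maxent fit did not converge: {res.message}")
    w = res.x[:8] - res.x[8:]
    eta_bg = F_bg @ w
    log_z = float(logsumexp(eta_bg) - np.log(len(F_bg)))
    eta_pres = F_pres @ w

    # calibrate the cloglog offset so the mean presence suitability is 0.5
    def mean_out(const):
        return float(np.mean(1.0 - np.exp(-np.exp(eta_pres + const)))) - 0.5

    lo, hi = -40.0, 40.0
    offset = optimize.brentq(mean_out, lo, hi)
    return EnvelopeModel(
        weights=w,
        scaling=scaling,
        reg_multiplier=float(reg_multiplier),
        log_normalizer=log_z,
        cloglog_offset=float(offset),
        converged=bool(res.success or res.status == 2),
        penalty_scales=lam,
        train_info={"n_presence": len(F_pres), "n_background": len(F_bg), "nll": float(res.fun)},
    )


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(random presence outscores random background),
    ties counted half."""
    a = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("auc needs non-empty score lists")
    ranks = rankdata(np.concatenate([a, b]))
    return float((ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2) / (len(a) * len(b)))


def select_regularization(
    occ: OccurrenceSet,
    climate: ClimateSlice,
    multipliers,
    k: int = 4,
    seed: int = 0,
) -> dict:
    """Choose the regularization multiplier by k-fold cross-validated AUC.

    Presences are partitioned into k seeded random folds; each candidate
    multiplier is refit on k-1 folds and scored by AUC of the held-out
    presences against the full background. The winner maximizes mean AUC,
    ties going to the larger multiplier (stronger shrinkage).

    Returns {"chosen", "table"} where table has one row per multiplier
    with mean_auc and var_auc.
    """
    multipliers = sorted(float(m) for m in multipliers)
    if any(m <= 0 for m in multipliers):
        raise InvalidParameterError("multipliers must be positive")
    n = len(occ.presence)
    if k > n:
        raise InsufficientDataError(f"k={k} folds exceed {n} presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    bg_values = climate.values_at(occ.background[:, 0], occ.background[:, 1])
    rows = []
    for m in multipliers:
        aucs = []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            train = OccurrenceSet(occ.presence[mask], occ.background)
            model = fit_envelope(train, climate, reg_multiplier=m)
            held = climate.values_at(occ.presence[fold, 0], occ.presence[fold, 1])
            aucs.append(auc(model.raw_score(held), build_features(bg_values, model.scaling) @ model.weights))
        rows.append({"multiplier": m, "mean_auc": float(np.mean(aucs)), "var_auc": float(np.var(aucs, ddof=1))})
    table = pd.DataFrame(rows)
    best = table["mean_auc"].max()
    chosen = table.loc[np.isclose(table["mean_auc"], best), "multiplier"].max()
    return {"chosen": float(chosen), "table": table}


@dataclass
class SuitabilitySurface:
    """Per-cell suitability for one century, aligned to its climate slice."""

    century: int
    values: np.ndarray
    valid: np.ndarray
    x0: float
    y0: float
    cellsize: float

    def value_at(self, lon, lat):
        col = np.floor((np.asarray(lon, float) - self.x0) / self.cellsize).astype(int)
        row = np.floor((self.y0 - np.asarray(lat, float)) / self.cellsize).astype(int)
        nr, nc = self.valid.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ExtentError("point outside surface extent")
        if not np.all(self.valid[row, col]):
            raise ExtentError("point on a nodata cell")
        return self.values[row, col]


def hindcast(model: EnvelopeModel, climate: ClimateSlice, output: str | None = None) -> SuitabilitySurface:
    """Project the fitted envelope over one climate slice.

    Applies the model's own training scaling to the slice's variables
    (geometry and variables must be complete), producing suitability in
    [0, 1] on the cloglog scale (or the raw linear score). Nodata cells
    are propagated as NaN.
    """
    vals = climate.valid_cell_values()
    suit = model.suitability(vals, output=output)
    grid = np.full(climate.shape, np.nan)
    grid[climate.valid] = suit
    return SuitabilitySurface(
        century=climate.century,
        values=grid,
        valid=climate.valid,
        x0=climate.x0,
        y0=climate.y0,
        cellsize=climate.cellsize,
    )


def round_to_century(age) -> np.ndarray:
    """Round ages BP to the nearest century, halves away from zero
    (12,350 -> 12,400)."""
    age = np.asarray(age, dtype=float)
    return (np.floor(age / 100.0 + 0.5) * 100).astype(int)


def extract_at_sites(surfaces: dict[int, SuitabilitySurface], sites: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Suitability at each site's (century, cell).

    ``sites`` needs columns ``site_id, lon, lat, age_bp``. Each site is
    assigned the century of its median calibrated age (half-up rounding)
    and the value of its containing cell. Sites whose century has no
    surface, that fall off-grid, or that sit on nodata cells are skipped;
    the second return value counts the skips by reason.
    """
    records = []
    skipped = {"out_of_range_century": 0, "out_of_extent": 0}
    for row in sites.itertuples(index=False):
        century = int(round_to_century(row.age_bp))
        surf = surfaces.get(century)
        if surf is None:
            skipped["out_of_range_century"] += 1
            continue
        try:
            val = float(surf.value_at(row.lon, row.lat))
        except ExtentError:
            skipped["out_of_extent"] += 1
            continue
        records.append({"site_id": row.site_id, "century": century, "suitability": val})
    if any(skipped.values()):
        logger.info("extract_at_sites skipped sites: %s", skipped)
    return pd.DataFrame(records, columns=["site_id", "century", "suitability"]), skipped
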