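"""Synthetic worlds with known ground truth for every pipeline input.

Each generator is a pure function of (configuration, seed): reference
fauna tables with known allometric slopes, coherent four-variable climate
cubes on century time slices, occurrence points drawn from a known
linear-quadratic suitability, dated archaeological sites whose counts
follow a known occupation-intensity function (with a toy monotone
calibration curve), and zooarchaeological assemblages whose expected
composition follows prey rank, habitat suitability and an optional
human-pressure term.  The accompanying truth records let every stage of
the pipeline be scored for parameter recovery without external data.

The assemblage share model (softmax over species of a*log PERR +
b*logit(suitability) - g*population*rank_penalty, Dirichlet-multinomial
sampling) is a synthetic-only stand-in for real foraging noise; it is
never used by the inference code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit, softmax

from .sdm import ClimateSlice, FeatureScaling, OccurrenceSet, build_features
from .spd import CalCurve

__all__ = [
    "WorldConfig",
    "DEFAULT_CTU_WINDOWS",
    "gen_reference_fauna",
    "gen_climate_cube",
    "gen_occurrences",
    "toy_cal_curve",
    "gen_sites_dates",
    "gen_assemblages",
    "gen_pseudo_ctu_table",
]

#: raw technocomplex labels emitted per CTU by the assemblage generator;
#: the trailing entries are deliberately unmappable so the
#: reclassification filter has real work to do
CTU_LABEL_VARIANTS = {
    "Magdalenian": ["Magdalenian", "Late Magdalenian", "Hamburgian", "Cresswellian"],
    "Epigravettian": ["Epigravettian", "Late Epigravettian", "Romanellian"],
    "ABC": ["Azilian", "Federmesser", "ABC"],
    "TPC": ["Ahrensburgian", "Bromme", "Swiderian"],
    "Mesolithic": ["Mesolithic", "Maglemose", "Sauveterrian"],
    "BBT": ["Belloisian", "Laborian"],
}
UNMAPPABLE_LABELS = ("Unknown", "Gravettian", "Solutrean")

#: synthetic CTU time windows (cal BP, old -> young), tiling 22.0-9.0 kya
DEFAULT_CTU_WINDOWS = {
    "Magdalenian": (22000, 15500),
    "Epigravettian": (15500, 14000),
    "ABC": (14000, 12800),
    "TPC": (12800, 11500),
    "Mesolithic": (11500, 9000),
}


@dataclass
class WorldConfig:
    """Shape and climate-field parameters of a synthetic world."""

    n_rows: int = 60
    n_cols: int = 80
    century_old: int = 22000
    century_young: int = 9000
    century_step: int = 100
    x0: float = 0.0
    y0: float = 60.0
    cellsize: float = 0.5
    # climate field construction
    lat_gradient: float = 8.0  # degC drop from south edge to north edge
    noise_scale: float = 2.0  # sd of the smooth spatial noise, degC
    noise_smooth: float = 4.0  # gaussian smoothing radius, cells
    warming_trend: float = 0.05  # degC of domain-mean warming per century slice
    t_base: float = 4.0  # domain-mean of mean temperature at the oldest slice
    diurnal_span: float = 9.0  # mean half-distance between high and low T
    precip_base: float = 600.0  # mm, domain mean
    seed: int = 0

    @property
    def centuries(self) -> np.ndarray:
        return np.arange(self.century_old, self.century_young - 1, -self.century_step)


def gen_reference_fauna(
    n: int = 30,
    slopes: dict[str, float] | None = None,
    noise_sds: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Reference fauna table with known allometric structure.

    Body weights are log-uniform over [5, 5000] kg. Energy and handling
    are log-linear in weight (lognormal noise); pursuit cost and failure
    probability are linear in log weight (Gaussian noise, p clipped to
    [0.02, 0.95]). Defaults give ~1300 kcal of edible energy per kg of
    body weight, full post-acquisition processing near 35 h for a 100 kg
    animal scaling almost isometrically (so return rates sit in the
    few-thousand kcal/h range and depend only weakly on size), sub-hour
    pursuit times, and failure probabilities rising with size.
    """
    if n < 10:
        raise ValueError("need n >= 10 reference species")
    slopes = {**{"e": 0.95, "h": 0.90, "c": 0.08, "p": 0.05}, **(slopes or {})}
    intercepts = {
        "e": np.log(130000.0) - slopes["e"] * np.log(100.0),
        "h": np.log(35.0) - slopes["h"] * np.log(100.0),
        "c": 0.15 - slopes["c"] * np.log(30.0),
        "p": 0.10 - slopes["p"] * np.log(30.0),
    }
    noise_sds = {**{"e": 0.25, "h": 0.25, "c": 0.12, "p": 0.08}, **(noise_sds or {})}
    rng = np.random.default_rng(seed)
    w = np.exp(rng.uniform(np.log(5.0), np.log(5000.0), size=n))
    lw = np.log(w)
    e = np.exp(intercepts["e"] + slopes["e"] * lw + rng.normal(0, noise_sds["e"], n))
    h = np.exp(intercepts["h"] + slopes["h"] * lw + rng.normal(0, noise_sds["h"], n))
    c = np.maximum(intercepts["c"] + slopes["c"] * lw + rng.normal(0, noise_sds["c"], n), 0.01)
    p = np.clip(intercepts["p"] + slopes["p"] * lw + rng.normal(0, noise_sds["p"], n), 0.02, 0.95)
    df = pd.DataFrame(
        {
            "species": [f"ref_sp_{i:02d}" for i in range(n)],
            "weight_kg": w,
            "e_kcal": e,
            "h_hr": h,
            "c_hr": c,
            "p_fail": p,
        }
    )
    truth = {"slopes": slopes, "intercepts": intercepts, "noise_sds": noise_sds, "seed": seed}
    return df, truth


def _smooth_field(rng, shape, sd, smooth):
    f = rng.normal(0.0, 1.0, size=shape)
    f = gaussian_filter(f, smooth, mode="reflect")
    s = f.std()
    return f / s * sd if s > 0 else f


def gen_climate_cube(cfg: WorldConfig) -> dict[int, ClimateSlice]:
    """Century-sliced climate cube with coherent spatial/temporal structure.

    Mean temperature = latitudinal gradient + seeded smooth spatial noise
    + linear warming over slices; low/high temperature bracket it with
    strictly positive offsets; precipitation is positive with its own
    smooth field. The spatial pattern is fixed across centuries so the
    only temporal signal is the warming trend.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    lat_idx = np.linspace(1.0, 0.0, cfg.n_rows)[:, None]  # row 0 = north
    base = cfg.t_base - cfg.lat_gradient * (1.0 - lat_idx) + _smooth_field(rng, shape, cfg.noise_scale, cfg.noise_smooth)
    span_hi = cfg.diurnal_span + _smooth_field(rng, shape, 1.0, cfg.noise_smooth).clip(-cfg.diurnal_span * 0.8, None)
    span_lo = cfg.diurnal_span + _smooth_field(rng, shape, 1.0, cfg.noise_smooth).clip(-cfg.diurnal_span * 0.8, None)
    lprec = np.log(cfg.precip_base) + 0.4 * _smooth_field(rng, shape, 1.0, cfg.noise_smooth) + 0.3 * (1.0 - lat_idx)
    valid = np.ones(shape, dtype=bool)
    cube: dict[int, ClimateSlice] = {}
    centuries = cfg.centuries
    for i, cent in enumerate(centuries):
        tmean = base + cfg.warming_trend * i
        cube[int(cent)] = ClimateSlice(
            century=int(cent),
            variables={
                "tmean": tmean,
                "tlow": tmean - span_lo,
                "thigh": tmean + span_hi,
                "precip": np.exp(lprec),
            },
            x0=cfg.x0,
            y0=cfg.y0,
            cellsize=cfg.cellsize,
            valid=valid,
        )
    return cube


def gen_occurrences(
    climate: ClimateSlice,
    true_weights: np.ndarray,
    n_presence: int = 2000,
    n_background: int = 10000,
    seed: int = 0,
) -> tuple[OccurrenceSet, dict]:
    """Presence/background points from a known linear-quadratic surface.

    Cell selection probability is proportional to exp(w . f(x)) with
    features standardized over all valid cells; points are jittered
    uniformly within their cell. Background is uniform over valid cells.
    The returned truth carries the weights, the scaling and the per-cell
    true suitability (softmax scale).
    """
    if n_presence < 100:
        raise ValueError("need n_presence >= 100")
    rng = np.random.default_rng(seed)
    true_weights = np.asarray(true_weights, dtype=float)
    vals = climate.valid_cell_values()
    scaling = FeatureScaling.from_values(vals)
    F = build_features(vals, scaling)
    prob = softmax(F @ true_weights)
    rows, cols = np.nonzero(climate.valid)
    n_cells = len(rows)

    def draw(n, p=None):
        idx = rng.choice(n_cells, size=n, replace=True, p=p)
        lon = climate.x0 + (cols[idx] + rng.uniform(0.05, 0.95, n)) * climate.cellsize
        lat = climate.y0 - (rows[idx] + rng.uniform(0.05, 0.95, n)) * climate.cellsize
        return np.column_stack([lon, lat])

    occ = OccurrenceSet(presence=draw(n_presence, prob), background=draw(n_background))
    truth = {
        "weights": true_weights,
        "scaling": scaling,
        "cell_prob": prob,
        "cell_score": F @ true_weights,
        "seed": seed,
    }
    return occ, truth


def toy_cal_curve(
    old: float = 26000.0,
    young: float = 5000.0,
    amplitude: float = 150.0,
    period: float = 5000.0,
    sigma: float = 30.0,
) -> CalCurve:
    """Monotone toy calibration curve: mu(theta) = theta + slow sinusoid.

    The sinusoid's slope perturbation stays below 1 in magnitude, so the
    curve is strictly monotone and every radiocarbon age maps back to a
    unique calendar age. Knots every 10 years; constant 1-sigma error.
    """
    theta = np.arange(young, old + 1.0, 10.0)
    mu = theta + amplitude * np.sin(2.0 * np.pi * theta / period)
    return CalCurve(cal_bp=theta, c14_bp=mu, sigma=np.full_like(theta, sigma))


def gen_sites_dates(
    cfg: WorldConfig,
    intensity: dict[str, float] | None = None,
    windows: dict[str, tuple[int, int]] | None = None,
    n_sites_total: int = 300,
    date_error: tuple[float, float] = (40.0, 80.0),
    curve: CalCurve | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CalCurve, dict]:
    """Dated site records whose counts follow a known occupation intensity.

    ``intensity`` gives relative per-century site-founding rates per CTU
    window; site true ages are uniform within their window, locations
    uniform over the grid, and each site receives 1-4 radiocarbon
    determinations back-transformed through the calibration curve with
    Gaussian measurement error. Returns (sites, dates, curve, truth).
    """
    rng = np.random.default_rng(seed)
    windows = windows or DEFAULT_CTU_WINDOWS
    intensity = intensity or {k: 1.0 for k in windows}
    curve = curve if curve is not None else toy_cal_curve()
    # expected sites per window proportional to intensity * window span
    spans = {k: (w[0] - w[1]) for k, w in windows.items()}
    weight = np.array([intensity[k] * spans[k] for k in windows], dtype=float)
    weight /= weight.sum()
    counts = rng.multinomial(n_sites_total, weight)
    site_rows, date_rows = [], []
    true_ages = {}
    sid = 0
    for (ctu, (old, young)), m in zip(windows.items(), counts):
        for _ in range(m):
            age = rng.uniform(young, old)
            site_id = f"site_{sid:04d}"
            lon = cfg.x0 + rng.uniform(0.02, 0.98) * cfg.n_cols * cfg.cellsize
            lat = cfg.y0 - rng.uniform(0.02, 0.98) * cfg.n_rows * cfg.cellsize
            site_rows.append(
                {"site_id": site_id, "lon": lon, "lat": lat, "age_bp": age, "ctu": ctu}
            )
            true_ages[site_id] = age
            for d in range(rng.integers(1, 5)):
                err = rng.uniform(*date_error)
                c14 = float(np.interp(age, curve.cal_bp, curve.c14_bp)) + rng.normal(0.0, err)
                date_rows.append(
                    {
                        "site_id": site_id,
                        "lab_id": f"LAB-{sid:04d}-{d}",
                        "c14_age": c14,
                        "error": err,
                    }
                )
            sid += 1
    sites = pd.DataFrame(site_rows)
    dates = pd.DataFrame(date_rows)
    truth = {"intensity": dict(intensity), "windows": dict(windows), "true_ages": true_ages, "seed": seed}
    return sites, dates, curve, truth


def gen_assemblages(
    suitabilities: pd.DataFrame,
    perr_by_species: dict[str, float],
    population_by_ctu: dict[str, float],
    a_rank: float = 1.0,
    b_suit: float = 1.0,
    g_pop: float = 0.0,
    n_per_ctu: int = 20,
    nisp_total: int = 200,
    concentration: float = 50.0,
    frac_unmappable: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Zooarchaeological assemblages with a tunable human-pressure effect.

    ``suitabilities`` has one row per CTU with ``suit_<species>``
    columns. Expected species shares per assemblage are a softmax over
    species of  a*log(PERR) + b*logit(suitability)
    - g*population*rank_penalty, where the rank penalty is the species'
    PERR rank (1 = best) normalized to [0, 1]: under human pressure
    (g > 0) high-ranked species are depressed most, while g = 0 encodes
    the no-depression null. Realized NISP counts are
    Dirichlet-multinomial around the expected shares. Raw technocomplex
    labels are drawn from the CTU's vocabulary variants, with a fraction
    ``frac_unmappable`` given labels outside the CTU vocabulary, so the
    reclassification step has real work to do.
    """
    rng = np.random.default_rng(seed)
    species = [c[5:] for c in suitabilities.columns if c.startswith("suit_")]
    perr_vals = np.array([perr_by_species[s] for s in species], dtype=float)
    order = np.argsort(-perr_vals)
    rank = np.empty(len(species))
    rank[order] = np.arange(1, len(species) + 1)
    rank_penalty = 1.0 - (rank - 1) / max(len(species) - 1, 1)  # 1 for top rank
    rows = []
    truth_shares = {}
    for r in suitabilities.itertuples(index=False):
        ctu = r.ctu
        suit = np.array([np.clip(getattr(r, f"suit_{s}"), 1e-6, 1 - 1e-6) for s in species])
        pop = population_by_ctu[ctu]
        logits = a_rank * np.log(perr_vals) + b_suit * logit(suit) - g_pop * pop * rank_penalty
        shares = softmax(logits)
        truth_shares[ctu] = dict(zip(species, shares))
        variants = CTU_LABEL_VARIANTS.get(ctu, [ctu])
        for i in range(n_per_ctu):
            alpha = np.maximum(shares * concentration, 1e-6)
            pvec = rng.dirichlet(alpha)
            nisp = rng.multinomial(nisp_total, pvec)
            props = nisp / nisp_total
            if rng.uniform() < frac_unmappable:
                label = UNMAPPABLE_LABELS[rng.integers(len(UNMAPPABLE_LABELS))]
            else:
                label = variants[rng.integers(len(variants))]
            rows.append(
                {
                    "assemblage_id": f"{ctu[:4].lower()}_{i:03d}",
                    "technocomplex": label,
                    **{f"nisp_{s}": props[j] for j, s in enumerate(species)},
                }
            )
    records = pd.DataFrame(rows)
    truth = {
        "a_rank": a_rank,
        "b_suit": b_suit,
        "g_pop": g_pop,
        "shares": truth_shares,
        "rank_penalty": dict(zip(species, rank_penalty)),
        "seed": seed,
    }
    return records, truth


def gen_pseudo_ctu_table(
    n_units: int = 200,
    b_suit: float = 0.0,
    g_pop: float = 0.0,
    b_clim_pop: float = 0.8,
    b_clim_suit: float = 0.8,
    concentration: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """CTU-summary-like table of n pseudo-units with known path structure.

    Generating process (one focal species):

    - climate  ~ N(0, 1)
    - population = expit(b_clim_pop * climate + noise)     (SPD analogue)
    - suitability = expit(b_clim_suit * climate + noise)
    - zooarch share ~ Beta around expit(b0 + b_suit * z(logit suit)
      + g_pop * z(pop)) with the stated concentration, i.e. binomial-type
      variance inflated by a constant factor -- exactly the quasibinomial
      regime the path models assume.

    With g_pop = 0 the population path is null by construction, so the
    fitted population-path standardized beta should center on zero; with
    b_suit > 0 the suitability path is real. Used for calibration/power
    experiments on the path models. Also fills nisp columns for reindeer
    and boar (sharing the suitability signal) so the mediation model can
    run on the same worlds.
    """
    rng = np.random.default_rng(seed)
    climate = rng.normal(0.0, 1.0, n_units)
    pop = expit(b_clim_pop * climate + rng.normal(0.0, 0.7, n_units))
    suit = expit(b_clim_suit * climate + rng.normal(0.0, 0.7, n_units))

    def beta_around(mean):
        a = np.maximum(mean * concentration, 1e-3)
        b = np.maximum((1.0 - mean) * concentration, 1e-3)
        return rng.beta(a, b)

    z_suit = (logit(suit) - logit(suit).mean()) / logit(suit).std()
    z_pop = (pop - pop.mean()) / pop.std()
    mean_nisp = expit(-0.5 + b_suit * z_suit + g_pop * z_pop)
    nisp = beta_around(mean_nisp)
    # companion species for the mediation structure
    nisp_boar = beta_around(expit(-1.2 + 0.5 * b_suit * z_suit + g_pop * z_pop))
    df = pd.DataFrame(
        {
            "ctu": [f"unit_{i:03d}" for i in range(n_units)],
            "suit_focal": suit,
            "nisp_focal": nisp,
            "suit_reindeer": suit,
            "nisp_reindeer": nisp,
            "suit_boar": np.clip(suit * 0.8 + 0.05, 1e-4, 1 - 1e-4),
            "nisp_boar": nisp_boar,
            "nisp_red_deer": beta_around(expit(0.2 - 0.8 * ((nisp + nisp_boar) - (nisp + nisp_boar).mean()) / (nisp + nisp_boar).std())),
            "mean_spd": pop,
            "mean_warm_t": climate * 3.0 + 15.0,
        }
    )
    truth = {
        "b_suit": b_suit,
        "g_pop": g_pop,
        "b_clim_pop": b_clim_pop,
        "b_clim_suit": b_clim_suit,
        "seed": seed,
    }
    return df, truth
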