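"""End-to-end orchestration over synthetic or user-supplied inputs.

``run_all`` executes the full analysis in the study's order -- prey
ranking, per-species climate-envelope fitting and hindcasting,
radiocarbon SPD, CTU aggregation, path models -- writing every stage's
output as CSV/JSON into the configured directory together with a
manifest of seeds, stage row counts and filter reports.  Each stage is a
plain function over serialized inputs, so any stage can be rerun
standalone and ``run_all`` is their composition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ctu as ctu_mod
from . import prey, psem, sdm, spd, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-world pipeline run."""

    out_dir: Path = Path("results/pipeline")
    seed: int = 0
    species: tuple[str, ...] = ctu_mod.FOCAL_SPECIES
    # world scale (kept modest: the scientific structure, not the area,
    # is what downstream stages consume)
    n_rows: int = 40
    n_cols: int = 50
    n_sites: int = 250
    n_presence: int = 800
    n_background: int = 4000
    n_assemblages_per_ctu: int = 20
    # SDM settings
    multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    folds: int = 4
    output_transform: str = "cloglog"
    # SPD settings
    window: tuple[float, float] = spd.STUDY_WINDOW
    bin_width: float = 200.0
    smooth_width: float = 200.0
    # aggregation / path models
    stat: str = "mean"
    # injected CTU summary table: when set, upstream stages are skipped
    summary_table: Path | None = None

    # ground-truth effect sizes of the generated world
    b_suit: float = 1.0
    g_pop: float = 0.0


def _true_sdm_weights(rng) -> np.ndarray:
    w = np.zeros(8)
    w[0] = rng.uniform(1.0, 2.5)  # mean temperature preference...
    w[4] = -rng.uniform(0.5, 1.5)  # ...with an interior optimum
    w[3] = rng.uniform(-0.8, 0.8)
    return w


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the result bundle (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    bundle: dict = {}
    try:
        if config.summary_table is not None:
            summary = pd.read_csv(config.summary_table)
            manifest["stages"]["aggregate"] = {"injected": str(config.summary_table), "n_ctu": len(summary)}
        else:
            summary = _run_upstream(config, out, manifest, bundle)
        bundle["summary"] = summary
        summary.to_csv(out / "ctu_summary.csv", index=False)

        # ---- path models -----------------------------------------------
        path_tables = []
        psem_results = {}
        for sp in ("reindeer", "boar", "red_deer"):
            if f"nisp_{sp}" not in summary.columns or f"suit_{sp}" not in summary.columns:
                continue
            res = psem.fit_species_psem(summary, sp)
            psem_results[sp] = res
            t = res.table()
            t.insert(0, "model", sp)
            path_tables.append(t)
        red = psem.fit_reddeer_psem(summary)
        psem_results["red_deer_mediation"] = red
        t = red.table()
        t.insert(0, "model", "red_deer_mediation")
        path_tables.append(t)
        coef_table = pd.concat(path_tables, ignore_index=True)
        coef_table.to_csv(out / "path_coefficients.csv", index=False)
        bundle["psem"] = psem_results
        bundle["coef_table"] = coef_table
        manifest["stages"]["psem"] = {"n_paths": len(coef_table)}
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _run_upstream(config: PipelineConfig, out: Path, manifest: dict, bundle: dict) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)

    # ---- prey ranking on a synthetic reference fauna --------------------
    reference, ref_truth = synth.gen_reference_fauna(n=30, seed=config.seed)
    target = pd.DataFrame(
        {
            "species": list(config.species),
            "weight_kg": [86.0, 117.0, 187.0, 385.0, 500.0][: len(config.species)],
        }
    )
    fits, ranked = prey.reproduce_prey_ranking(reference, target)
    ranked.to_csv(out / "prey_ranking.csv", index=False)
    (out / "allometric_fits.json").write_text(json.dumps(fits.to_dict(), indent=2))
    manifest["stages"]["rank"] = {"n_reference": len(reference), "n_ranked": len(ranked)}
    bundle["ranking"] = ranked
    bundle["allometric_fits"] = fits

    # ---- climate cube + per-species envelopes ---------------------------
    wcfg = synth.WorldConfig(
        n_rows=config.n_rows, n_cols=config.n_cols, seed=config.seed
    )
    cube = synth.gen_climate_cube(wcfg)
    modern = cube[wcfg.century_old]
    surfaces: dict[str, dict[int, sdm.SuitabilitySurface]] = {}
    sdm_report = {}
    for i, sp in enumerate(config.species):
        true_w = _true_sdm_weights(rng)
        occ, occ_truth = synth.gen_occurrences(
            modern,
            true_w,
            n_presence=config.n_presence,
            n_background=config.n_background,
            seed=config.seed + 101 + i,
        )
        sel = sdm.select_regularization(
            occ, modern, config.multipliers, k=config.folds, seed=config.seed + 11 + i
        )
        model = sdm.fit_envelope(occ, modern, reg_multiplier=sel["chosen"])
        surfaces[sp] = {c: sdm.hindcast(model, sl) for c, sl in cube.items()}
        sdm_report[sp] = {
            "chosen_multiplier": sel["chosen"],
            "cv": sel["table"].to_dict(orient="records"),
            "weights": model.weights.tolist(),
        }
    (out / "sdm_models.json").write_text(json.dumps(sdm_report, indent=2))
    manifest["stages"]["sdm"] = {sp: r["chosen_multiplier"] for sp, r in sdm_report.items()}

    # ---- sites, dates, SPD ----------------------------------------------
    sites, dates, curve, site_truth = synth.gen_sites_dates(
        wcfg, n_sites_total=config.n_sites, seed=config.seed + 7
    )
    kept_dates = spd.truncate_dates_by_median(dates, curve, config.window)
    # the site database carries one record per date; same-site dates in
    # the same century are duplicates of one occupation and collapse
    site_dates = kept_dates.merge(sites[["site_id", "lon", "lat", "ctu"]], on="site_id")
    site_dates = site_dates.rename(columns={"median_cal_bp": "age_bp"})
    sites_deduped, dedupe_report = ctu_mod.dedupe_sites(site_dates)
    bins = spd.bin_dates(kept_dates, bin_width=config.bin_width)
    curve_spd = spd.smooth(spd.spd(bins, curve, config.window), config.smooth_width)
    curve_spd.to_frame().to_csv(out / "spd.csv", index=False)
    manifest["stages"]["spd"] = {
        "n_dates": len(dates),
        "n_dates_in_window": len(kept_dates),
        "n_bins": len(bins),
        "dedupe": dedupe_report,
    }

    # ---- extraction at sites --------------------------------------------
    suit_rows = []
    for sp in config.species:
        extracted, skipped = sdm.extract_at_sites(surfaces[sp], sites_deduped)
        extracted = extracted.merge(sites_deduped[["site_id", "ctu"]], on="site_id")
        extracted["species"] = sp
        suit_rows.append(extracted)
    site_suit = pd.concat(suit_rows, ignore_index=True)
    site_spd = sites_deduped[["site_id", "ctu"]].copy()
    ages_clamped = np.clip(
        sites_deduped["age_bp"].to_numpy(), curve_spd.ages[0], curve_spd.ages[-1]
    )
    site_spd["spd"] = spd.spd_at(curve_spd, ages_clamped)
    site_climate = sites_deduped[["site_id", "ctu"]].copy()
    warm = []
    for row in sites_deduped.itertuples(index=False):
        cent = int(sdm.round_to_century(row.age_bp))
        sl = cube.get(cent, cube[min(cube, key=lambda c: abs(c - cent))])
        warm.append(float(sl.values_at(row.lon, row.lat)[0, 2]))
    site_climate["warm_t"] = warm

    # ---- faunal assemblages + reclassification --------------------------
    suit_by_ctu = (
        site_suit.groupby(["ctu", "species"])["suitability"].mean().unstack()
    )
    suit_table = pd.DataFrame({"ctu": suit_by_ctu.index})
    for sp in config.species:
        suit_table[f"suit_{sp}"] = suit_by_ctu[sp].to_numpy()
    perr_by_species = dict(zip(ranked["species"], ranked["perr"]))
    pop_by_ctu = site_spd.groupby("ctu")["spd"].mean()
    pop_scaled = ((pop_by_ctu - pop_by_ctu.min()) / (pop_by_ctu.max() - pop_by_ctu.min())).to_dict()
    faunal_raw, faunal_truth = synth.gen_assemblages(
        suit_table,
        perr_by_species,
        pop_scaled,
        b_suit=config.b_suit,
        g_pop=config.g_pop,
        n_per_ctu=config.n_assemblages_per_ctu,
        seed=config.seed + 23,
    )
    mapping = ctu_mod.load_default_ctu_mapping()
    faunal, reclass_report = ctu_mod.reclassify_fauna(faunal_raw, mapping)
    manifest["stages"]["fauna"] = reclass_report

    summary = ctu_mod.summarize_ctu(
        site_suit, faunal, site_spd, site_climate, species=config.species, stat=config.stat
    )
    manifest["stages"]["aggregate"] = {"n_ctu": len(summary)}
    bundle["truth"] = {"fauna": faunal_truth, "sites": site_truth, "reference": ref_truth}
    return summary


def validate_inputs(config: PipelineConfig, tables: dict[str, pd.DataFrame] | None = None) -> list[dict]:
    """Schema and range checks; returns a machine-readable issue list.

    ``tables`` maps dataset name to its loaded DataFrame (reference
    fauna, sites, dates, faunal records, summary). Unknown datasets are
    reported, never fatal.
    """
    required = {
        "reference_fauna": ["species", "weight_kg", "e_kcal", "h_hr", "c_hr", "p_fail"],
        "sites": ["site_id", "lon", "lat", "age_bp", "ctu"],
        "dates": ["site_id", "c14_age", "error"],
        "faunal": ["technocomplex"],
        "summary": ["ctu", "mean_spd", "mean_warm_t"],
    }
    issues: list[dict] = []
    for name, df in (tables or {}).items():
        if name not in required:
            issues.append({"dataset": name, "issue": "unknown dataset name"})
            continue
        for col in required[name]:
            if col not in df.columns:
                issues.append({"dataset": name, "issue": f"missing column {col!r}"})
        if name == "sites" and "age_bp" in df.columns:
            bad = int(((df["age_bp"] < 9000) | (df["age_bp"] > 22000)).sum())
            if bad:
                issues.append({"dataset": name, "issue": f"{bad} site ages outside 9000-22000 BP"})
        if name == "dates" and "error" in df.columns:
            bad = int((df["error"] <= 0).sum())
            if bad:
                issues.append({"dataset": name, "issue": f"{bad} non-positive date errors"})
    if config.summary_table is not None and not Path(config.summary_table).exists():
        issues.append({"dataset": "summary", "issue": f"file not found: {config.summary_table}"})
    return issues
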