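"""Fit the piecewise structural equation models and calibrate them.

Part 1 fits the species path models and the red-deer mediation model on
the CTU summary table produced by 04_combine_ctu.py (rerunning the
pipeline if it is absent). Part 2 runs the calibration experiment on
ground-truth pseudo-unit worlds: with no human-pressure effect in the
generating process the population path centers on zero, while a real
habitat-suitability effect is detected with high power -- the design's
discriminating property. Writes results/path_coefficients.csv and
results/psem_calibration.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from paleoforage import psem, synth
from paleoforage.pipeline import PipelineConfig, run_all

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0
N_REPS = 200
N_UNITS = 200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary_path = OUT / "ctu_summary.csv"
    if not summary_path.exists():
        run_all(PipelineConfig(out_dir=OUT, seed=SEED))
    summary = pd.read_csv(summary_path)

    warnings.filterwarnings("ignore", message="quasibinomial fit on only")
    tables = []
    for sp in ("reindeer", "boar", "red_deer"):
        res = psem.fit_species_psem(summary, sp)
        t = res.table()
        t.insert(0, "model", sp)
        tables.append(t)
    med = psem.fit_reddeer_psem(summary)
    t = med.table()
    t.insert(0, "model", "red_deer_mediation")
    tables.append(t)
    coef = pd.concat(tables, ignore_index=True)
    coef.to_csv(OUT / "path_coefficients.csv", index=False)
    show = coef[coef["term"] != "(Intercept)"]
    print("path coefficients on the 5-CTU synthetic table "
          "(std_beta = latent-standardized):")
    print(show[["model", "response", "term", "b", "se", "p", "std_beta"]]
          .round(3).to_string(index=False))
    print("\nCaution: with five aggregated units these individual fits "
          "carry 2-3 residual df; the calibration below is what "
          "validates the machinery.\n")

    rows = []
    betas, cover = [], 0
    for r in range(N_REPS):
        df, _ = synth.gen_pseudo_ctu_table(n_units=N_UNITS, b_suit=1.0, g_pop=0.0, seed=1000 + r)
        res = psem.fit_species_psem(df, "reindeer")
        path = res.path("zooarch", "population")
        betas.append(path["std_beta"])
        tcrit = stats.t.ppf(0.975, res.paths["zooarch"].df_resid)
        cover += abs(path["std_beta"]) <= tcrit * path["std_se"]
    rows.append({"experiment": "null_population_path", "mean_std_beta": np.mean(betas),
                 "coverage_95": cover / N_REPS, "n_reps": N_REPS})
    hits = 0
    for r in range(N_REPS):
        df, _ = synth.gen_pseudo_ctu_table(n_units=N_UNITS, b_suit=1.0, g_pop=0.0, seed=5000 + r)
        path = psem.fit_species_psem(df, "reindeer").path("zooarch", "suitability")
        hits += path["b"] > 0 and path["p"] < 0.05
    rows.append({"experiment": "suitability_power", "mean_std_beta": np.nan,
                 "coverage_95": np.nan, "n_reps": N_REPS, "power": hits / N_REPS})
    calib = pd.DataFrame(rows)
    calib.to_csv(OUT / "psem_calibration.csv", index=False)
    print(f"null worlds (g=0): population-path std_beta mean "
          f"{np.mean(betas):+.4f}, 95% interval coverage {cover / N_REPS:.3f}")
    print(f"effect worlds (b_suit=1): suitability path positive with "
          f"p<0.05 in {hits / N_REPS:.0%} of {N_REPS} replicates")
    print("When the generating process lacks human depression, the "
          "models say so; when habitat drives composition, they detect it.")


if __name__ == "__main__":
    main()
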