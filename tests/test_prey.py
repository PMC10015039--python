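"""Prey-choice model: return rates, allometry, ranking, diet breadth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoforage import prey
from paleoforage.errors import (
    DegenerateModelError,
    InsufficientDataError,
    InvalidParameterError,
)
from paleoforage.prey import AllometricFit, AllometricFits
from paleoforage.synth import gen_reference_fauna

valid_params = st.tuples(
    st.floats(1.0, 1e6),  # e
    st.floats(0.0, 0.99),  # p
    st.floats(0.01, 100.0),  # h
    st.floats(0.0, 100.0),  # c
)


class TestPerr:
    @pytest.mark.parametrize(
        "e,p,h,c,expected",
        [
            (3600, 0.0, 2, 1, 1200.0),  # no failure: e / (h + c)
            (3600, 1.0, 2, 1, 0.0),  # certain failure: zero return
            (3600, 0.5, 2, 1, 900.0),  # 1800 / 2
        ],
    )
    def test_hand_evaluated(self, e, p, h, c, expected):
        assert prey.perr(e, p, h, c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(e=-1, p=0.5, h=1, c=1),
            dict(e=100, p=1.5, h=1, c=1),
            dict(e=100, p=-0.1, h=1, c=1),
            dict(e=100, p=0.5, h=0, c=1),
            dict(e=100, p=0.5, h=1, c=-1),
        ],
    )
    def test_domain_violations(self, kwargs):
        with pytest.raises(InvalidParameterError):
            prey.perr(**kwargs)

    def test_certain_failure_without_pursuit_cost_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            prey.perr(100, 1.0, 2, 0.0)

    @given(valid_params)
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity_and_classical_reduction(self, params):
        e, p, h, c = params
        base = prey.perr(e, p, h, c)
        assert base >= 0 and np.isfinite(base)
        # p = 0 reduces to the classical e / (h + c)
        assert prey.perr(e, 0.0, h, c) == pytest.approx(e / (h + c), rel=1e-12)
        # strictly increasing in e
        assert prey.perr(e * 1.01, p, h, c) > base
        # strictly decreasing in h, and in c
        assert prey.perr(e, p, h * 1.01, c) < base
        assert prey.perr(e, p, h, c + 0.01) < base
        # strictly decreasing in p on (0,1) when c > 0 (evaluated with c
        # bounded away from 0, where the effect exceeds float precision)
        if p < 0.98:
            c_eff = max(c, 0.5)
            assert prey.perr(e, p + 0.01, h, c_eff) < prey.perr(e, p, h, c_eff)


class TestAllometry:
    def test_noiseless_linear_recovery(self):
        w = np.array([10.0, 50.0, 100.0, 400.0, 900.0])
        ref = pd.DataFrame(
            {
                "species": list("abcde"),
                "weight_kg": w,
                "e_kcal": 40.0 * w,
                "h_hr": w**0.7,
                "c_hr": 0.2 + 0.1 * np.log(w),
                "p_fail": 0.05 + 0.02 * np.log(w),
            }
        )
        fits = prey.fit_allometry(ref, transforms={"e": "linear"})
        assert fits["e"].slope == pytest.approx(40.0)
        assert fits["e"].r_squared == pytest.approx(1.0)
        assert fits["h"].slope == pytest.approx(0.7)
        assert fits["c"].slope == pytest.approx(0.1)
        assert fits["p"].slope == pytest.approx(0.02)

    def test_insufficient_and_degenerate_inputs(self):
        ref, _ = gen_reference_fauna(n=10, seed=0)
        with pytest.raises(InsufficientDataError):
            prey.fit_allometry(ref.head(3))
        const = ref.copy()
        const["weight_kg"] = 50.0
        with pytest.raises(DegenerateModelError):
            prey.fit_allometry(const)

    def test_slope_recovered_within_three_se(self):
        ref, truth = gen_reference_fauna(
            n=50, slopes={"e": 2.5}, noise_sds={"e": 0.1}, seed=11
        )
        fits = prey.fit_allometry(ref)
        lw = np.log(ref["weight_kg"])
        resid_se = 0.1 / np.sqrt(np.sum((lw - lw.mean()) ** 2))
        assert abs(fits["e"].slope - 2.5) < 3 * resid_se

    def test_ci_coverage_calibrated(self):
        """~95% of replicate 95% CIs contain the generating slope."""
        from scipy import stats

        n, hits, reps = 50, 0, 500
        for r in range(reps):
            ref, truth = gen_reference_fauna(n=n, seed=10_000 + r)
            fits = prey.fit_allometry(ref)
            lw = np.log(ref["weight_kg"].to_numpy())
            ly = np.log(ref["e_kcal"].to_numpy())
            res = stats.linregress(lw, ly)
            tcrit = stats.t.ppf(0.975, n - 2)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
            hits += lo <= truth["slopes"]["e"] <= hi
        assert 0.90 <= hits / reps <= 0.98


class TestPredictParameters:
    def test_line_evaluation_and_clamping(self):
        fits = AllometricFits(
            fits={
                "e": AllometricFit(10.0, 0.0, 0.0, 1.0, "linear"),
                "h": AllometricFit(0.0, 2.0, 0.0, 1.0, "linear"),
                "c": AllometricFit(0.0, 0.5, 0.0, 1.0, "linear"),
                "p": AllometricFit(0.1, -0.5, 0.0, 1.0, "linear-log"),
            },
            n_reference=10,
        )
        sp = pd.DataFrame({"species": ["big", "tiny"], "weight_kg": [100.0, 1.0]})
        out = prey.predict_parameters(fits, sp)
        assert out.loc[0, "e_kcal"] == pytest.approx(1000.0)
        # p(1 kg) = -0.5 -> clamped to 0
        assert out.loc[1, "p_fail"] == 0.0
        assert (out["provenance"] == "predicted").all()

    def test_nonpositive_weight_rejected(self):
        ref, _ = gen_reference_fauna(seed=0)
        fits = prey.fit_allometry(ref)
        with pytest.raises(InvalidParameterError):
            prey.predict_parameters(fits, pd.DataFrame({"species": ["x"], "weight_kg": [0.0]}))


class TestRankPrey:
    def test_sort_and_rank_assignment(self):
        df = pd.DataFrame(
            {
                "species": ["first", "second", "third"],
                "weight_kg": [10.0, 20.0, 30.0],
                "e_kcal": [10.0, 20.0, 15.0],
                "h_hr": [1.0, 1.0, 1.0],
                "c_hr": [0.0, 0.0, 0.0],
                "p_fail": [0.0, 0.0, 0.0],
            }
        )
        ranked = prey.rank_prey(df)
        assert list(ranked["species"]) == ["second", "third", "first"]
        assert list(ranked["rank"]) == [1, 2, 3]
        assert ranked["perr"].is_monotonic_decreasing

    def test_single_species(self):
        df = pd.DataFrame(
            {"species": ["only"], "weight_kg": [50.0], "e_kcal": [100.0], "h_hr": [1.0], "c_hr": [0.0], "p_fail": [0.0]}
        )
        assert prey.rank_prey(df)["rank"].tolist() == [1]

    def test_permutation_and_idempotence(self):
        ref, _ = gen_reference_fauna(n=15, seed=5)
        ranked = prey.rank_prey(ref)
        assert sorted(ranked["species"]) == sorted(ref["species"])
        again = prey.rank_prey(ranked.drop(columns=["perr", "rank"]))
        assert list(again["species"]) == list(ranked["species"])

    def test_tie_break_by_weight_then_name(self):
        df = pd.DataFrame(
            {
                "species": ["zeta", "alpha", "mid"],
                "weight_kg": [10.0, 10.0, 99.0],
                "e_kcal": [100.0, 100.0, 100.0],
                "h_hr": [1.0, 1.0, 1.0],
                "c_hr": [0.0, 0.0, 0.0],
                "p_fail": [0.0, 0.0, 0.0],
            }
        )
        assert list(prey.rank_prey(df)["species"]) == ["mid", "alpha", "zeta"]


class TestOverallReturnRate:
    def test_hand_evaluations(self, ranked_params):
        one = ranked_params.head(1)
        assert prey.overall_return_rate(one, {"alpha": 0.1}) == pytest.approx(1000 * 0.1 / 1.1)
        lam0 = {s: 0.0 for s in ranked_params["species"]}
        assert prey.overall_return_rate(ranked_params, lam0) == 0.0
        two = pd.DataFrame(
            {
                "species": ["a", "b"],
                "e_kcal": [100.0, 100.0],
                "h_hr": [1.0, 1.0],
                "c_hr": [0.0, 0.0],
                "p_fail": [0.0, 0.0],
            }
        )
        assert prey.overall_return_rate(two, {"a": 1.0, "b": 1.0}) == pytest.approx(200 / 3)

    def test_missing_rate_signalled(self, ranked_params):
        with pytest.raises(InvalidParameterError):
            prey.overall_return_rate(ranked_params, {"alpha": 0.1})


def brute_force_diet(ranking: pd.DataFrame, rates: dict) -> int:
    """Independent oracle: the rank-prefix maximizing the overall rate."""
    best_j, best_rate = 1, -np.inf
    for j in range(1, len(ranking) + 1):
        r = prey.overall_return_rate(ranking.head(j), rates)
        if r > best_rate:
            best_rate, best_j = r, j
    return best_j


class TestDietBreadth:
    def test_worked_example(self, ranked_params):
        rates = {"alpha": 0.1, "beta": 0.1, "gamma": 10.0}
        db = prey.diet_breadth(ranked_params, rates)
        assert db.included_species == ("alpha", "beta")
        assert db.overall_return_rate == pytest.approx(150 / 1.2)

    def test_single_species_always_included(self, ranked_params):
        db = prey.diet_breadth(ranked_params.head(1), {"alpha": 1e-9})
        assert db.included_species == ("alpha",)

    def test_excluded_species_density_irrelevant(self, ranked_params):
        rates = {"alpha": 0.1, "beta": 0.1, "gamma": 10.0}
        base = prey.diet_breadth(ranked_params, rates)
        rates["gamma"] *= 10
        assert prey.diet_breadth(ranked_params, rates).included_species == base.included_species

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            n = rng.integers(1, 9)
            df = pd.DataFrame(
                {
                    "species": [f"s{i}" for i in range(n)],
                    "weight_kg": rng.uniform(5, 500, n),
                    "e_kcal": rng.uniform(100, 5000, n),
                    "h_hr": rng.uniform(0.1, 10, n),
                    "c_hr": rng.uniform(0, 2, n),
                    "p_fail": rng.uniform(0, 0.9, n),
                }
            )
            ranking = prey.rank_prey(df)
            rates = {s: rng.uniform(0, 2) for s in df["species"]}
            db = prey.diet_breadth(ranking, rates)
            assert db.cutoff_rank == brute_force_diet(ranking, rates)

    def test_empty_ranking_signalled(self):
        with pytest.raises(InsufficientDataError):
            prey.diet_breadth(pd.DataFrame(columns=["species", "rank", "perr"]), {})
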