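"""Climate-envelope model: features, maxent fit, AUC, CV, hindcast,
site extraction."""

import numpy as np
import pandas as pd
import pytest

from paleoforage import sdm, synth
from paleoforage.errors import ExtentError, InsufficientDataError, InvalidParameterError
from paleoforage.sdm import FeatureScaling, OccurrenceSet


@pytest.fixture(scope="module")
def planted_occ(small_slice):
    """Presences drawn from exp(2 z1 - z1^2) on the mean-temperature axis."""
    w = np.array([2.0, 0, 0, 0, -1.0, 0, 0, 0])
    occ, truth = synth.gen_occurrences(small_slice, w, n_presence=600, n_background=3000, seed=9)
    return occ, truth


class TestBuildFeatures:
    def test_centering_and_unit_scaling(self):
        scaling = FeatureScaling(means=np.array([1.0, 2.0, 3.0, 4.0]), sds=np.ones(4))
        assert np.allclose(sdm.build_features(np.array([1.0, 2.0, 3.0, 4.0]), scaling), 0.0)
        f = sdm.build_features(np.array([2.0, 2.0, 3.0, 4.0]), scaling)
        assert f[0] == pytest.approx(1.0) and f[4] == pytest.approx(1.0)
        assert np.allclose(f[[1, 2, 3, 5, 6, 7]], 0.0)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 3, size=(20, 4))
        scaling = FeatureScaling.from_values(vals)
        z = (vals - vals.mean(0)) / vals.std(0)
        assert np.allclose(sdm.build_features(vals, scaling), np.hstack([z, z**2]))

    def test_nonfinite_rejected(self):
        scaling = FeatureScaling(means=np.zeros(4), sds=np.ones(4))
        with pytest.raises(InvalidParameterError):
            sdm.build_features(np.array([1.0, np.nan, 0.0, 0.0]), scaling)


class TestAuc:
    @pytest.mark.parametrize(
        "pres,bg,expected",
        [
            ([3, 4], [1, 2], 1.0),
            ([1, 2], [1, 2], 0.5),
            ([1, 3], [2, 4], 0.25),
        ],
    )
    def test_enumerated_cases(self, pres, bg, expected):
        assert sdm.auc(pres, bg) == pytest.approx(expected)

    def test_complement_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        assert sdm.auc(a, b) + sdm.auc(b, a) == pytest.approx(1.0)
        assert sdm.auc(np.exp(a), np.exp(b)) == pytest.approx(sdm.auc(a, b))

    def test_empty_input_signalled(self):
        with pytest.raises(InsufficientDataError):
            sdm.auc([], [1.0])


class TestFitEnvelope:
    def test_sign_recovery_from_planted_surface(self, small_slice, planted_occ):
        occ, _ = planted_occ
        model = sdm.fit_envelope(occ, small_slice, reg_multiplier=0.5)
        assert model.weights[0] > 0.5  # linear term on mean temperature
        assert model.weights[4] < -0.2  # quadratic term

    def test_uniform_presences_shrink_to_zero(self, small_slice):
        occ, _ = synth.gen_occurrences(small_slice, np.zeros(8), n_presence=400, n_background=2000, seed=4)
        model = sdm.fit_envelope(occ, small_slice, reg_multiplier=20.0)
        assert np.abs(model.weights).sum() < 0.05

    def test_duplication_invariance(self, small_slice, planted_occ):
        occ, _ = planted_occ
        doubled = OccurrenceSet(np.vstack([occ.presence, occ.presence]), occ.background)
        m1 = sdm.fit_envelope(occ, small_slice, reg_multiplier=1.0)
        m2 = sdm.fit_envelope(doubled, small_slice, reg_multiplier=1.0)
        assert np.allclose(m1.weights, m2.weights)

    def test_penalty_norm_monotone_in_regularization(self, small_slice, planted_occ):
        # with per-feature penalty scales the multiplier directly
        # controls sum_f lam_f |w_f|, which is non-increasing in it
        occ, _ = planted_occ
        norms = [
            sdm.fit_envelope(occ, small_slice, reg_multiplier=m).penalty_weighted_norm()
            for m in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b <= a + 1e-7 for a, b in zip(norms, norms[1:]))

    def test_too_few_presences_signalled(self, small_slice):
        occ, _ = synth.gen_occurrences(small_slice, np.zeros(8), n_presence=400, n_background=1000, seed=0)
        with pytest.raises(InsufficientDataError):
            sdm.fit_envelope(OccurrenceSet(occ.presence[:5], occ.background), small_slice)


class TestSelectRegularization:
    def test_single_candidate_chosen(self, small_slice, planted_occ):
        occ, _ = planted_occ
        sel = sdm.select_regularization(occ, small_slice, [1.5], seed=0)
        assert sel["chosen"] == 1.5

    def test_signal_prefers_weak_regularization(self, small_slice, planted_occ):
        occ, _ = planted_occ
        sel = sdm.select_regularization(occ, small_slice, [0.5, 100.0], seed=0)
        assert sel["chosen"] == 0.5
        tab = sel["table"].set_index("multiplier")
        assert tab.loc[0.5, "mean_auc"] > tab.loc[100.0, "mean_auc"]

    def test_tie_broken_toward_larger_multiplier(self, small_slice, planted_occ):
        # at extreme regularization all weights vanish, scores are
        # constant and both candidates give AUC 0.5 exactly
        occ, _ = planted_occ
        sel = sdm.select_regularization(occ, small_slice, [500.0, 1000.0], seed=0)
        assert sel["chosen"] == 1000.0

    def test_k_exceeding_presences_signalled(self, small_slice, planted_occ):
        occ, _ = planted_occ
        tiny = OccurrenceSet(occ.presence[:3], occ.background)
        with pytest.raises(InsufficientDataError):
            sdm.select_regularization(tiny, small_slice, [1.0], k=4)


class TestHindcast:
    def test_zero_weight_model_constant(self, small_slice):
        scaling = FeatureScaling.from_values(small_slice.valid_cell_values())
        model = sdm.EnvelopeModel(
            weights=np.zeros(8), scaling=scaling, reg_multiplier=1.0,
            log_normalizer=0.0, cloglog_offset=0.0,
        )
        surf = sdm.hindcast(model, small_slice)
        vals = surf.values[small_slice.valid]
        assert np.allclose(vals, vals[0])

    def test_monotone_link_along_weighted_variable(self, small_slice):
        scaling = FeatureScaling.from_values(small_slice.valid_cell_values())
        model = sdm.EnvelopeModel(
            weights=np.array([1.0, 0, 0, 0, 0, 0, 0, 0]), scaling=scaling,
            reg_multiplier=1.0, log_normalizer=0.0, cloglog_offset=0.0,
        )
        surf = sdm.hindcast(model, small_slice)
        t = small_slice.variables["tmean"][small_slice.valid]
        s = surf.values[small_slice.valid]
        order = np.argsort(t)
        assert np.all(np.diff(s[order]) >= -1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_training_scores_reproduced_bitwise(self, small_slice, planted_occ):
        occ, _ = planted_occ
        model = sdm.fit_envelope(occ, small_slice, reg_multiplier=1.0)
        surf = sdm.hindcast(model, small_slice)
        vals = small_slice.valid_cell_values()
        direct = model.suitability(vals)
        assert np.array_equal(surf.values[small_slice.valid], direct)


class TestExtractAtSites:
    @pytest.fixture()
    def surfaces(self, small_slice):
        scaling = FeatureScaling.from_values(small_slice.valid_cell_values())
        model = sdm.EnvelopeModel(
            weights=np.zeros(8), scaling=scaling, reg_multiplier=1.0,
            log_normalizer=0.0, cloglog_offset=0.0,
        )
        return {c: sdm.hindcast(model, small_slice) for c in (12300, 12400)}

    def test_century_rounding_half_up(self, surfaces, small_slice):
        lon = small_slice.x0 + 2.25 * small_slice.cellsize
        lat = small_slice.y0 - 2.25 * small_slice.cellsize
        sites = pd.DataFrame(
            {
                "site_id": ["a", "b"],
                "lon": [lon, lon],
                "lat": [lat, lat],
                "age_bp": [12349.0, 12350.0],
            }
        )
        out, skipped = sdm.extract_at_sites(surfaces, sites)
        assert out.set_index("site_id")["century"].to_dict() == {"a": 12300, "b": 12400}
        assert sum(skipped.values()) == 0

    def test_skip_paths_logged(self, surfaces, small_slice):
        sites = pd.DataFrame(
            {
                "site_id": ["off_grid", "bad_century"],
                "lon": [small_slice.x0 - 100.0, small_slice.x0 + 1.0],
                "lat": [small_slice.y0 + 100.0, small_slice.y0 - 1.0],
                "age_bp": [12300.0, 17000.0],
            }
        )
        out, skipped = sdm.extract_at_sites(surfaces, sites)
        assert len(out) == 0
        assert skipped == {"out_of_range_century": 1, "out_of_extent": 1}

    def test_nodata_cell_skipped(self, small_slice):
        masked = sdm.ClimateSlice(
            century=12300,
            variables={k: v.copy() for k, v in small_slice.variables.items()},
            x0=small_slice.x0, y0=small_slice.y0, cellsize=small_slice.cellsize,
            valid=small_slice.valid.copy(),
        )
        masked.valid[0, 0] = False
        scaling = FeatureScaling.from_values(masked.valid_cell_values())
        model = sdm.EnvelopeModel(
            weights=np.zeros(8), scaling=scaling, reg_multiplier=1.0,
            log_normalizer=0.0, cloglog_offset=0.0,
        )
        surfaces = {12300: sdm.hindcast(model, masked)}
        sites = pd.DataFrame(
            {
                "site_id": ["sea"],
                "lon": [masked.x0 + 0.5 * masked.cellsize],
                "lat": [masked.y0 - 0.5 * masked.cellsize],
                "age_bp": [12311.0],
            }
        )
        out, skipped = sdm.extract_at_sites(surfaces, sites)
        assert len(out) == 0 and skipped["out_of_extent"] == 1


def test_values_at_raises_off_grid(small_slice):
    with pytest.raises(ExtentError):
        small_slice.values_at(small_slice.x0 - 5.0, small_slice.y0)


def test_climate_slice_frame_roundtrip(small_slice):
    df = small_slice.to_frame()
    back = sdm.ClimateSlice.from_frame(
        df, small_slice.shape, small_slice.x0, small_slice.y0, small_slice.cellsize
    )
    for v in sdm.CLIMATE_VARS:
        assert np.allclose(
            back.variables[v][back.valid], small_slice.variables[v][small_slice.valid]
        )
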