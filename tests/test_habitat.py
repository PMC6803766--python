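"""Pseudo-absence construction, detection weights and occurrence models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rangeshift.grids import GridSpec
from rangeshift.habitat import (
    assign_pixel_habitat,
    buffer_class_fractions,
    candidate_absences,
    detection_weight,
    detection_weights_for_absences,
    fit_habitat_model,
    margin_context,
    phenology_filter,
    phenology_keep,
    specialisation,
)
from rangeshift.synthetic import N_CLASSES, LandCoverMap


def _lc_uniform(grid, cls=0):
    return LandCoverMap(np.full(grid.lc_shape, cls, dtype=np.int16))


class TestPixelHabitat:
    def test_uniform_pixel_has_weight_one(self):
        grid = GridSpec(0, 0, 1, 1)
        lc = _lc_uniform(grid, 4)
        assert assign_pixel_habitat(0, 0, lc) == (4, 1.0)

    def test_nine_of_sixteen_counting_oracle(self):
        grid = GridSpec(0, 0, 1, 1)
        arr = np.zeros(grid.lc_shape, dtype=np.int16)
        block = np.full(16, 2, dtype=np.int16)
        block[:9] = 7
        arr[:4, :4] = block.reshape(4, 4)
        cls, w = assign_pixel_habitat(0, 0, LandCoverMap(arr))
        assert (cls, w) == (7, 9 / 16)

    def test_tie_breaks_to_lowest_code(self):
        grid = GridSpec(0, 0, 1, 1)
        arr = np.zeros(grid.lc_shape, dtype=np.int16)
        block = np.array([3] * 8 + [7] * 8, dtype=np.int16)
        arr[:4, :4] = block.reshape(4, 4)
        cls, w = assign_pixel_habitat(0, 0, LandCoverMap(arr))
        assert (cls, w) == (3, 0.5)

    def test_fully_discarded_pixel_excluded(self):
        grid = GridSpec(0, 0, 1, 1)
        arr = np.full(grid.lc_shape, -1, dtype=np.int16)
        assert assign_pixel_habitat(0, 0, LandCoverMap(arr)) == (-1, 0.0)


class TestDetectionWeight:
    def test_certain_detection_gives_weight_one(self):
        assert detection_weight(3, np.ones(5)) == 1.0

    @pytest.mark.parametrize(
        "t,p,expected",
        [(2, [0.5], 0.75), (1, [1.0, 0.0], 0.5), (1, [0.2, 0.4, 0.6], 0.4)],
    )
    def test_hand_evaluations(self, t, p, expected):
        assert detection_weight(t, np.array(p)) == pytest.approx(expected)

    def test_monotone_in_visits_and_probability(self):
        p = np.array([0.3, 0.6])
        assert detection_weight(2, p) > detection_weight(1, p)
        assert detection_weight(2, p + 0.1) > detection_weight(2, p)
        assert detection_weight(500, p) == pytest.approx(1.0, abs=1e-10)

    def test_matches_monte_carlo_oracle(self):
        # simulate the detection process directly: t visits, site drawn
        # uniformly, per-visit detection Bernoulli(p_s)
        rng = np.random.default_rng(0)
        p = np.array([0.15, 0.5, 0.85])
        t = 3
        n_trials = 10_000
        sites = rng.integers(0, 3, n_trials)
        detected = (rng.random((n_trials, t)) < p[sites][:, None]).any(axis=1)
        mc = detected.mean()
        exact = detection_weight(t, p)
        se = np.sqrt(exact * (1 - exact) / n_trials)
        assert abs(mc - exact) <= 3 * se

    def test_zero_visits_rejected(self):
        with pytest.raises(ValueError):
            detection_weight(0, np.array([0.5]))


def _visit_table(rows):
    df = pd.DataFrame(rows, columns=["scheme", "easting_km", "northing_km", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def _record_table(rows):
    df = pd.DataFrame(
        rows, columns=["species", "scheme", "easting_km", "northing_km", "precision", "date"]
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestCandidateAbsences:
    def _grid(self):
        return GridSpec(0, 0, 20, 20)  # 200 km square

    def test_only_visited_pixels_are_candidates(self):
        grid = self._grid()
        visits = _visit_table([("g", 10.05, 10.05, "1980-06-01")])
        records = _record_table(
            [("sp", "g", 10.15, 10.15, "ha", "1980-06-01"), ("sp", "g", 10.15, 10.15, "ha", "2005-06-01")]
        )
        cand = candidate_absences("sp", "g", visits, records, grid)
        assert len(cand) == 1  # the unvisited presence pixel is not there
        assert cand.iloc[0]["survives"]

    def test_distance_flag_beyond_50km(self):
        grid = self._grid()
        visits = _visit_table(
            [("g", 10.05, 10.05, "1980-06-01"), ("g", 10.05, 170.05, "1980-06-01")]
        )
        records = _record_table(
            [("sp", "g", 10.15, 10.15, "ha", "1980-06-01"), ("sp", "g", 10.15, 10.15, "ha", "2005-06-01")]
        )
        cand = candidate_absences("sp", "g", visits, records, grid).set_index("northing_km")
        assert not cand.loc[10.05, "too_far"]
        assert cand.loc[170.05, "too_far"] and not cand.loc[170.05, "survives"]

    def test_single_period_landscape_flag(self):
        grid = self._grid()
        visits = _visit_table([("g", 10.05, 10.05, "1980-06-01")])
        records = _record_table([("sp", "g", 10.15, 10.15, "ha", "1980-06-01")])  # period 1 only
        cand = candidate_absences("sp", "g", visits, records, grid)
        assert cand.iloc[0]["single_period"] and not cand.iloc[0]["survives"]

    def test_presence_pixels_flagged(self):
        grid = self._grid()
        visits = _visit_table([("g", 10.05, 10.05, "1980-06-01")])
        records = _record_table(
            [("sp", "g", 10.05, 10.05, "ha", "1980-06-01"), ("sp", "g", 10.05, 10.05, "ha", "2005-06-01")]
        )
        cand = candidate_absences("sp", "g", visits, records, grid)
        assert cand.iloc[0]["presence_pixel"] and not cand.iloc[0]["survives"]


class TestPhenology:
    def test_modal_date_retained_uniform_tail_removed(self):
        target = np.arange(100, 201, dtype=float)  # uniform days 100..200
        keep = phenology_keep(np.array([150.0, 104.0]), target)
        assert keep[0] and not keep[1]

    def test_percentile_fallback_small_samples(self):
        target = np.linspace(100, 200, 8)  # < 10 dates: raw percentiles
        keep = phenology_keep(np.array([150.0, 101.0, 199.0]), target)
        assert keep.tolist() == [True, False, False]

    def test_year_break_handled_circularly(self):
        # winter species flying Dec..Jan: mid-season dates on both sides of
        # the break are kept, a mid-summer date is not
        target = np.concatenate([np.arange(335, 366), np.arange(1, 32)]).astype(float)
        target = np.repeat(target, 3)
        keep = phenology_keep(np.array([360.0, 5.0, 180.0]), target)
        assert keep[0] and keep[1] and not keep[2]

    def test_no_local_dates_excludes_candidate(self):
        grid = GridSpec(0, 0, 20, 20)
        visits = _visit_table([("g", 10.05, 10.05, "1980-06-01")] * 3)
        records = _record_table(
            [("sp", "g", 10.15, 10.15, "ha", "1980-06-01"), ("sp", "g", 10.15, 10.15, "ha", "2005-06-01")]
        )
        cand = candidate_absences("sp", "g", visits, records, grid)
        empty = records.iloc[0:0]
        out = phenology_filter(cand, empty, "sp", grid)
        assert out["no_phenology"].all() and not out["survives"].any()


class TestFitHabitatModel:
    def _simulate(self, pref, seed, n=1500, climate_beta=(0.5, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        cls = rng.integers(0, N_CLASSES, n)
        z = rng.normal(size=(n, 3))
        p = expit(pref[cls] + z @ np.array(climate_beta))
        y = (rng.random(n) < p).astype(float)
        return pd.DataFrame(
            dict(
                y=y,
                habitat_class=cls,
                habitat_weight=1.0,
                detection_weight=1.0,
                winter_min=z[:, 0],
                degree_days=z[:, 1],
                moisture=z[:, 2],
            )
        )

    def test_specialist_class_recovered(self):
        # strong single-class preference: that class gets the top fitted
        # probability in nearly every seed
        pref = np.full(N_CLASSES, -2.0)
        pref[6] = 2.0
        hits = 0
        for seed in range(50):
            m = fit_habitat_model(self._simulate(pref, seed), "spec")
            hits += m.class_probs.argmax() == 6
        assert hits >= 48  # >= 95% of 50 seeds

    def test_generalist_cv_below_specialist(self):
        spec_pref = np.full(N_CLASSES, -2.0)
        spec_pref[6] = 2.0
        gen_pref = np.zeros(N_CLASSES)
        wins = 0
        for seed in range(50):
            m_s = fit_habitat_model(self._simulate(spec_pref, seed), "s")
            m_g = fit_habitat_model(self._simulate(gen_pref, 10_000 + seed), "g")
            wins += specialisation(m_g.class_probs) < specialisation(m_s.class_probs)
        assert wins >= 48

    def test_all_presence_input_is_an_error(self):
        df = self._simulate(np.zeros(N_CLASSES), 0)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            fit_habitat_model(df, "bad")

    def test_unobserved_class_flagged_with_intercept_probability(self):
        df = self._simulate(np.zeros(N_CLASSES), 1)
        df = df[df["habitat_class"] != 9]
        m = fit_habitat_model(df, "gap")
        assert "class-9-unobserved" in m.flags
        assert m.class_probs[9] == pytest.approx(expit(m.intercept))

    def test_dispersion_positive_and_probs_in_unit_interval(self):
        m = fit_habitat_model(self._simulate(np.zeros(N_CLASSES), 2), "ok")
        assert m.dispersion > 0
        assert np.all((m.class_probs > 0) & (m.class_probs < 1))

    def test_detection_weights_reduce_absence_influence(self):
        # weighting absences to near zero pushes fitted probabilities up
        df = self._simulate(np.zeros(N_CLASSES), 3)
        df_w = df.copy()
        df_w.loc[df_w["y"] == 0, "detection_weight"] = 0.05
        m0 = fit_habitat_model(df, "a")
        m1 = fit_habitat_model(df_w, "b")
        assert m1.class_probs.mean() > m0.class_probs.mean()


class TestSpecialisation:
    def test_equal_probabilities_give_zero(self):
        assert specialisation(np.full(18, 0.3)) == 0.0

    def test_indicator_vector_closed_form(self):
        p = np.full(18, 1e-9)
        p[0] = 1.0
        assert specialisation(p) == pytest.approx(np.sqrt(18), rel=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.9, 18)
        assert specialisation(3 * p) == pytest.approx(specialisation(p))


class TestMarginContext:
    def _model(self, probs_logit, climate_coefs=(1.0, 0.0, 0.0)):
        from rangeshift.habitat import SpeciesHabitatModel

        return SpeciesHabitatModel(
            species="m",
            intercept=0.0,
            class_coefs=np.asarray(probs_logit, dtype=float),
            climate_coefs=np.array(climate_coefs),
            climate_means=np.zeros(3),
            dispersion=1.0,
            class_probs=expit(np.asarray(probs_logit, dtype=float)),
            reference_class=0,
        )

    def test_identical_period_climates_give_zero_exposure(self):
        grid = GridSpec(0, 0, 2, 2)
        lc = _lc_uniform(grid, 0)
        model = self._model(np.zeros(N_CLASSES))
        ctx = margin_context(
            model, lc, grid, np.array([[10.0, 10.0]]), np.zeros(3), np.zeros(3)
        )
        assert ctx.exposure == 0.0

    def test_uniform_buffer_availability_is_class_probability(self):
        grid = GridSpec(0, 0, 2, 2)
        lc = _lc_uniform(grid, 5)
        logits = np.linspace(-2, 2, N_CLASSES)
        model = self._model(logits)
        ctx = margin_context(
            model, lc, grid, np.array([[10.0, 10.0]]), np.zeros(3), np.zeros(3)
        )
        assert ctx.availability == pytest.approx(expit(logits[5]))
        assert ctx.log10_availability == pytest.approx(np.log10(expit(logits[5])))

    def test_suitability_doubling_gives_ln2_exposure(self):
        grid = GridSpec(0, 0, 2, 2)
        lc = _lc_uniform(grid, 0)
        # tiny probabilities are ~linear in odds: climate shift of ln 2
        # doubles suitability
        model = self._model(np.full(N_CLASSES, -8.0), climate_coefs=(1.0, 0.0, 0.0))
        c1 = np.zeros(3)
        c2 = np.array([np.log(2.0), 0.0, 0.0])
        ctx = margin_context(model, lc, grid, np.array([[10.0, 10.0]]), c1, c2)
        assert ctx.exposure == pytest.approx(np.log(2.0), abs=1e-3)

    def test_exposure_antisymmetry(self):
        grid = GridSpec(0, 0, 2, 2)
        rng = np.random.default_rng(1)
        lc = LandCoverMap(rng.integers(0, N_CLASSES, grid.lc_shape).astype(np.int16))
        model = self._model(rng.normal(size=N_CLASSES), climate_coefs=(0.7, -0.3, 0.2))
        c1, c2 = rng.normal(size=(2, 3))
        a = margin_context(model, lc, grid, np.array([[10.0, 10.0]]), c1, c2).exposure
        b = margin_context(model, lc, grid, np.array([[10.0, 10.0]]), c2, c1).exposure
        assert a == pytest.approx(-b)

    def test_availability_equals_bruteforce_pixel_mean(self):
        grid = GridSpec(0, 0, 2, 2)
        rng = np.random.default_rng(2)
        lc = LandCoverMap(rng.integers(0, N_CLASSES, grid.lc_shape).astype(np.int16))
        logits = rng.normal(size=N_CLASSES)
        model = self._model(logits)
        centre = np.array([[10.0, 10.0]])
        ctx = margin_context(model, lc, grid, centre, np.zeros(3), np.zeros(3))
        # brute force over every 25 m pixel in the buffer
        ny, nx = lc.classes.shape
        pn = (np.arange(ny) + 0.5) * 0.025
        pe = (np.arange(nx) + 0.5) * 0.025
        nn, ee = np.meshgrid(pn, pe, indexing="ij")
        mask = (nn - 10.0) ** 2 + (ee - 10.0) ** 2 <= 50.0**2
        probs = expit(logits)[lc.classes[mask]]
        assert ctx.availability == pytest.approx(probs.mean(), abs=1e-12)

    def test_empty_buffer_errors(self):
        grid = GridSpec(0, 0, 2, 2)
        lc = LandCoverMap(np.full(grid.lc_shape, -1, dtype=np.int16))
        with pytest.raises(ValueError):
            buffer_class_fractions(lc, grid, np.array([[10.0, 10.0]]))


class TestDetectionWeightsIntegration:
    def test_weights_from_visit_and_record_tables(self):
        grid = GridSpec(0, 0, 20, 20)
        # presence site visited 4x recorded 2x -> p = 0.5; absence visited 2x
        visits = _visit_table(
            [("g", 10.05, 10.05, f"1980-06-{d:02d}") for d in (1, 2, 3, 4)]
            + [("g", 10.05, 12.05, "1980-06-01"), ("g", 10.05, 12.05, "1980-06-02")]
        )
        records = _record_table(
            [
                ("sp", "g", 10.05, 10.05, "ha", "1980-06-01"),
                ("sp", "g", 10.05, 10.05, "ha", "2005-06-02"),
            ]
        )
        cand = candidate_absences("sp", "g", visits, records, grid)
        cand = cand[cand["survives"]]
        w = detection_weights_for_absences(cand, "sp", "g", visits, records, grid)
        # p_s = 0.5, t = 2 -> 1 - 0.25 = 0.75
        assert w[0] == pytest.approx(0.75)
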