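"""Linear condition models, AICc selection and day standardisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pupmonitor import condition_models as cm
from pupmonitor import synthetic_data as sd


def make_records(
    seed=0, n=1200, n_years=6, sex_effect=0.7, day_effect=0.04,
    colony_effects=(0.0, -0.5), year_sd=0.3, noise_sd=0.5,
):
    """Directly generated additive records (independent of the simulator)."""
    rng = np.random.default_rng(seed)
    colonies = [f"col{i}" for i in range(len(colony_effects))]
    colony = rng.choice(len(colonies), n)
    year = rng.integers(0, n_years, n)
    year_effects = rng.normal(0, year_sd, n_years)
    sex = rng.integers(0, 2, n)  # 1 = male
    day = rng.integers(20, 41, n)
    mass = (
        6.0
        + sex_effect * sex
        + day_effect * (day - 30)
        + np.asarray(colony_effects)[colony]
        + year_effects[year]
        + rng.normal(0, noise_sd, n)
    )
    return pd.DataFrame(
        {
            "colony": np.asarray(colonies)[colony],
            "year": 2000 + year,
            "day": day,
            "sex": np.where(sex == 1, "male", "female"),
            "mass_kg": mass,
            "bci1": mass / 70.0,
        }
    )


FULL = cm.ModelSpec("mass", ("Year", "Sex", "Colony", "Day"))


class TestFit:
    def test_intercept_only_hand_arithmetic(self):
        df = make_records(n=3).iloc[:3].copy()
        df["mass_kg"] = [5.0, 6.0, 7.0]
        fm = cm.fit_linear_model(cm.ModelSpec("mass", ()), df)
        assert fm.coefficients.loc["Intercept", "coef"] == pytest.approx(6.0)
        assert fm.rss == pytest.approx(2.0)
        assert np.isnan(fm.aicc)  # n=3 is below the AICc correction's floor

    def test_zero_noise_recovers_coefficients_exactly(self):
        df = make_records(seed=1, noise_sd=0.0, year_sd=0.4)
        fm = cm.fit_linear_model(FULL, df)
        assert fm.adj_r2 == pytest.approx(1.0, abs=1e-10)
        assert fm.coefficients.loc["C(sex)[T.male]", "coef"] == pytest.approx(
            0.7, abs=1e-8
        )
        assert fm.coefficients.loc["day", "coef"] == pytest.approx(0.04, abs=1e-8)
        assert fm.coefficients.loc["C(colony)[T.col1]", "coef"] == pytest.approx(
            -0.5, abs=1e-8
        )

    def test_simulator_effects_recovered_within_ci(self):
        """Generator truth (male +0.69 kg, +0.04 kg/day, colony offsets
        -0.14 and -0.75 kg) falls inside each coefficient's 95% CI."""
        ds = sd.simulate_dataset(sd.coefficient_recovery_config(seed=12345))
        fm = cm.fit_linear_model(FULL, ds.biometrics)
        truth = {
            "C(sex)[T.male]": 0.69,
            "day": 0.04,
            "C(colony)[T.Colony-North]": -0.14,
            "C(colony)[T.Colony-South-Island]": -0.75,
        }
        for name, true_val in truth.items():
            row = fm.coefficients.loc[name]
            assert row["ci_lower"] <= true_val <= row["ci_upper"], name

    def test_unknown_sex_excluded_when_sex_modelled(self):
        df = make_records(seed=2, n=300)
        df.loc[:49, "sex"] = "unknown"
        with_sex = cm.fit_linear_model(cm.ModelSpec("mass", ("Sex",)), df)
        without = cm.fit_linear_model(cm.ModelSpec("mass", ()), df)
        assert with_sex.n == 250
        assert without.n == 300

    def test_rank_deficient_design_names_columns(self):
        df = make_records(seed=3, n=200)
        df["colony"] = np.where(df["year"] == 2000, "colA", "colB")
        df["year"] = np.where(df["colony"] == "colA", 2000, 2001)
        with pytest.raises(ValueError, match="aliased.*colony|aliased.*year"):
            cm.fit_linear_model(cm.ModelSpec("mass", ("Year", "Colony")), df)


class TestAicc:
    def test_small_sample_correction_arithmetic(self):
        # 2k(k+1)/(n-k-1) for n=10, k=3 is 4
        df = make_records(seed=4, n=10)
        fm = cm.fit_linear_model(cm.ModelSpec("mass", ("Day",)), df.iloc[:10])
        assert fm.k == 3
        assert fm.aicc == pytest.approx(-2 * fm.loglik + 2 * 3 + 4.0)

    def test_identical_fits_have_identical_aicc(self):
        df = make_records(seed=5)
        a = cm.fit_linear_model(cm.ModelSpec("mass", ("Sex",)), df)
        b = cm.fit_linear_model(cm.ModelSpec("mass", ("Sex",)), df)
        assert a.aicc == b.aicc

    def test_junk_predictors_penalised_on_pure_noise(self):
        rng = np.random.default_rng(6)
        df = make_records(seed=6, n=100, sex_effect=0, day_effect=0,
                          colony_effects=(0.0,), year_sd=0.0, noise_sd=1.0)
        # 18 junk year levels via a fake fine-grained factor
        df["year"] = rng.integers(0, 18, 100)
        null = cm.fit_linear_model(cm.ModelSpec("mass", ()), df)
        junk = cm.fit_linear_model(cm.ModelSpec("mass", ("Year",)), df)
        assert null.aicc < junk.aicc

    @given(st.floats(min_value=-100, max_value=100))
    def test_aicc_ordering_invariant_to_response_shift(self, shift):
        df = make_records(seed=7, n=400)
        shifted = df.assign(mass_kg=df["mass_kg"] + shift)
        specs = [cm.ModelSpec("mass", ()), cm.ModelSpec("mass", ("Sex", "Day"))]
        deltas = [
            cm.fit_linear_model(s, df).aicc - cm.fit_linear_model(s, shifted).aicc
            for s in specs
        ]
        assert deltas[0] == pytest.approx(deltas[1], abs=1e-6)


class TestSelection:
    def test_strong_effects_select_full_model(self):
        ds = sd.simulate_dataset(
            sd.coefficient_recovery_config(seed=8, n_pups_per_year=85,
                                           year_effect_sd=0.3)
        )
        candidates = [
            cm.ModelSpec("mass", ("Sex",)),
            cm.ModelSpec("mass", ("Sex", "Day")),
            FULL,
        ]
        best, ranking = cm.select_model(candidates, ds.biometrics)
        assert best.spec == FULL
        assert list(ranking["model"])[0] == FULL.label()
        assert ranking["delta_aicc"].iloc[0] == 0.0

    def test_identical_candidates_tie_goes_to_first(self):
        df = make_records(seed=9, n=300)
        spec = cm.ModelSpec("mass", ("Sex",))
        best, ranking = cm.select_model([spec, spec], df)
        assert best.spec == spec
        assert (ranking["aicc"] == ranking["aicc"].iloc[0]).all()
        assert ranking.sort_values("order")["order"].tolist() == [0, 1]

    def test_sex_only_signal_beats_intercept_in_most_replicates(self):
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            df = make_records(seed=100 + seed, n=400, sex_effect=0.7,
                              day_effect=0.0, colony_effects=(0.0,),
                              year_sd=0.0, noise_sd=1.0)
            best, _ = cm.select_model(
                [cm.ModelSpec("mass", ()), cm.ModelSpec("mass", ("Sex",))], df
            )
            wins += best.spec.terms == ("Sex",)
        assert wins >= 0.95 * n_rep

    def test_oversized_candidates_annotated_not_fatal(self):
        df = make_records(seed=10, n=200)
        candidates = [FULL, cm.ModelSpec("mass", ("Day",))]
        best, ranking = cm.select_model(candidates, df, max_params=3)
        assert best.spec.terms == ("Day",)
        notes = ranking.set_index("model")["note"]
        assert "max_params" in notes[FULL.label()]

    def test_candidate_generator_scope(self):
        specs = cm.candidate_specs("mass", include_interactions=False)
        assert len(specs) == 16  # all subsets of four main effects
        labels = {s.label() for s in cm.candidate_specs("mass")}
        assert "mass ~ Year + Sex + Year:Sex" in labels


class TestStandardisation:
    def test_all_on_reference_day_equals_raw_year_means(self):
        df = make_records(seed=11, n=600, colony_effects=(0.0,), sex_effect=0.0)
        df["day"] = 30
        df = df[df["sex"] == "female"]  # single sex: prediction = year mean
        series = cm.standardise_by_day(
            cm.ModelSpec("mass", ("Year",)), df, fixed_day_effect=0.04,
            reference_day=30,
        )
        raw = df.groupby("year")["mass_kg"].mean()
        for yr, m in zip(series.years, series.means):
            assert m == pytest.approx(raw.loc[yr], abs=1e-8)

    def test_late_survey_year_corrected_by_day_offset(self):
        # one year measured 10 days late with a true 0.04 kg/day effect:
        # its raw mean exceeds the standardised mean by ~0.4 kg
        df = make_records(seed=12, n=200 * 6, n_years=6, colony_effects=(0.0,),
                          day_effect=0.04, noise_sd=0.3)
        late = df["year"] == 2003
        df.loc[late, "day"] = df.loc[late, "day"] + 10
        df.loc[late, "mass_kg"] = df.loc[late, "mass_kg"] + 0.04 * 10
        series = cm.standardise_by_day(
            cm.ModelSpec("mass", ("Year", "Sex")), df, fixed_day_effect=0.04,
            reference_day=30,
        )
        raw = df.groupby("year")["mass_kg"].mean()
        i = series.years.index(2003)
        # analytic offset: day effect times the realized mean day excess
        expected = 0.04 * (df.loc[late, "day"].mean() - 30)
        assert expected == pytest.approx(0.40, abs=0.08)
        assert raw.loc[2003] - series.means[i] == pytest.approx(expected, abs=0.05)

    def test_zero_day_effect_reduces_to_adjusted_means(self):
        df = make_records(seed=13, n=400, colony_effects=(0.0,))
        a = cm.standardise_by_day(cm.ModelSpec("mass", ("Year", "Sex")), df, 0.0, 30)
        b = cm.standardise_by_day(cm.ModelSpec("mass", ("Year", "Sex")), df, 0.0, 25)
        np.testing.assert_allclose(a.means, b.means, atol=1e-10)

    def test_standardisation_idempotent_at_reference(self):
        df = make_records(seed=14, n=400, colony_effects=(0.0,))
        df["day"] = 30
        once = cm.standardise_by_day(
            cm.ModelSpec("mass", ("Year", "Sex")), df, 0.04, 30
        )
        twice = cm.standardise_by_day(
            cm.ModelSpec("mass", ("Year", "Sex")), df, 0.04, 30
        )
        assert once.means == twice.means

    def test_multi_colony_input_rejected(self):
        df = make_records(seed=15)
        with pytest.raises(ValueError, match="single colony"):
            cm.standardise_by_day(cm.ModelSpec("mass", ("Year",)), df, 0.0, 30)


class TestInterSurveyChange:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ([7.0, 7.0, 7.0], [0.0, 0.0]),
            ([8.0, 6.4], [-20.0]),
            ([6.0, 7.2, 6.48], [20.0, -10.0]),
        ],
    )
    def test_values(self, means, expected):
        assert cm.inter_survey_change(means) == pytest.approx(expected)

    def test_requires_two_surveys_and_positive_means(self):
        with pytest.raises(ValueError):
            cm.inter_survey_change([7.0])
        with pytest.raises(ValueError):
            cm.inter_survey_change([0.0, 5.0])


class TestCorrelation:
    @pytest.mark.parametrize(
        "x,y,expected_r",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_pearson_values(self, x, y, expected_r):
        out = cm.mass_abundance_correlation(x, y)
        assert out["r"] == pytest.approx(expected_r, abs=1e-9)
        assert 0 <= out["p"] <= 1
        assert out["n"] == len(x)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            cm.mass_abundance_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            cm.mass_abundance_correlation([1, 2], [1, 2])

    def test_pairing_uses_previous_survey_difference(self):
        mass = {2018: 7.0, 2020: 6.5, 2023: 6.0, 2025: 6.8}
        abund = {2018: 900, 2020: 1000, 2023: 640, 2025: 560}
        m, d, years = cm.pair_mass_with_abundance_change(mass, abund)
        assert years == [2020, 2023, 2025]
        np.testing.assert_allclose(d, [100, -360, -80])
        np.testing.assert_allclose(m, [6.5, 6.0, 6.8])

    def test_consistent_shuffle_leaves_r_unchanged_inconsistent_destroys_it(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=24)
        y = x + rng.normal(0, 0.5, 24)
        r0 = cm.mass_abundance_correlation(x, y)["r"]
        perm = rng.permutation(24)
        r_joint = cm.mass_abundance_correlation(x[perm], y[perm])["r"]
        assert r_joint == pytest.approx(r0, abs=1e-12)
        rs = []
        for _ in range(500):
            p = rng.permutation(24)
            rs.append(cm.mass_abundance_correlation(x, y[p])["r"])
        assert abs(np.mean(rs)) < 0.2
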