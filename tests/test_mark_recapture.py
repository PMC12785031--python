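"""Chapman/Petersen estimation, SE oracle, and percent-change arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pupmonitor import mark_recapture as mr
from pupmonitor import synthetic_data as sd


def session(pis=None, replicates=None, marked=500, colony="c", year=2000):
    if replicates is None:
        # build replicates whose Chapman estimates equal the requested pis:
        # with Ri = 0, Pi = (M+1)(Ci+1) - 1 -> choose M = 0 so Pi = Ci
        replicates = tuple((int(p), 0) for p in pis)
        marked = 0
    return mr.RecaptureSession(colony, year, marked, tuple(replicates))


class TestPetersenReplicate:
    @pytest.mark.parametrize(
        "m,c,r,expected",
        [
            (10, 10, 10, 10.0),  # every counted pup marked -> estimate = M
            (50, 20, 0, 1070.0),  # finite despite zero resightings
            (100, 50, 25, 197.1154),  # 101*51/26 - 1
        ],
    )
    def test_values(self, m, c, r, expected):
        assert mr.petersen_replicate(m, c, r) == pytest.approx(expected, abs=1e-4)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            mr.petersen_replicate(10, 50, 20)  # more marked seen than marked
        with pytest.raises(ValueError, match="inconsistent"):
            mr.petersen_replicate(100, 10, 20)  # more marked seen than counted
        with pytest.raises(ValueError):
            mr.petersen_replicate(-1, 10, 5)


class TestPetersenMean:
    def test_mean_se_and_normal_ci(self):
        est = mr.petersen_mean(session(pis=[100, 110, 120]), ci_method="normal")
        assert est.mean_estimate == pytest.approx(110.0)
        assert est.se == pytest.approx(5.7735, abs=1e-3)
        assert est.ci_lower == pytest.approx(98.68, abs=0.01)
        assert est.ci_upper == pytest.approx(121.32, abs=0.01)

    def test_default_t_interval_is_wider_than_normal(self):
        t_est = mr.petersen_mean(session(pis=[100, 110, 120]))
        z_est = mr.petersen_mean(session(pis=[100, 110, 120]), ci_method="normal")
        assert t_est.ci_lower < z_est.ci_lower < z_est.ci_upper < t_est.ci_upper

    def test_identical_replicates_have_zero_se(self):
        est = mr.petersen_mean(session(pis=[200] * 5))
        assert est.mean_estimate == 200.0
        assert est.se == 0.0

    def test_single_replicate_has_no_se_or_ci(self):
        est = mr.petersen_mean(session(pis=[150]))
        assert est.mean_estimate == 150.0
        assert est.se is None and est.ci_lower is None and est.ci_upper is None

    def test_empty_replicate_list_is_an_error(self):
        with pytest.raises(ValueError, match="at least one replicate"):
            mr.RecaptureSession("c", 2000, 10, ())

    @given(
        st.lists(st.integers(min_value=0, max_value=5000), min_size=2, max_size=12)
    )
    def test_se_equals_sample_sd_over_sqrt_q(self, cis):
        """The printed SE formula is algebraically sd(Pi)/sqrt(Q)."""
        est = mr.petersen_mean(session(pis=cis))
        oracle = np.std(est.replicate_estimates, ddof=1) / math.sqrt(len(cis))
        assert est.se == pytest.approx(oracle, abs=1e-10)

    def test_mean_is_mean_of_replicate_estimates(self):
        s = mr.RecaptureSession("c", 2000, 100, ((50, 20), (60, 25), (40, 10)))
        est = mr.petersen_mean(s)
        pis = [mr.petersen_replicate(100, c, r) for c, r in s.replicates]
        assert est.mean_estimate == pytest.approx(np.mean(pis))
        assert est.ci_lower <= est.mean_estimate <= est.ci_upper


def test_estimator_near_unbiased_in_chapman_regime():
    """Hypergeometric resampling: mean Chapman estimate within 2% of true N
    when M*Ci is comfortably above 4N."""
    n_true, m, ci = 1000, 500, 300
    rng = np.random.default_rng(42)
    ests = [
        mr.petersen_replicate(m, ci, rng.hypergeometric(m, n_true - m, ci))
        for _ in range(1500)
    ]
    assert np.mean(ests) == pytest.approx(n_true, rel=0.02)


class TestDeadPupFraction:
    @pytest.mark.parametrize(
        "dead,live,expected",
        [(100, 900, 10.0), (0, 500, 0.0), (37, 248, 12.982)],
    )
    def test_values(self, dead, live, expected):
        assert mr.dead_pup_fraction(dead, live) == pytest.approx(expected, abs=1e-3)

    def test_empty_record_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            mr.dead_pup_fraction(0, 0)

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.1, max_value=1e6),
    )
    def test_bounded_and_monotone_in_dead_count(self, dead, live):
        f = mr.dead_pup_fraction(dead, live)
        assert 0.0 <= f <= 100.0
        assert mr.dead_pup_fraction(dead + 1, live) > f


class TestPercentChangeArithmetic:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(916, 566, -38.21), (100, 100, 0.0), (254, 143, -43.70)],
    )
    def test_period_change(self, start, end, expected):
        assert mr.period_percent_change(start, end) == pytest.approx(expected, abs=0.01)

    def test_period_change_rejects_nonpositive_start(self):
        with pytest.raises(ValueError):
            mr.period_percent_change(0, 100)

    @pytest.mark.parametrize(
        "changes,expected",
        [
            ([-78.7, -20.5], -83.07),
            ([-36.0, -38.3], -60.51),
            ([0, 0, 0], 0.0),
        ],
    )
    def test_compound(self, changes, expected):
        assert mr.compound_percent_changes(changes) == pytest.approx(expected, abs=0.01)

    def test_compound_rejects_total_loss(self):
        with pytest.raises(ValueError):
            mr.compound_percent_changes([-100.0])

    @given(
        st.lists(
            st.floats(min_value=-95, max_value=300, allow_nan=False),
            min_size=1,
            max_size=6,
        )
    )
    def test_compound_is_order_invariant_and_identity_on_singletons(self, changes):
        forward = mr.compound_percent_changes(changes)
        backward = mr.compound_percent_changes(list(reversed(changes)))
        assert forward == pytest.approx(backward, rel=1e-9, abs=1e-9)
        assert mr.compound_percent_changes(changes[:1]) == pytest.approx(changes[0])

    @pytest.mark.parametrize(
        "start,end,n,expected",
        [(916, 566, 7, -6.65), (100, 100, 10, 0.0), (100, 50, 1, -50.0)],
    )
    def test_annualized(self, start, end, n, expected):
        assert mr.annualized_percent_change(start, end, n) == pytest.approx(
            expected, abs=0.02
        )

    @given(
        st.floats(min_value=1, max_value=1e5),
        st.floats(min_value=1, max_value=1e5),
    )
    def test_annualized_matches_period_change_over_one_year(self, start, end):
        assert mr.annualized_percent_change(start, end, 1) == pytest.approx(
            mr.period_percent_change(start, end), rel=1e-12, abs=1e-9
        )


class TestSessionTable:
    def test_round_trip_through_csv(self, tmp_path, small_dataset):
        p = tmp_path / "sessions.csv"
        small_dataset.sessions.to_csv(p, index=False)
        sessions = mr.read_sessions_csv(p)
        assert len(sessions) == small_dataset.sessions.groupby(["colony", "year"]).ngroups
        est = mr.estimates_to_frame(mr.estimate_sessions(sessions))
        assert set(est.columns) == {
            "colony", "year", "mean_estimate", "se", "ci_lower", "ci_upper",
            "n_replicates",
        }
        assert (est["ci_lower"] <= est["mean_estimate"]).all()

    def test_invalid_row_names_the_colony_year(self, tmp_path, small_dataset):
        df = small_dataset.sessions.copy()
        df.loc[0, "marked_count"] = df.loc[0, "total_count"] + 5
        df.loc[0, "marked"] = df.loc[0, "marked_count"] + 1
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        name, year = df.loc[0, "colony"], df.loc[0, "year"]
        with pytest.raises(ValueError, match=f"{name} {year}"):
            mr.read_sessions_csv(p)

    def test_missing_column_is_an_error(self, tmp_path):
        p = tmp_path / "short.csv"
        p.write_text("colony,year\na,2000\n")
        with pytest.raises(ValueError, match="missing columns"):
            mr.read_sessions_csv(p)


def test_mortality_join(small_dataset):
    ests = mr.estimate_sessions(mr.sessions_from_frame(small_dataset.sessions))
    recs = mr.mortality_records(small_dataset.dead_counts, ests)
    assert recs
    for m in recs:
        assert 0 <= m.dead_fraction_pct <= 100
        assert m.dead_fraction_pct == pytest.approx(
            mr.dead_pup_fraction(m.dead_count, m.live_estimate)
        )
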