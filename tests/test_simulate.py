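import math

import numpy as np
import pandas as pd
import pytest

from overdx.lifetable import make_gompertz_lifetable
from overdx.netrisk import kaplan_meier_net_risk
from overdx.simulate import (
    TrialSimConfig,
    read_records,
    simulate_trial,
    true_overdiagnosis_fraction,
    write_records,
)


def base_config(**kw):
    defaults = dict(
        n_screen=5_000,
        n_control=5_000,
        incidence_hazard=0.005,
        mortality=make_gompertz_lifetable(0.0008, 0.09, 50, 110),
        seed=123,
        attendance=1.0,
        lead_time_mean=10.0,
        entry_age_dist=60,
        followup_max=15.0,
    )
    defaults.update(kw)
    return TrialSimConfig(**defaults)


class TestMechanism:
    def test_attendance_zero_switches_screening_off(self):
        records = simulate_trial(base_config(attendance=0.0, seed=1))
        assert not records["screen_detected"].any()
        # arms distributionally identical: compare KM at mid follow-up
        cA = kaplan_meier_net_risk(records, "screen")
        cB = kaplan_meier_net_risk(records, "control")
        F_A = np.interp(10, cA.times, cA.F)
        F_B = np.interp(10, cB.times, cB.F)
        se = np.hypot(np.interp(10, cA.times, cA.se), np.interp(10, cB.times, cB.se))
        assert abs(F_A - F_B) < 3 * se

    def test_no_mortality_means_no_overdiagnosis(self):
        records = simulate_trial(
            base_config(mortality=None, followup_max=math.inf, seed=2)
        )
        assert records["screen_detected"].sum() > 0
        assert not records["overdiagnosed_true"].any()

    def test_screen_detection_implies_time_zero_cancer(self):
        records = simulate_trial(base_config(seed=3))
        det = records[records["screen_detected"]]
        assert len(det) > 0
        assert (det["arm"] == "screen").all()
        assert (det["observed_time"] == 0).all()
        assert (det["observed_event"] == "cancer").all()

    def test_observed_time_is_min_of_latents(self):
        records = simulate_trial(base_config(seed=4))
        rest = records[~records["screen_detected"]]
        expected = np.minimum(
            np.minimum(rest["t_clinical"], rest["t_death"]), 15.0
        )
        np.testing.assert_allclose(rest["observed_time"], expected)

    def test_deterministic_given_seed(self):
        a = simulate_trial(base_config(seed=7))
        b = simulate_trial(base_config(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trial(base_config(seed=8))
        assert not a["t_clinical"].equals(c["t_clinical"])

    def test_screen_arm_dominates_control_incidence(self, screening_sim):
        _, records = screening_sim
        cA = kaplan_meier_net_risk(records, "screen")
        cB = kaplan_meier_net_risk(records, "control")
        grid = np.arange(1, 16)
        FA = np.interp(grid, cA.times, cA.F)
        FB = np.interp(grid, cB.times, cB.F)
        assert np.all(FA >= FB - 0.002)

    def test_contamination_raises_control_incidence(self):
        clean = simulate_trial(base_config(seed=9))
        dirty = simulate_trial(base_config(seed=9, contamination_rate=0.3))
        fb_clean = (clean.loc[clean.arm == "control", "observed_event"] == "cancer").mean()
        fb_dirty = (dirty.loc[dirty.arm == "control", "observed_event"] == "cancer").mean()
        assert fb_dirty > fb_clean
        assert not dirty.loc[dirty.arm == "control", "screen_detected"].any()

    def test_age_specific_incidence_accepted(self):
        inc = make_gompertz_lifetable(0.002, 0.05, 50, 110)
        records = simulate_trial(base_config(incidence_hazard=inc, seed=10))
        assert (records["observed_event"] == "cancer").sum() > 0


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_screen=0),
            dict(attendance=1.5),
            dict(incidence_hazard=-0.01),
            dict(incidence_hazard=math.nan),
            dict(lead_time_mean=0.0),
            dict(followup_max=0.0),
            dict(entry_age_dist={60: 0.5, 70: 0.4}),
            dict(contamination_rate=-0.2),
        ],
    )
    def test_bad_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            base_config(**kw)


class TestTrueOverdiagnosisFraction:
    def test_everyone_dies_first(self):
        records = pd.DataFrame(
            {
                "screen_detected": [True] * 4,
                "t_clinical": [2.0, 3.0, 5.0, 9.0],
                "t_death": [0.5] * 4,
            }
        )
        assert true_overdiagnosis_fraction(records) == 1.0

    def test_nobody_dies(self):
        records = pd.DataFrame(
            {
                "screen_detected": [True] * 3,
                "t_clinical": [2.0, 3.0, 5.0],
                "t_death": [math.inf] * 3,
            }
        )
        assert true_overdiagnosis_fraction(records, math.inf) == 0.0

    def test_finite_horizon_counts_unexpired_leads(self):
        # cancer would have presented at year 9; within a 5-year horizon it
        # counts as overdiagnosed even though the man never dies
        records = pd.DataFrame(
            {
                "screen_detected": [True, True],
                "t_clinical": [9.0, 2.0],
                "t_death": [math.inf, math.inf],
            }
        )
        assert true_overdiagnosis_fraction(records, 5.0) == 0.5

    def test_matches_direct_enumeration(self, screening_sim):
        _, records = screening_sim
        det = records[records["screen_detected"]]
        for horizon in (10.0, 15.0, math.inf):
            manual = float(
                np.mean(
                    np.minimum(det["t_death"], horizon) < det["t_clinical"]
                )
            )
            assert true_overdiagnosis_fraction(records, horizon) == pytest.approx(
                manual, abs=1e-12
            )

    def test_no_detections_rejected(self):
        records = pd.DataFrame(
            {"screen_detected": [False], "t_clinical": [1.0], "t_death": [2.0]}
        )
        with pytest.raises(ValueError):
            true_overdiagnosis_fraction(records)

    def test_monotone_in_mortality_scale(self):
        fractions = []
        for b in (0.0004, 0.0008, 0.0016, 0.0032):
            lt = make_gompertz_lifetable(b, 0.09, 50, 110)
            records = simulate_trial(
                base_config(n_screen=20_000, n_control=1, mortality=lt, seed=55)
            )
            fractions.append(true_overdiagnosis_fraction(records, math.inf))
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))


class TestOverdiagnosisOracle:
    def test_screen_detected_fraction_matches_integration(self):
        # lifetime overdiagnosed fraction among screen-detected vs direct
        # numerical integration of P(t_death < t_clinical | t_clinical <= L)
        lt = make_gompertz_lifetable(0.0008, 0.09, 60, 151)
        cfg = base_config(
            n_screen=200_000, n_control=1, mortality=lt, entry_age_dist=60,
            seed=2468, followup_max=20.0,
        )
        records = simulate_trial(cfg)
        frac = true_overdiagnosis_fraction(records, math.inf)

        # oracle: t_clinical ~ Exp(0.005) truncated at the simulator's age
        # ceiling, L ~ Exp(mean 10), death hazard Gompertz from age 60
        lam, mu = 0.005, 10.0
        du = 0.002
        u = np.arange(du / 2, 91, du)
        f_clin = lam * np.exp(-lam * u)
        p_lead = np.exp(-u / mu)
        ages = 60 + u.astype(int)
        h = lt.hazard[np.clip(ages - 60, 0, lt.ages.size - 1)]
        cumh = np.cumsum(h * du)
        p_dead_before = 1 - np.exp(-(cumh - h * du / 2))
        num = np.sum(f_clin * p_lead * p_dead_before) * du
        den = np.sum(f_clin * p_lead) * du
        oracle = num / den

        n_det = int(records["screen_detected"].sum())
        mc_se = math.sqrt(oracle * (1 - oracle) / n_det)
        assert abs(frac - oracle) < 3 * mc_se


class TestIO:
    def test_round_trip_without_oracle(self, tmp_path):
        records = simulate_trial(base_config(n_screen=200, n_control=200, seed=11))
        path = tmp_path / "records.csv"
        write_records(records, path)
        back = read_records(path)
        assert list(back.columns) == [
            "arm", "entry_age", "observed_time", "observed_event", "screen_detected",
        ]
        assert len(back) == 400

    def test_oracle_columns_behind_flag(self, tmp_path):
        records = simulate_trial(base_config(n_screen=50, n_control=50, seed=12))
        path = tmp_path / "records.csv"
        write_records(records, path, oracle=True)
        back = read_records(path)
        assert "t_clinical" in back.columns and "overdiagnosed_true" in back.columns

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"arm": ["screen"], "entry_age": [60]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_records(path)
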