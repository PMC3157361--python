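"""Schedule arithmetic, initialization, unit-scale dynamics, outcome
metrics and the failure/bias analyses."""

import numpy as np
import pytest

from pepvax.simulator import (
    STEPS_PER_YEAR,
    CHANNELS,
    TimeSeries,
    build_schedule,
    classify_outcome,
    failure_profile,
    initialize,
    reactiveness,
    run,
    step,
)
from pepvax.synthetic import synthetic_config


@pytest.fixture(scope="module")
def small_cfg(env):
    """A 2 µl desk configuration used across the dynamic tests."""
    def make(**kw):
        defaults = dict(seed=5, env=env, volume_ul=2.0, initial_cancer=50,
                        duration=60)
        defaults.update(kw)
        return synthetic_config(**defaults)
    return make


class TestSchedule:
    def test_default_schedule(self):
        assert build_schedule() == [0, 84, 168, 252, 336, 420]

    def test_no_boosts(self):
        assert build_schedule(n_boosts=0) == [0]

    def test_daily_interval(self):
        assert build_schedule(n_boosts=3, interval_days=1) == [0, 3, 6, 9]

    def test_year_length(self):
        assert STEPS_PER_YEAR == 1095

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            build_schedule(interval_days=0)


class TestInitialize:
    def test_cancer_count_and_contiguity(self, small_cfg):
        state = initialize(small_cfg(initial_cancer=100))
        cancer = state.agents.where(5)
        assert len(cancer) == 100
        # solid tumor: cells concentrated on few neighboring sites
        assert len(np.unique(state.agents.pos[cancer])) <= 30

    def test_same_seed_same_state(self, small_cfg):
        s1 = initialize(small_cfg(seed=9))
        s2 = initialize(small_cfg(seed=9))
        assert s1.state_hash() == s2.state_hash()

    def test_volume_scales_immune_counts(self, env):
        small = initialize(synthetic_config(seed=1, env=env, volume_ul=2.0))
        big = initialize(synthetic_config(seed=1, env=env, volume_ul=4.0))
        for t in range(5):  # TH..DC
            n_small = len(small.agents.where(t))
            n_big = len(big.agents.where(t))
            assert n_big == pytest.approx(2 * n_small, abs=1)

    def test_lattice_side_from_volume(self, env):
        state = initialize(synthetic_config(seed=1, env=env, volume_ul=5.0))
        assert state.side == 20  # 5 ul x 1600 sites/ul = 8000 = 20^3


class TestStepAndRun:
    def test_duration_zero_gives_initial_series(self, small_cfg):
        ts = run(small_cfg(duration=0))
        assert len(ts) == 1
        assert ts.cancer[0] == 50

    def test_determinism_of_full_series(self, small_cfg):
        a = run(small_cfg(seed=11, duration=40))
        b = run(small_cfg(seed=11, duration=40))
        assert np.array_equal(a.data, b.data)

    def test_counts_and_molecules_nonnegative(self, small_cfg):
        ts = run(small_cfg(duration=60))
        assert (ts.data >= 0).all()

    def test_zero_bias_keeps_immune_baseline_and_tumor_growth(self, small_cfg):
        ts = run(small_cfg(duration=80, ip_bias=0.0))
        assert ts.get("TC_active").max() == 0
        assert ts.get("TH_active").max() == 0
        assert ts.get("B_plasma").max() == 0
        assert np.all(np.diff(ts.cancer) >= 0)

    def test_conservation_ledger_balances(self, small_cfg):
        state = initialize(small_cfg(duration=30))
        for _ in range(30):
            step(state)
        for entry in state.ledger:
            births = sum(entry["births"].values())
            deaths = sum(entry["deaths"].values())
            assert entry["alive_after"] == entry["alive_before"] + births - deaths

    def test_no_adjuvant_recognition_yields_anergy_not_activation(self, small_cfg):
        ts = run(small_cfg(seed=3, duration=150, adjuvant=False))
        assert ts.get("TC_active").max() == 0
        assert ts.get("TH_active").max() == 0

    def test_saturated_recognition_with_adjuvant_eradicates(self, small_cfg):
        ts = run(small_cfg(seed=7, duration=200, ip_bias=1e9))
        assert ts.final_cancer == 0


class TestOutcomeMetrics:
    def _series_with_final(self, final, initial=100, env=None):
        data = np.zeros((2, len(CHANNELS)))
        cancer_col = CHANNELS.index("Cancer_resting")
        data[0, cancer_col] = initial
        data[1, cancer_col] = final
        return TimeSeries(data)

    def test_reactiveness_formula(self):
        treated = self._series_with_final(50)
        untreated = self._series_with_final(200)
        assert reactiveness(treated, untreated) == pytest.approx(75.0)

    def test_reactiveness_eradication_is_100(self):
        assert reactiveness(self._series_with_final(0),
                            self._series_with_final(200)) == 100.0

    def test_reactiveness_no_change_is_0_and_floored(self):
        t = self._series_with_final(200)
        assert reactiveness(t, self._series_with_final(200)) == 0.0
        assert reactiveness(self._series_with_final(300),
                            self._series_with_final(200)) == 0.0

    def test_reactiveness_undefined_for_extinct_untreated(self):
        with pytest.raises(ValueError):
            reactiveness(self._series_with_final(10), self._series_with_final(0))

    @pytest.mark.parametrize("final,expected", [
        (99, "success"), (100, "failure"), (0, "success"), (150, "failure"),
    ])
    def test_classify_outcome(self, final, expected):
        assert classify_outcome(self._series_with_final(final), 100) == expected


class TestFailureProfile:
    def _ts(self, channels_on, final=150):
        data = np.zeros((3, len(CHANNELS)))
        data[:, CHANNELS.index("Cancer_resting")] = [100, 120, final]
        for ch in channels_on:
            data[1, CHANNELS.index(ch)] = 1
        return TimeSeries(data)

    def test_all_successes_give_empty_table_rare_group(self):
        runs = [(self._ts([], final=10), "success")] * 4
        table, group = failure_profile(runs)
        assert table == {}
        assert group == "rare_failures"

    def test_zero_recognition_runs_have_zero_tc_propensity(self):
        runs = [(self._ts(["DC_presenting_I"]), "failure")] * 5
        table, group = failure_profile(runs)
        assert table["TC_active"] == 0.0
        assert table["DC_presenting_I"] == 1.0
        assert group == "frequent_failures"

    def test_propensities_bounded(self):
        runs = [
            (self._ts(["TC_active"]), "failure"),
            (self._ts([]), "failure"),
            (self._ts([], final=10), "success"),
        ]
        table, _ = failure_profile(runs)
        assert all(0.0 <= v <= 1.0 for v in table.values())
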