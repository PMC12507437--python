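"""Response quantification, inclusion testing and tuning-curve slicing."""
import math

import numpy as np
import pytest

import vistune as vt
from vistune.datamodel import TuningCurve
from vistune.synth import B2_TEMPORAL_FREQUENCIES


def grating(direction=0.0, sf=0.1, tf=4.0, contrast=1.0, drift="unidirectional"):
    return vt.StimulusCondition(
        kind="grating", duration=4.0, drift_mode=drift, direction=direction,
        spatial_frequency=sf, temporal_frequency=tf, contrast=contrast,
    )


def trials(rates, cond=None):
    cond = cond or grating()
    return [
        vt.TrialObservation("u", cond, i, rate_mean=float(r))
        for i, r in enumerate(rates)
    ]


class TestMeanResponse:
    @pytest.mark.parametrize(
        "rates, blank, expected",
        [([4, 6], 2.0, 3.0), ([1, 1], 4.0, -3.0), ([5], 5.0, 0.0)],
    )
    def test_blank_subtracted_mean(self, rates, blank, expected):
        assert vt.mean_response(trials(rates), blank) == pytest.approx(expected)

    def test_no_trials_is_an_error(self):
        with pytest.raises(vt.ValidationError):
            vt.mean_response([], 0.0)


class TestF1Response:
    def test_empty_train_gives_zero(self):
        assert vt.f1_response([], 4.0, 4.0) == 0.0

    def test_single_spike_at_zero(self):
        # (2/T) |e^0| with T=1 -> 2 Hz
        assert vt.f1_response([0.0], 1.0, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_modulated_poisson_train_recovers_modulation_depth(self):
        """Spikes from rate 10 + 5 sin(2 pi 4 t): trial-averaged F1 ~ 5 Hz."""
        rng = np.random.default_rng(42)
        T, f, m, a = 4.0, 4.0, 10.0, 5.0
        peak = m + a
        coeffs = []
        for _ in range(200):
            # thinning of a homogeneous Poisson process at the peak rate
            n = rng.poisson(peak * T)
            t = np.sort(rng.uniform(0, T, n))
            keep = rng.uniform(0, peak, n) < m + a * np.sin(2 * np.pi * f * t)
            coeffs.append(vt.f1_complex(t[keep], T, f))
        assert abs(np.mean(coeffs)) == pytest.approx(a, abs=0.5)

    def test_constant_rate_train_has_small_f1(self):
        rng = np.random.default_rng(1)
        coeffs = [
            vt.f1_complex(np.sort(rng.uniform(0, 4.0, rng.poisson(80))), 4.0, 4.0)
            for _ in range(200)
        ]
        assert abs(np.mean(coeffs)) < 0.5


class TestInclusionAnova:
    def test_identical_rates_not_included(self, unit_factory):
        table = {grating(tf=tf): 5.0 for tf in (1.0, 2.0, 4.0)}
        unit = unit_factory(table, blank_rate=5.0)
        res = vt.inclusion_anova(unit, "B2")
        assert res.p_value == pytest.approx(1.0)
        assert not res.included

    def test_single_responsive_condition_included(self, unit_factory):
        table = {grating(tf=tf): 0.0 for tf in (1.0, 2.0, 4.0)}
        table[grating(tf=8.0)] = 50.0
        unit = unit_factory(table, blank_rate=0.0)
        res = vt.inclusion_anova(unit, "B2")
        assert res.included
        assert res.p_value < 1e-10

    def test_condition_with_one_trial_is_an_error(self, unit_factory):
        unit = unit_factory({grating(): 5.0}, n_trials=5)
        lonely = grating(tf=16.0)
        unit.trials.append(vt.TrialObservation("u0", lonely, 0, rate_mean=3.0))
        with pytest.raises(vt.ValidationError, match="2 trials"):
            vt.inclusion_anova(unit, "B2")

    def test_null_type_one_error_is_nominal(self):
        """Poisson null: ~5% of unresponsive units pass the ANOVA at alpha=0.05."""
        rng = np.random.default_rng(2024)
        conds = vt.make_battery("B2")
        n_units, n_rep, rate, T = 300, 7, 5.0, 4.0
        hits = 0
        for u in range(n_units):
            rec = vt.UnitRecord(f"u{u}", "a0", "left", "control")
            for cond in conds:
                for r in range(n_rep):
                    rec.trials.append(
                        vt.TrialObservation(
                            f"u{u}", cond, r,
                            rate_mean=rng.poisson(rate * T) / T,
                        )
                    )
            hits += vt.inclusion_anova(rec, "B2").included
        assert 0.025 <= hits / n_units <= 0.075


class TestChooseModality:
    def curve(self, responses, modality):
        return TuningCurve("direction", [0, 45, 90, 135, 180],
                           responses, np.zeros(5), response_modality=modality)

    def test_larger_mean_wins(self):
        mean = self.curve([8, 0, 0, 0, 0], "mean")
        f1 = self.curve([3, 0, 0, 0, 0], "F1")
        assert vt.choose_modality(mean, f1) is mean

    def test_larger_f1_wins(self):
        mean = self.curve([3, 0, 0, 0, 0], "mean")
        f1 = self.curve([8, 0, 0, 0, 0], "F1")
        assert vt.choose_modality(mean, f1) is f1

    def test_tie_prefers_mean(self):
        mean = self.curve([5, 0, 0, 0, 0], "mean")
        f1 = self.curve([5, 0, 0, 0, 0], "F1")
        assert vt.choose_modality(mean, f1) is mean

    def test_mismatched_grids_rejected(self):
        mean = self.curve([5, 0, 0, 0, 0], "mean")
        f1 = TuningCurve("direction", [0, 45, 90, 135, 270],
                         [5, 0, 0, 0, 0], np.zeros(5), response_modality="F1")
        with pytest.raises(vt.ValidationError):
            vt.choose_modality(mean, f1)


class TestSliceTuning:
    def simulated_unit(self, sf_peak=0.16, pref_direction=90.0, fc=4.0):
        spec = vt.GroupSpec(
            "control", 1, 1,
            parameter_distributions={
                "sf_peak": {"dist": "const", "loc": sf_peak},
                "pref_direction": {"dist": "const", "loc": pref_direction},
                "fc": {"dist": "const", "loc": fc},
                "k": {"dist": "const", "loc": 30.0},
                "background": {"dist": "const", "loc": 2.0},
                "suppression_depth": {"dist": "const", "loc": 0.0},
                "dir_selectivity": {"dist": "const", "loc": 0.2},
                "lpi": {"dist": "const", "loc": 0.2},
            },
            animal_sd={"background": 0.0, "k": 0.0, "lpi": 0.0},
        )
        records, truth = vt.simulate_dataset(
            [spec], batteries=("B1", "B2"), repeats={"B1": 20, "B2": 20}, seed=9
        )
        return records[0], truth.iloc[0]

    def exhaustive_argmax(self, unit, battery, param):
        """Independent oracle: argmax of blank-subtracted means over a raw table."""
        blank = unit.blank_rate(battery)
        by_cond = {}
        for t in unit.trials_for_battery(battery):
            if not t.condition.is_blank:
                by_cond.setdefault(t.condition, []).append(t.rate_mean)
        best, best_val = None, -np.inf
        for cond, rates in by_cond.items():
            v = np.mean(rates) - blank
            if v > best_val:
                best, best_val = cond, v
        return getattr(best, param)

    def test_orientation_curve_sliced_at_preferred_sf(self):
        unit, truth = self.simulated_unit(sf_peak=0.16)
        curve = vt.slice_tuning(unit, "orientation")
        assert list(curve.x_values) == [0.0, 45.0, 90.0, 135.0]
        # the best single condition identifies the same preferred SF
        assert self.exhaustive_argmax(unit, "B1", "spatial_frequency") == pytest.approx(
            0.16
        )

    def test_direction_curve_at_preferred_tf(self):
        unit, truth = self.simulated_unit(fc=4.0)
        curve = vt.slice_tuning(unit, "direction")
        assert len(curve) == 8
        tf_star = self.exhaustive_argmax(unit, "B2", "temporal_frequency")
        tf_curve = vt.slice_tuning(unit, "temporal_frequency")
        assert tf_curve.x_values[np.argmax(tf_curve.responses)] == pytest.approx(tf_star)

    def test_excluded_unit_raises(self, unit_factory):
        table = {grating(tf=tf): 5.0 for tf in B2_TEMPORAL_FREQUENCIES}
        unit = unit_factory(table, blank_rate=5.0)
        with pytest.raises(vt.ValidationError, match="inclusion"):
            vt.slice_tuning(unit, "temporal_frequency")


def test_blank_subtraction_shift_invariance(small_dataset):
    """Adding a constant to every trial rate leaves blank-subtracted curves unchanged."""
    records, _ = small_dataset
    unit = next(
        r for r in records
        if vt.inclusion_anova(r, "B1").included and vt.inclusion_anova(r, "B2").included
    )
    shifted = vt.UnitRecord(unit.unit_id, unit.animal_id, unit.hemisphere, unit.group)
    for t in unit.trials:
        shifted.trials.append(
            vt.TrialObservation(t.unit_id, t.condition, t.trial_index,
                                rate_mean=t.rate_mean + 7.5)
        )
    for target in ("temporal_frequency", "direction", "orientation"):
        a = vt.slice_tuning(unit, target)
        b = vt.slice_tuning(shifted, target)
        np.testing.assert_allclose(a.responses, b.responses, atol=1e-9)
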