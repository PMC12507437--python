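"""Stimulus batteries, generative rate model, and simulator statistics."""
import math

import numpy as np
import pytest
from scipy import stats

import vistune as vt
from vistune import synth
from vistune.synth import (
    B1_CONTRASTS,
    B1_SPATIAL_FREQUENCIES,
    B2_TEMPORAL_FREQUENCIES,
    STIM_DURATION,
)


class TestMakeBattery:
    def test_b1_condition_grid(self):
        conds = vt.make_battery("B1")
        gratings = [c for c in conds if not c.is_blank]
        blanks = [c for c in conds if c.is_blank]
        assert len(gratings) == 4 * 8 * 6 == 192
        assert len(blanks) == 1
        assert {c.direction for c in gratings} == {0.0, 45.0, 90.0, 135.0}
        assert {c.spatial_frequency for c in gratings} == set(B1_SPATIAL_FREQUENCIES)
        assert {c.contrast for c in gratings} == set(B1_CONTRASTS)
        assert all(c.temporal_frequency == 4.0 for c in gratings)
        assert all(c.drift_mode == "back_and_forth" for c in conds)
        assert all(c.duration == STIM_DURATION for c in conds)

    def test_b2_condition_grid(self):
        conds = vt.make_battery("B2")
        gratings = [c for c in conds if not c.is_blank]
        assert len(gratings) == 8 * 7 == 56
        assert sum(c.is_blank for c in conds) == 1
        assert {c.direction for c in gratings} == set(float(d) for d in range(0, 360, 45))
        assert {c.temporal_frequency for c in gratings} == set(B2_TEMPORAL_FREQUENCIES)
        assert all(c.spatial_frequency == 0.1 for c in gratings)
        assert all(c.contrast == 1.0 for c in gratings)
        assert all(c.drift_mode == "unidirectional" for c in conds)

    def test_unknown_battery_rejected(self):
        with pytest.raises(vt.ValidationError):
            vt.make_battery("B3")


class TestExpectedRate:
    def test_blank_returns_background_exactly(self):
        n = vt.GroundTruthNeuron(background=3.7)
        blank = vt.StimulusCondition(kind="blank", duration=4.0)
        assert vt.expected_rate(n, blank) == 3.7

    def test_peak_condition_gives_background_plus_gain(self):
        n = vt.GroundTruthNeuron(k=11.0, background=2.0, suppression_depth=0.0)
        cond = vt.StimulusCondition(
            kind="grating", duration=4.0, drift_mode="unidirectional",
            direction=n.pref_direction, spatial_frequency=n.sf_peak,
            temporal_frequency=vt.tf_peak_frequency(n), contrast=1.0,
        )
        assert vt.expected_rate(n, cond) == pytest.approx(n.background + n.k, rel=1e-9)

    def test_direction_symmetric_when_selectivity_one(self):
        n = vt.GroundTruthNeuron(pref_direction=30.0, dir_selectivity=1.0)
        for tf in (1.0, 8.0):
            a = vt.StimulusCondition(kind="grating", duration=4.0, direction=75.0,
                                     spatial_frequency=0.1, temporal_frequency=tf,
                                     contrast=1.0)
            b = vt.StimulusCondition(kind="grating", duration=4.0, direction=255.0,
                                     spatial_frequency=0.1, temporal_frequency=tf,
                                     contrast=1.0)
            assert vt.expected_rate(n, a) == pytest.approx(vt.expected_rate(n, b), rel=1e-12)

    def test_rate_never_negative_under_deep_suppression(self):
        n = vt.GroundTruthNeuron(background=1.0, suppression_depth=50.0)
        cond = vt.StimulusCondition(kind="grating", duration=4.0, direction=90.0,
                                    spatial_frequency=0.1, temporal_frequency=32.0,
                                    contrast=1.0)
        assert vt.expected_rate(n, cond) == 0.0


class TestSolveFhForLpi:
    @pytest.mark.parametrize("target", [0.1, 0.2, 0.35, 0.6, 0.9])
    def test_solved_fh_reproduces_target(self, target):
        fc = 6.0
        fh = vt.solve_fh_for_lpi(target, fc)
        assert vt.ground_truth_lpi(vt.GroundTruthNeuron(fc=fc, fh=fh)) == pytest.approx(
            target, abs=1e-6
        )


class TestSimulateDataset:
    def test_same_seed_identical_dataset(self, tmp_path):
        specs = [vt.GroupSpec("control", 1, 2)]
        a, _ = vt.simulate_dataset(specs, batteries=("B2",), seed=5)
        b, _ = vt.simulate_dataset(specs, batteries=("B2",), seed=5)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        vt.write_trial_table(a, pa)
        vt.write_trial_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_trial_counts(self):
        specs = [vt.GroupSpec("control", 2, 3), vt.GroupSpec("EO2", 2, 3)]
        records, truth = vt.simulate_dataset(specs, batteries=("B2",), seed=1)
        assert len(records) == 2 * 2 * 3
        assert sum(len(r.trials) for r in records) == 2 * 2 * 3 * (56 + 1) * 7
        assert len(truth) == len(records)

    def test_zero_rate_neuron_yields_all_zero_trials(self):
        spec = vt.GroupSpec(
            "control", 1, 2,
            parameter_distributions={
                "k": {"dist": "const", "loc": 0.0},
                "background": {"dist": "const", "loc": 0.0},
                "suppression_depth": {"dist": "const", "loc": 0.0},
            },
        )
        spec.animal_sd = {"background": 0.0, "k": 0.0, "lpi": 0.0}
        records, _ = vt.simulate_dataset([spec], batteries=("B2",), seed=2)
        rates = [t.rate_mean for r in records for t in r.trials]
        assert max(rates) == 0.0

    def test_poisson_trial_variance_matches_mean_over_duration(self):
        """Pooled dispersion statistic consistent with Poisson counts (alpha=0.01)."""
        spec = vt.GroupSpec("control", 1, 4,
                            parameter_distributions={"background": {"loc": 5.0}})
        records, _ = vt.simulate_dataset([spec], batteries=("B2",), seed=11)
        disp = 0.0
        df = 0
        for rec in records:
            by_cond = {}
            for t in rec.trials:
                by_cond.setdefault(t.condition, []).append(t.rate_mean * STIM_DURATION)
            for counts in by_cond.values():
                counts = np.asarray(counts)
                if counts.mean() > 0:
                    disp += float(((counts - counts.mean()) ** 2).sum() / counts.mean())
                    df += len(counts) - 1
        lo, hi = stats.chi2.ppf([0.005, 0.995], df)
        assert lo < disp < hi


def test_parameter_recovery_through_full_pipeline():
    """High-repeat simulation: fitted fc within 20%, preferred direction within 10 deg."""
    spec = vt.GroupSpec(
        "control", 1, 30,
        parameter_distributions={
            "background": {"dist": "const", "loc": 2.0},
            "dir_selectivity": {"dist": "uniform", "low": 0.0, "high": 0.3},
            "k": {"dist": "const", "loc": 10.0},
            "fc": {"low": 2.0, "high": 12.0},
            "suppression_depth": {"dist": "const", "loc": 0.0},
            "sf_peak": {"dist": "const", "loc": 0.1},
        },
        animal_sd={"background": 0.0, "k": 0.0, "lpi": 0.0},
    )
    records, truth = vt.simulate_dataset([spec], batteries=("B2",), repeats={"B2": 50},
                                         seed=3)
    n_checked = 0
    for rec, (_, row) in zip(records, truth.iterrows()):
        inc = vt.inclusion_anova(rec, "B2")
        assert inc.included
        tf_curve = vt.slice_tuning(rec, "temporal_frequency", inc)
        fit = vt.fit_frequency_curve(tf_curve, "rectified")
        assert fit.fc == pytest.approx(row["fc"], rel=0.20)
        dir_curve = vt.slice_tuning(rec, "direction", inc)
        dg = vt.fit_double_gaussian(dir_curve)
        assert dg.fit_ok
        err = abs((dg.pref_direction - row["pref_direction"] + 180.0) % 360.0 - 180.0)
        assert err <= 10.0
        n_checked += 1
    assert n_checked == 30
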