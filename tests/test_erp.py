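"""ERP pipeline: baseline, rejection, averaging, filtering, windows,
exclusions and contrasts."""

import numpy as np
import pytest

from mmnlab import (
    AdaptationParams,
    NoiseSpec,
    RecordingSpec,
    SequenceSpec,
    generate_sequence,
    simulate_subject,
)
from mmnlab.erp import (
    AmplitudeSummary,
    ComponentWindow,
    ErpAverage,
    ExclusionCriteria,
    PipelineError,
    RejectionPolicy,
    SubjectQC,
    amplitude_ranges,
    apply_exclusions,
    average_erp,
    baseline_correct,
    condition_summaries,
    difference_wave,
    find_peak,
    lowpass_30,
    reject_artifacts,
    window_mean,
)

from conftest import make_epochset


def _erp(data, fs=1024.0, window=(-100.0, 400.0),
         channels=("Fz", "FCz", "Cz")):
    return ErpAverage(
        data=np.asarray(data, dtype=float), n_trials=1, selector={},
        fs_hz=fs, window_ms=window, channels=channels,
    )


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        es = make_epochset(np.full((2, 3, 513), 5.0))
        out = baseline_correct(es)
        assert np.allclose(out.data, 0.0)

    def test_idempotent(self, rng):
        es = make_epochset(rng.normal(size=(4, 3, 513)))
        once = baseline_correct(es)
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_shape_preserved_up_to_offset(self, rng):
        es = make_epochset(rng.normal(size=(3, 2, 513)))
        out = baseline_correct(es)
        diff = es.data - out.data
        # removed part is constant per trial and channel
        assert np.allclose(diff, diff[:, :, :1], atol=1e-12)

    def test_missing_baseline_raises(self, rng):
        es = make_epochset(
            rng.normal(size=(2, 2, 100)), window_ms=(0.0, 97.0)
        )
        with pytest.raises(PipelineError):
            baseline_correct(es)


class TestAmplitudeRanges:
    def test_constant_epoch_has_zero_range(self):
        es = make_epochset(np.full((3, 3, 513), 2.5))
        assert np.allclose(amplitude_ranges(es), 0.0)

    def test_full_cycle_sine_has_range_2a(self, times_ms):
        a = 7.0
        wave = a * np.sin(2 * np.pi * 10.0 * times_ms / 1000.0)  # 10 Hz, 5 cycles
        es = make_epochset(np.tile(wave, (2, 3, 1)))
        assert amplitude_ranges(es) == pytest.approx([2 * a, 2 * a], rel=1e-3)

    def test_invariant_to_baseline_correction(self, rng):
        es = make_epochset(rng.normal(size=(5, 3, 513)))
        before = amplitude_ranges(es)
        after = amplitude_ranges(baseline_correct(es))
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_matches_brute_force(self, rng):
        es = make_epochset(rng.normal(size=(6, 5, 120)))
        fast = amplitude_ranges(es, channels=("Fz", "FCz", "Cz"))
        idx = [0, 1, 2]
        for t in range(6):
            best = max(
                max(es.data[t, c]) - min(es.data[t, c]) for c in idx
            )
            assert abs(fast[t] - best) < 1e-9


class TestRejectArtifacts:
    def test_nothing_rejected_below_fixed_cutoff(self, rng):
        es = make_epochset(rng.normal(scale=5.0, size=(20, 3, 513)))
        kept, log = reject_artifacts(es, RejectionPolicy("fixed_uv", 200.0))
        assert kept[0].n_trials == 20
        assert log["retention"] == 1.0

    def test_injected_outlier_trials_are_rejected(self, rng):
        data = rng.normal(scale=5.0, size=(100, 3, 513))
        bad = [3, 17, 42, 64, 99]
        data[bad, 0, 250] += 500.0
        es = make_epochset(data)
        kept, log = reject_artifacts(
            es, RejectionPolicy("percentile", percentile=95.0)
        )
        kept_idx = {e.trial_index for e in kept[0].events}
        assert set(bad).isdisjoint(kept_idx)
        assert log["n_kept"] == log["n_total"] - len(bad)
        assert log["retention"] == pytest.approx(0.95)

    def test_cutoff_killing_everything_raises(self):
        es = make_epochset(np.tile(np.linspace(0, 300, 513), (4, 3, 1)))
        with pytest.raises(PipelineError):
            reject_artifacts(es, RejectionPolicy("fixed_uv", 1.0))


class TestAverageErp:
    def test_single_trial_identity(self, rng):
        es = make_epochset(rng.normal(size=(1, 3, 513)))
        erp = average_erp(es, role="standard")
        np.testing.assert_array_equal(erp.data, es.data[0])
        assert erp.n_trials == 1

    def test_mean_of_copies_is_the_trial(self, rng):
        trial = rng.normal(size=(3, 513))
        es = make_epochset(np.tile(trial, (5, 1, 1)))
        np.testing.assert_allclose(
            average_erp(es).data, trial, atol=1e-12
        )

    def test_grand_average_is_trial_weighted(self, rng):
        d1 = rng.normal(size=(10, 3, 513))
        d2 = rng.normal(size=(30, 3, 513))
        es1, es2 = make_epochset(d1), make_epochset(d2)
        grand = average_erp([es1, es2])
        manual = (10 * d1.mean(axis=0) + 30 * d2.mean(axis=0)) / 40
        np.testing.assert_allclose(grand.data, manual, atol=1e-12)

    def test_warmup_trials_never_contribute(self, rng):
        data = rng.normal(size=(10, 3, 513))
        roles = ["warmup"] * 3 + ["standard"] * 7
        es = make_epochset(data, roles=roles)
        erp = average_erp(es, role="standard")
        assert erp.n_trials == 7
        np.testing.assert_allclose(
            erp.data, data[3:].mean(axis=0), atol=1e-12
        )

    def test_empty_selection_raises(self, rng):
        es = make_epochset(rng.normal(size=(4, 3, 513)))
        with pytest.raises(PipelineError):
            average_erp(es, role="deviant")


class TestLowpass:
    def test_constant_preserved(self):
        out = lowpass_30(np.full((3, 513), 4.0), fs_hz=1024.0)
        assert np.allclose(out, 4.0)

    def test_passband_and_stopband(self, times_ms):
        t = times_ms / 1000.0
        slow = np.sin(2 * np.pi * 5.0 * t)
        fast = np.sin(2 * np.pi * 100.0 * t)
        out_slow = lowpass_30(slow, fs_hz=1024.0)
        out_fast = lowpass_30(fast, fs_hz=1024.0)
        mid = slice(100, 400)  # avoid filter edges
        assert np.max(np.abs(out_slow[mid])) > 0.99
        assert np.max(np.abs(out_fast[mid])) < 0.10

    def test_zero_phase_keeps_peak_latency(self, times_ms):
        wave = -np.exp(-((times_ms - 93.0) ** 2) / (2 * 16.0**2))
        out = lowpass_30(wave, fs_hz=1024.0)
        assert abs(times_ms[np.argmin(out)] - 93.0) <= 1000.0 / 1024.0


class TestFindPeak:
    def test_gaussian_dip_located(self, times_ms):
        wave = -np.exp(-((times_ms - 93.0) ** 2) / (2 * 16.0**2))
        erp = _erp(np.tile(wave, (3, 1)))
        pk = find_peak(erp, "neg", (50.0, 150.0))
        assert pk.latency_ms == pytest.approx(93.0, abs=1.0)
        assert not pk.at_edge

    def test_tie_breaks_to_earliest(self, times_ms):
        wave = np.zeros_like(times_ms)
        i1 = np.argmin(np.abs(times_ms - 120.0))
        i2 = np.argmin(np.abs(times_ms - 160.0))
        wave[[i1, i2]] = -5.0
        pk = find_peak(_erp(np.tile(wave, (3, 1))), "neg", (100.0, 250.0))
        assert pk.latency_ms == pytest.approx(times_ms[i1])

    def test_monotone_ramp_flags_edge(self, times_ms):
        wave = -times_ms / 100.0
        pk = find_peak(_erp(np.tile(wave, (3, 1))), "neg", (50.0, 150.0))
        assert pk.at_edge


class TestWindowMean:
    def test_constant_wave(self):
        erp = _erp(np.full((3, 513), 2.0))
        assert window_mean(erp, ComponentWindow("N1", 93.0, 15.0)) == 2.0

    def test_antisymmetric_wave_cancels(self, times_ms):
        # window centered on a grid sample; ramp is odd around that center
        center = float(times_ms[np.argmin(np.abs(times_ms - 93.0))])
        wave = times_ms - center
        erp = _erp(np.tile(wave, (3, 1)))
        val = window_mean(erp, ComponentWindow("N1", center, 15.0))
        assert abs(val) < 1e-9

    def test_matches_brute_force(self, rng, times_ms):
        data = rng.normal(size=(3, 513))
        erp = _erp(data)
        win = ComponentWindow("MMN", 140.0, 25.0, channels=("Fz", "Cz"))
        fast = window_mean(erp, win)
        acc, cnt = 0.0, 0
        for ci, ch in enumerate(("Fz", "FCz", "Cz")):
            if ch not in win.channels:
                continue
            for si, t in enumerate(times_ms):
                if 115.0 <= t <= 165.0:
                    acc += data[ci, si]
                    cnt += 1
        assert abs(fast - acc / cnt) < 1e-9

    def test_window_outside_epoch_raises(self):
        erp = _erp(np.zeros((3, 513)))
        with pytest.raises(PipelineError):
            window_mean(erp, ComponentWindow("late", 500.0, 25.0))


class TestDifferenceWave:
    def test_self_difference_is_zero(self, rng):
        a = _erp(rng.normal(size=(3, 513)))
        assert np.allclose(difference_wave(a, a).data, 0.0)

    def test_chain_rule(self, rng):
        a, b, c = (_erp(rng.normal(size=(3, 513))) for _ in range(3))
        lhs = difference_wave(a, b).data + difference_wave(b, c).data
        np.testing.assert_allclose(lhs, difference_wave(a, c).data, atol=1e-12)

    def test_window_mean_is_linear(self, rng):
        a = _erp(rng.normal(size=(3, 513)))
        b = _erp(rng.normal(size=(3, 513)))
        win = ComponentWindow("MMN", 140.0, 25.0)
        assert window_mean(difference_wave(a, b), win) == pytest.approx(
            window_mean(a, win) - window_mean(b, win), abs=1e-12
        )

    def test_grid_mismatch_raises(self, rng):
        a = _erp(rng.normal(size=(3, 513)))
        b = _erp(rng.normal(size=(3, 257)), fs=512.0)
        with pytest.raises(PipelineError):
            difference_wave(a, b)


class TestExclusions:
    @staticmethod
    def _qc(sid, err=1.0, retention=0.9, n1=-1.0, base_sd=0.2):
        return SubjectQC(
            subject_id=sid, max_count_error=err,
            retention={"standard": retention}, std_n1_mean_uv=n1,
            baseline_sd_uv=base_sd,
        )

    def test_identical_behavior_no_outliers(self):
        report = apply_exclusions([self._qc(i, err=2.0) for i in range(5)])
        assert not report.flags["behavior_outlier"].any()

    def test_clear_behavioral_outlier_flagged(self):
        qc = [self._qc(i, err=1.0) for i in range(9)] + [self._qc(9, err=15.0)]
        report = apply_exclusions(qc)
        assert report.flags.loc[9, "behavior_outlier"]
        assert report.flags["behavior_outlier"].sum() == 1

    def test_low_retention_flagged_at_65_percent(self):
        qc = [self._qc(0, retention=0.65), self._qc(1, retention=0.75)]
        report = apply_exclusions(qc)
        assert report.flags.loc[0, "low_retention"]
        assert not report.flags.loc[1, "low_retention"]

    def test_absent_n1_subject_flagged(self):
        """A subject simulated with zero N1 leaves only the slow positivity
        in the N1 window, which trips the automated proxy."""
        seqs = {"oddball": generate_sequence("oddball", SequenceSpec(seed=2))}
        rec = RecordingSpec(fs_hz=256.0)
        adapt = AdaptationParams(base_n1_uv=0.0)
        eps = simulate_subject(
            seqs, rec, adapt=adapt, noise=NoiseSpec(sd_uv=0.0), seed=0
        )
        erp = average_erp(baseline_correct(eps[0]), role="standard")
        n1 = window_mean(erp, ComponentWindow("N1", 93.0, 15.0))
        qc = [
            self._qc(0, n1=n1, base_sd=0.0),
            self._qc(1, n1=-0.5, base_sd=0.0),
        ]
        report = apply_exclusions(qc)
        assert report.flags.loc[0, "no_n1"]
        assert not report.flags.loc[1, "no_n1"]
        assert report.included == [1]


class TestConditionSummaries:
    def _summary(self, rng) -> AmplitudeSummary:
        windows = {
            "N1": ComponentWindow("N1", 93.0, 15.0),
            "MMN": ComponentWindow("MMN", 140.0, 25.0),
        }
        erps = {}
        for sid in range(4):
            erps[sid] = {
                label: _erp(rng.normal(size=(3, 513)))
                for label in ("standard", "deviant", "cascade", "norep")
            }
        return condition_summaries(erps, windows)

    def test_contrast_identity_per_subject(self, rng):
        s = self._summary(rng)
        c = s.contrasts.set_index("contrast")
        lhs = (
            c.loc["norep_corrected_mmn", "mean"]
            - c.loc["cascade_corrected_mmn", "mean"]
        )
        assert lhs == pytest.approx(c.loc["mmn_condition_diff", "mean"], abs=1e-12)

    def test_ci_uses_t_critical_value(self, rng):
        from scipy import stats as sps

        s = self._summary(rng)
        row = s.contrasts.set_index("contrast").loc["oddball_mmn"]
        half = row["ci_high"] - row["mean"]
        assert half == pytest.approx(
            sps.t.ppf(0.975, 3) * row["se"], rel=1e-9
        )

    def test_effect_estimate_roundtrip(self, rng):
        s = self._summary(rng)
        eff = s.effect("mmn_condition_diff")
        row = s.contrasts.set_index("contrast").loc["mmn_condition_diff"]
        assert eff.mean_diff == pytest.approx(row["mean"])
        assert eff.se == pytest.approx(row["se"])
        assert eff.n == 4
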