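"""Synthetic EEG generator: adaptation model, calibration, reproducibility."""

import numpy as np
import pytest

from mmnlab import (
    AdaptationParams,
    ComponentSpec,
    NoiseSpec,
    RecordingSpec,
    SequenceSpec,
    ToneEvent,
    adaptation_gain,
    adaptation_gains,
    default_components,
    generate_sequence,
    load_epochs,
    save_epochs,
    simulate_study,
    simulate_subject,
)
from mmnlab.erp import (
    ComponentWindow,
    average_erp,
    baseline_correct,
    difference_wave,
    window_mean,
)
from mmnlab.workflow import _detect_windows


def _event(freq: float, idx: int = 10) -> ToneEvent:
    return ToneEvent(
        trial_index=idx, onset_ms=idx * 500.0, frequency_hz=freq,
        role="standard", condition="oddball",
    )


def _history(freqs: list[float]) -> list[ToneEvent]:
    return [_event(f, idx=9 - i) for i, f in enumerate(freqs)]


class TestAdaptationGain:
    def test_empty_history_gives_unit_gain(self):
        assert adaptation_gain(_event(500.0), [], AdaptationParams()) == 1.0

    def test_identical_history_reaches_full_adaptation(self):
        params = AdaptationParams(strength=0.4, recency_tau_trials=1e9)
        g = adaptation_gain(
            _event(550.0), _history([550.0] * 8), params
        )
        assert g == pytest.approx(1 - 0.4, abs=1e-9)

    def test_tonotopic_distance_weakens_adaptation(self):
        params = AdaptationParams()
        near = adaptation_gain(_event(500.0), _history([550.0] * 8), params)
        far = adaptation_gain(_event(500.0), _history([732.0] * 8), params)
        assert near < far <= 1.0

    def test_recency_weakens_with_lag(self):
        params = AdaptationParams()
        recent = adaptation_gain(
            _event(500.0), _history([500.0, 732.0, 732.0, 732.0]), params
        )
        distant = adaptation_gain(
            _event(500.0), _history([732.0, 732.0, 732.0, 500.0]), params
        )
        assert recent < distant

    def test_standard_more_adapted_than_norep_control(self):
        """The oddball standard follows identical tones; the no-repetition
        control follows tonotopically distant ones."""
        params = AdaptationParams()
        std = generate_sequence("oddball", SequenceSpec(seed=1))
        nor = generate_sequence("norep", SequenceSpec(seed=1))
        g_std = adaptation_gains(std, params)
        g_nor = adaptation_gains(nor, params)
        std_mean = np.mean(
            [g for g, e in zip(g_std, std.events) if e.role == "standard"]
        )
        nor_mean = np.mean(
            [g for g, e in zip(g_nor, nor.events) if e.role == "control"]
        )
        assert std_mean < nor_mean


def _single_subject_erps(noise_sd=0.0, components=None, adapt=None, seed=5):
    seqs = {
        c: generate_sequence(c, SequenceSpec(seed=seed + i))
        for i, c in enumerate(["oddball", "cascade", "norep"])
    }
    rec = RecordingSpec()
    eps = simulate_subject(
        seqs, rec, components=components, adapt=adapt,
        noise=NoiseSpec(sd_uv=noise_sd), seed=1,
    )
    eps = [baseline_correct(e) for e in eps]
    by = {e.condition: e for e in eps}
    return {
        "standard": average_erp(by["oddball"], role="standard"),
        "deviant": average_erp(by["oddball"], role="deviant"),
        "cascade": average_erp(by["cascade"], role="control"),
        "norep": average_erp(by["norep"], role="control"),
    }


class TestSimulateSubject:
    def test_without_adaptation_controls_are_identical(self):
        """With adaptation off and no noise the 500-Hz tone evokes the same
        response everywhere (MMN removed so only adaptation could
        differentiate the three conditions)."""
        comps = [
            c for c in default_components() if c.name != "MMN"
        ]
        adapt = AdaptationParams(strength=0.0)
        erps = _single_subject_erps(components=comps, adapt=adapt)
        win = ComponentWindow("N1", 93.0, 15.0)
        vals = [
            window_mean(erps[k], win) for k in ("deviant", "cascade", "norep")
        ]
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_calibrated_window_means_match_reference_values(self):
        """Noise-free defaults reproduce the published condition means in
        both pipeline-detected windows, within 0.15 uV."""
        erps = _single_subject_erps()
        windows, _ = _detect_windows({0: erps}, [0])
        expected = {
            ("standard", "N1"): 0.66, ("deviant", "N1"): -0.55,
            ("cascade", "N1"): -0.58, ("norep", "N1"): -0.72,
            ("standard", "MMN"): 1.91, ("deviant", "MMN"): -0.76,
            ("cascade", "MMN"): 0.74, ("norep", "MMN"): 0.76,
        }
        for (label, wname), target in expected.items():
            got = window_mean(erps[label], windows[wname])
            assert got == pytest.approx(target, abs=0.15), (label, wname)

    def test_adaptation_orders_n1_amplitudes(self):
        """Deviant (preceded by near-identical standards) has the weakest
        N1; the no-repetition control the strongest."""
        erps = _single_subject_erps()
        win = ComponentWindow("N1", 93.0, 15.0)
        dev = window_mean(erps["deviant"], win)
        casc = window_mean(erps["cascade"], win)
        nor = window_mean(erps["norep"], win)
        assert dev > casc > nor  # less negative = more adapted

    def test_mastoid_polarity_reversal_of_mmn(self):
        erps = _single_subject_erps()
        diff = difference_wave(erps["deviant"], erps["standard"])
        front = ComponentWindow("MMN", 140.0, 25.0)
        mast = ComponentWindow("MMN", 140.0, 25.0, channels=("M1p", "M2p"))
        assert window_mean(diff, front) < 0 < window_mean(diff, mast)

    def test_linearity_in_component_amplitudes(self):
        """Doubling every amplitude doubles every window mean (noise 0)."""
        base = _single_subject_erps()
        doubled_comps = [
            ComponentSpec(
                name=c.name, center_ms=c.center_ms, width_ms=c.width_ms,
                frontocentral_amp_uv=2 * c.frontocentral_amp_uv,
                mastoid_gain=c.mastoid_gain, width2_ms=c.width2_ms, mix=c.mix,
            )
            for c in default_components()
        ]
        adapt = AdaptationParams(base_n1_uv=-50.0)
        doubled = _single_subject_erps(components=doubled_comps, adapt=adapt)
        win = ComponentWindow("MMN", 140.0, 25.0)
        for label in base:
            assert window_mean(doubled[label], win) == pytest.approx(
                2 * window_mean(base[label], win), abs=1e-9
            )


class TestSimulateStudy:
    SMALL = dict(
        n_subjects=3,
        rec=RecordingSpec(fs_hz=256.0),
        seq_spec=SequenceSpec(n_trials=80),
        n_blocks_per_condition=1,
    )

    def test_same_seed_is_bit_identical(self):
        a = simulate_study(seed=7, **self.SMALL)
        b = simulate_study(seed=7, **self.SMALL)
        for sa, sb in zip(a, b):
            assert sa.max_count_error == sb.max_count_error
            for ea, eb in zip(sa.epoch_sets, sb.epoch_sets):
                np.testing.assert_array_equal(ea.data, eb.data)
                assert ea.events == eb.events

    def test_deterministic_study_has_identical_subjects(self):
        study = simulate_study(
            seed=3, noise=NoiseSpec(sd_uv=0.0), between_subject_sd=0.0,
            share_sequences=True, **self.SMALL,
        )
        ref = study[0].epoch_sets
        for subj in study[1:]:
            for ea, eb in zip(ref, subj.epoch_sets):
                np.testing.assert_array_equal(ea.data, eb.data)

    def test_between_subject_sd_varies_amplitudes(self):
        study = simulate_study(
            seed=3, noise=NoiseSpec(sd_uv=0.0),
            between_subject_sd={"MMN": 1.0}, share_sequences=True,
            **self.SMALL,
        )
        dev_waves = []
        for subj in study:
            odd = [e for e in subj.epoch_sets if e.condition == "oddball"][0]
            mask = odd.trial_mask(role="deviant")
            dev_waves.append(odd.data[mask].mean())
        assert np.std(dev_waves) > 0


class TestEpochIO:
    def test_npz_json_roundtrip(self, tmp_path):
        seqs = {"cascade": generate_sequence("cascade", SequenceSpec(n_trials=16))}
        eps = simulate_subject(
            seqs, RecordingSpec(fs_hz=256.0), noise=NoiseSpec(sd_uv=1.0), seed=4
        )
        save_epochs(eps[0], tmp_path / "block")
        back = load_epochs(tmp_path / "block")
        np.testing.assert_array_equal(back.data, eps[0].data)
        assert back.events == eps[0].events
        assert back.channels == eps[0].channels
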