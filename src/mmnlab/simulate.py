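"""Synthetic multi-subject epoched EEG with an N1 adaptation model.

Each trial's waveform is a sum of three fixed-latency components plus
noise:

* ``baseline_pos`` — a broad slow positivity, identical on every trial.
  It is what lets the heavily adapted standard end up with a *positive*
  mean amplitude in the N1 window, as observed empirically.
* ``N1`` — the auditory N1, a sharp negative peak at 93 ms riding on a
  sustained negativity. Both parts are scaled together by a trialwise
  *adaptation gain*: the more recent and the more tonotopically similar
  the preceding tones, the smaller the gain (neural refractoriness).
* ``MMN`` — the mismatch negativity proper, added only on oddball
  deviant trials, peaking at 140 ms.

Mastoid-proxy channels receive each component multiplied by its (negative)
``mastoid_gain``, producing the polarity reversal expected under a nose
reference.

The adaptation gain for a tone with log2-frequency f following tones
f_1 (most recent), f_2, ... is

    gain = 1 - strength * S,
    S = sum_k w_k * exp(-(f - f_k)^2 / (2 sigma^2)) / sum_k w_k,
    w_k = exp(-k / tau),

so S is a recency-weighted average tonotopic similarity in [0, 1]. An
empty history gives gain 1; an endless run of identical tones gives
gain = 1 - strength.

Default component amplitudes and adaptation parameters were calibrated
(see ``scripts/calibrate.py``) so that the noise-free pipeline reproduces
the reference condition-mean amplitudes in both the N1 and MMN windows:
0.66/-0.55/-0.58/-0.72 uV (N1 window) and 1.91/-0.76/0.74/0.76 uV (MMN
window) for standard/deviant/cascade/no-repetition tones.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .sequences import (
    ROLE_DEVIANT,
    SequenceSpec,
    ToneEvent,
    ToneSequence,
    generate_sequence,
)

__all__ = [
    "RecordingSpec",
    "ComponentSpec",
    "AdaptationParams",
    "NoiseSpec",
    "EpochSet",
    "SubjectSim",
    "default_components",
    "adaptation_gain",
    "adaptation_gains",
    "simulate_subject",
    "simulate_study",
    "save_epochs",
    "load_epochs",
]

FRONTOCENTRAL = ("Fz", "FCz", "Cz")
MASTOID_PROXIES = ("M1p", "M2p")

RING_CONDITIONS = ("one_letter", "six_letter")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RecordingSpec:
    """Sampling grid and montage of the synthetic recording."""

    fs_hz: float = 1024.0
    epoch_window_ms: tuple[float, float] = (-100.0, 400.0)
    channels: tuple[str, ...] = FRONTOCENTRAL + MASTOID_PROXIES
    n_subjects: int = 26
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.epoch_window_ms
        if not (lo < 0.0 < hi):
            raise SimulationError("epoch window must straddle tone onset")
        if self.fs_hz <= 0:
            raise SimulationError("fs_hz must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        k0 = int(round(self.epoch_window_ms[0] / 1000.0 * self.fs_hz))
        k1 = int(round(self.epoch_window_ms[1] / 1000.0 * self.fs_hz))
        return np.arange(k0, k1 + 1) / self.fs_hz * 1000.0

    @property
    def n_samples(self) -> int:
        return len(self.times_ms)


@dataclass(frozen=True)
class ComponentSpec:
    """A fixed-latency ERP component with a (dual-width) Gaussian profile.

    ``shape(t) = (1 - mix) * G(center, width) + mix * G(center, width2)``;
    with ``mix = 0`` this is a plain Gaussian. The dual-width form is used
    for the N1 so a sharp peak and a sustained negativity share one
    adaptation gain.
    """

    name: str
    center_ms: float
    width_ms: float
    frontocentral_amp_uv: float
    mastoid_gain: float = -0.4
    width2_ms: float | None = None
    mix: float = 0.0

    def validate(self) -> None:
        if self.width_ms <= 0:
            raise SimulationError(f"{self.name}: width_ms must be > 0")
        if not 0.0 <= self.mix <= 1.0:
            raise SimulationError(f"{self.name}: mix must be in [0, 1]")
        if self.mix > 0 and (self.width2_ms is None or self.width2_ms <= 0):
            raise SimulationError(f"{self.name}: mix > 0 requires width2_ms > 0")

    def shape(self, times_ms: np.ndarray) -> np.ndarray:
        g1 = np.exp(-((times_ms - self.center_ms) ** 2) / (2 * self.width_ms**2))
        if self.mix == 0.0:
            return g1
        g2 = np.exp(
            -((times_ms - self.center_ms) ** 2) / (2 * self.width2_ms**2)
        )
        return (1.0 - self.mix) * g1 + self.mix * g2


def default_components() -> list[ComponentSpec]:
    """Calibrated default component set (amplitudes in uV)."""
    return [
        ComponentSpec(
            name="baseline_pos",
            center_ms=101.5,
            width_ms=98.8,
            frontocentral_amp_uv=10.0,
            mastoid_gain=-0.2,
        ),
        ComponentSpec(
            name="N1",
            center_ms=93.0,
            width_ms=8.0,
            width2_ms=178.6,
            mix=0.9015,
            frontocentral_amp_uv=-25.0,
            mastoid_gain=-0.4,
        ),
        ComponentSpec(
            name="MMN",
            center_ms=140.0,
            width_ms=25.0,
            frontocentral_amp_uv=-2.304,
            mastoid_gain=-0.5,
        ),
    ]


@dataclass(frozen=True)
class AdaptationParams:
    """Recency- and tonotopy-weighted N1 adaptation.

    ``base_n1_uv`` is the unadapted N1 peak amplitude; at a 500-ms SOA it is
    never observed directly because every analyzed tone is preceded by
    others. ``tonotopic_sd_oct`` is the width (in octaves of log2 frequency
    distance) of the similarity kernel; ``recency_tau_trials`` the
    exponential decay of a predecessor's contribution with its lag.
    """

    base_n1_uv: float = -25.0
    strength: float = 0.2537
    tonotopic_sd_oct: float = 0.1157
    recency_tau_trials: float = 2.091
    history_len: int = 8

    def validate(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise SimulationError("strength must be in [0, 1]")
        if self.tonotopic_sd_oct <= 0 or self.recency_tau_trials <= 0:
            raise SimulationError("kernel widths must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive per-channel noise, white or AR(1) ('pink-ish') in time."""

    sd_uv: float = 8.0
    model: str = "ar1"
    ar1_rho: float = 0.95

    def validate(self) -> None:
        if self.sd_uv < 0:
            raise SimulationError("sd_uv must be >= 0")
        if self.model not in ("white", "ar1"):
            raise SimulationError(f"unknown noise model {self.model!r}")
        if abs(self.ar1_rho) >= 1:
            raise SimulationError("|ar1_rho| must be < 1")


@dataclass
class EpochSet:
    """Trials x channels x samples, with one ToneEvent per trial."""

    data: np.ndarray
    events: list[ToneEvent]
    subject_id: int
    condition: str
    fs_hz: float
    window_ms: tuple[float, float]
    channels: tuple[str, ...]
    ring_condition: str = "one_letter"

    def __post_init__(self) -> None:
        n, c, s = self.data.shape
        if n != len(self.events):
            raise SimulationError("trials and events misaligned")
        if c != len(self.channels):
            raise SimulationError("channel labels and data misaligned")

    @property
    def times_ms(self) -> np.ndarray:
        k0 = int(round(self.window_ms[0] / 1000.0 * self.fs_hz))
        return (k0 + np.arange(self.data.shape[2])) / self.fs_hz * 1000.0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def trial_mask(
        self, role: str | None = None, include_warmup: bool = False
    ) -> np.ndarray:
        mask = np.ones(self.n_trials, dtype=bool)
        if role is not None:
            mask &= np.array([e.role == role for e in self.events])
        if not include_warmup:
            mask &= np.array([not e.is_warmup for e in self.events])
        return mask

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            events=[e for e, m in zip(self.events, mask) if m],
            subject_id=self.subject_id,
            condition=self.condition,
            fs_hz=self.fs_hz,
            window_ms=self.window_ms,
            channels=self.channels,
            ring_condition=self.ring_condition,
        )


def adaptation_gain(
    event: ToneEvent,
    history: Sequence[ToneEvent],
    params: AdaptationParams,
) -> float:
    """Gain in [1 - strength, 1] for one tone given its predecessors.

    ``history`` lists preceding tones most recent first; only the first
    ``history_len`` entries contribute.
    """
    params.validate()
    hist = history[: params.history_len]
    if not hist:
        return 1.0
    lags = np.arange(1, len(hist) + 1, dtype=float)
    w = np.exp(-lags / params.recency_tau_trials)
    d_oct = np.log2(event.frequency_hz) - np.log2(
        np.array([h.frequency_hz for h in hist])
    )
    k = np.exp(-(d_oct**2) / (2 * params.tonotopic_sd_oct**2))
    s = float(np.dot(w, k) / w.sum())
    return 1.0 - params.strength * s


def adaptation_gains(
    seq: ToneSequence, params: AdaptationParams
) -> np.ndarray:
    """Per-event gains over a whole block (warm-up events included, so the
    first analyzed tones already carry realistic adaptation)."""
    events = seq.events
    gains = np.empty(len(events))
    for i, e in enumerate(events):
        gains[i] = adaptation_gain(e, events[i - 1 :: -1] if i else [], params)
    return gains


def _make_noise(
    rng: np.random.Generator, shape: tuple[int, ...], noise: NoiseSpec
) -> np.ndarray:
    if noise.sd_uv == 0:
        return np.zeros(shape)
    if noise.model == "white":
        return rng.standard_normal(shape) * noise.sd_uv
    rho = noise.ar1_rho
    innov_sd = noise.sd_uv * np.sqrt(1.0 - rho**2)
    e = rng.standard_normal(shape) * innov_sd
    e[..., 0] /= np.sqrt(1.0 - rho**2)  # start the AR(1) in its stationary law
    return signal.lfilter([1.0], [1.0, -rho], e, axis=-1)


def _control_effect_amp(
    effect_uv: float, mmn: ComponentSpec, rec: RecordingSpec
) -> float:
    """Peak amplitude of an MMN-shaped extra component whose
    baseline-corrected mean over the nominal MMN window equals
    ``effect_uv``."""
    t = rec.times_ms
    sh = mmn.shape(t)
    base = sh[t < 0].mean()
    win = (t >= mmn.center_ms - 25.0) & (t <= mmn.center_ms + 25.0)
    coef = sh[win].mean() - base
    return effect_uv / coef


def simulate_subject(
    sequences: Mapping[str, Sequence[ToneSequence]] | Mapping[str, ToneSequence],
    rec: RecordingSpec,
    components: Sequence[ComponentSpec] | None = None,
    adapt: AdaptationParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: int = 0,
    control_effect_uv: float = 0.0,
    control_effect_condition: str = "cascade",
) -> list[EpochSet]:
    """Simulate all blocks of one subject.

    ``sequences`` maps condition name to one ToneSequence or a list of them
    (one per block); blocks of a condition are tagged with alternating ring
    conditions. ``control_effect_uv`` injects a genuine condition difference:
    an MMN-shaped deflection added to control-role trials of
    ``control_effect_condition`` whose MMN-window mean equals the requested
    value in uV (positive values make that control more positive).
    """
    rec.validate()
    components = list(components) if components is not None else default_components()
    adapt = adapt if adapt is not None else AdaptationParams()
    noise = noise if noise is not None else NoiseSpec()
    for c in components:
        c.validate()
    noise.validate()
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed

    t = rec.times_ms
    shapes = np.stack([c.shape(t) for c in components])  # (ncomp, nsamp)
    mast_gains = np.array([c.mastoid_gain for c in components])
    amps = np.array([c.frontocentral_amp_uv for c in components])
    names = [c.name for c in components]
    i_n1 = names.index("N1") if "N1" in names else None
    i_mmn = names.index("MMN") if "MMN" in names else None
    if i_n1 is not None and adapt.base_n1_uv is not None:
        amps = amps.copy()
        amps[i_n1] = adapt.base_n1_uv

    mmn_spec = components[i_mmn] if i_mmn is not None else None
    extra_amp = (
        _control_effect_amp(control_effect_uv, mmn_spec, rec)
        if (control_effect_uv and mmn_spec is not None)
        else 0.0
    )

    is_mastoid = np.array([ch in MASTOID_PROXIES for ch in rec.channels])

    out: list[EpochSet] = []
    for cond, seqs in sequences.items():
        if isinstance(seqs, ToneSequence):
            seqs = [seqs]
        for b, seq in enumerate(seqs):
            gains = (
                adaptation_gains(seq, adapt) if i_n1 is not None else None
            )
            n_ev = len(seq.events)
            coef = np.tile(amps, (n_ev, 1))  # (ntrials, ncomp)
            if i_n1 is not None:
                coef[:, i_n1] *= gains
            if i_mmn is not None:
                is_dev = np.array(
                    [e.role == ROLE_DEVIANT for e in seq.events]
                )
                coef[~is_dev, i_mmn] = 0.0
            front = coef @ shapes  # (ntrials, nsamp)
            mast = (coef * mast_gains) @ shapes
            if extra_amp and cond == control_effect_condition:
                is_ctl = np.array(
                    [e.role == "control" for e in seq.events]
                )
                front[is_ctl] += extra_amp * shapes[i_mmn]
                mast[is_ctl] += (
                    extra_amp * mmn_spec.mastoid_gain * shapes[i_mmn]
                )
            data = np.where(
                is_mastoid[None, :, None], mast[:, None, :], front[:, None, :]
            )
            data = data + _make_noise(
                rng, (n_ev, len(rec.channels), len(t)), noise
            )
            out.append(
                EpochSet(
                    data=data,
                    events=list(seq.events),
                    subject_id=subject_id,
                    condition=cond,
                    fs_hz=rec.fs_hz,
                    window_ms=rec.epoch_window_ms,
                    channels=tuple(rec.channels),
                    ring_condition=RING_CONDITIONS[b % len(RING_CONDITIONS)],
                )
            )
    return out


@dataclass
class SubjectSim:
    """One simulated subject: their epoch sets plus behavioral metadata."""

    subject_id: int
    epoch_sets: list[EpochSet]
    max_count_error: float


def simulate_study(
    n_subjects: int = 26,
    rec: RecordingSpec | None = None,
    components: Sequence[ComponentSpec] | None = None,
    adapt: AdaptationParams | None = None,
    noise: NoiseSpec | None = None,
    seq_spec: SequenceSpec | None = None,
    between_subject_sd: Mapping[str, float] | float = 0.0,
    behav_error_mean: float = 1.0,
    behav_error_sd: float = 0.8,
    n_blocks_per_condition: int = 2,
    conditions: Sequence[str] = ("oddball", "cascade", "norep"),
    seed: int = 0,
    control_effect_uv: float = 0.0,
    share_sequences: bool = False,
) -> list[SubjectSim]:
    """Simulate a whole study, reproducible from ``seed``.

    Per-subject component amplitudes are drawn from normal distributions
    around the calibrated group values (``between_subject_sd`` maps
    component name to an SD in uV, or is a single SD applied to all);
    each subject gets fresh tone sequences (or yoked ones with
    ``share_sequences=True``); a per-subject plus-counting error is drawn
    for the behavioral exclusion rule.
    """
    rec = rec if rec is not None else RecordingSpec()
    components = list(components) if components is not None else default_components()
    seq_spec = seq_spec if seq_spec is not None else SequenceSpec()
    if not isinstance(between_subject_sd, Mapping):
        between_subject_sd = {c.name: float(between_subject_sd) for c in components}

    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    study: list[SubjectSim] = []
    for sid, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        comps = [
            replace(
                c,
                frontocentral_amp_uv=rng.normal(
                    c.frontocentral_amp_uv, between_subject_sd.get(c.name, 0.0)
                ),
            )
            for c in components
        ]
        adapt_s = adapt if adapt is not None else AdaptationParams()
        if "N1" in between_subject_sd and between_subject_sd["N1"] > 0:
            n1_amp = [c for c in comps if c.name == "N1"][0].frontocentral_amp_uv
            adapt_s = replace(adapt_s, base_n1_uv=n1_amp)
        seqs: dict[str, list[ToneSequence]] = {}
        seq_rng = (
            np.random.default_rng(seed) if share_sequences else rng
        )
        for cond in conditions:
            seqs[cond] = [
                generate_sequence(
                    cond,
                    replace(seq_spec, seed=int(seq_rng.integers(2**31 - 1))),
                )
                for _ in range(n_blocks_per_condition)
            ]
        epoch_sets = simulate_subject(
            seqs,
            rec,
            comps,
            adapt_s,
            noise,
            seed=rng,
            subject_id=sid,
            control_effect_uv=control_effect_uv,
        )
        max_err = abs(rng.normal(behav_error_mean, behav_error_sd))
        study.append(
            SubjectSim(
                subject_id=sid, epoch_sets=epoch_sets, max_count_error=max_err
            )
        )
    return study


def save_epochs(es: EpochSet, prefix: str | Path) -> None:
    """Persist one EpochSet as <prefix>.npz plus a JSON sidecar with the
    event table embedded as TSV."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), data=es.data)
    seq = ToneSequence(condition=es.condition, events=es.events)
    buf = io.StringIO()
    seq.to_tsv(buf)
    meta = {
        "subject_id": es.subject_id,
        "condition": es.condition,
        "fs_hz": es.fs_hz,
        "window_ms": list(es.window_ms),
        "channels": list(es.channels),
        "ring_condition": es.ring_condition,
        "events_tsv": buf.getvalue(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npz"))["data"]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    seq = ToneSequence.from_tsv(io.StringIO(meta["events_tsv"]))
    return EpochSet(
        data=data,
        events=seq.events,
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        fs_hz=meta["fs_hz"],
        window_ms=tuple(meta["window_ms"]),
        channels=tuple(meta["channels"]),
        ring_condition=meta["ring_condition"],
    )
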