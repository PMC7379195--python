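"""Epochs-to-amplitudes ERP pipeline.

Transforms epoched data into condition ERPs, data-driven N1/MMN windows,
window-mean amplitudes, difference waves and subject exclusion decisions:

1. baseline-correct each epoch with its 100-ms pre-stimulus mean;
2. reject artifact trials by peak-to-peak amplitude range, blind to
   condition (an automated stand-in for per-subject visual cutoffs);
3. average selected trials into ERPs, always excluding warm-up trials;
4. detect the N1 peak (negative, ~93 ms) on the 30-Hz low-passed grand
   mean of oddball standards, and the MMN peak (negative, 100-250 ms) on
   the deviant-minus-standard difference wave — windows are peak +/-15 ms
   (N1) and +/-25 ms (MMN), derived from oddball data only so they cannot
   bias the cascade-vs-norep comparison;
5. extract frontocentral window means per subject and condition and build
   the derived contrasts with their 95% t-based confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .simulate import EpochSet, FRONTOCENTRAL

__all__ = [
    "ErpAverage",
    "ComponentWindow",
    "RejectionPolicy",
    "PeakResult",
    "ExclusionCriteria",
    "SubjectQC",
    "ExclusionReport",
    "AmplitudeSummary",
    "baseline_correct",
    "amplitude_ranges",
    "reject_artifacts",
    "average_erp",
    "lowpass_30",
    "find_peak",
    "window_mean",
    "difference_wave",
    "apply_exclusions",
    "condition_summaries",
]


class PipelineError(ValueError):
    pass


@dataclass
class ErpAverage:
    """Channels x samples mean waveform."""

    data: np.ndarray
    n_trials: int
    selector: dict
    fs_hz: float
    window_ms: tuple[float, float]
    channels: tuple[str, ...]

    @property
    def times_ms(self) -> np.ndarray:
        k0 = int(round(self.window_ms[0] / 1000.0 * self.fs_hz))
        return (k0 + np.arange(self.data.shape[1])) / self.fs_hz * 1000.0

    def channel_mean(self, channels: Sequence[str] | None = None) -> np.ndarray:
        idx = _channel_indices(self.channels, channels)
        return self.data[idx].mean(axis=0)


def _channel_indices(
    available: Sequence[str], wanted: Sequence[str] | None
) -> list[int]:
    if wanted is None:
        return list(range(len(available)))
    idx = [i for i, ch in enumerate(available) if ch in set(wanted)]
    if not idx:
        raise PipelineError(f"none of {wanted} in {available}")
    return idx


@dataclass(frozen=True)
class ComponentWindow:
    """Amplitude-extraction interval: detected center +/- half-width."""

    name: str
    center_ms: float
    half_width_ms: float
    channels: tuple[str, ...] = FRONTOCENTRAL

    def bounds(self) -> tuple[float, float]:
        return (self.center_ms - self.half_width_ms,
                self.center_ms + self.half_width_ms)


@dataclass(frozen=True)
class RejectionPolicy:
    """Amplitude-range artifact rejection.

    ``fixed_uv`` uses ``threshold_uv`` as the cutoff; ``percentile`` uses
    the given upper percentile of the subject's own trial ranges;
    ``capped_percentile`` (default) uses whichever of the two is lower,
    retaining as many trials as possible while trimming outliers.
    """

    mode: str = "capped_percentile"
    threshold_uv: float = 200.0
    percentile: float = 99.0

    def validate(self) -> None:
        if self.mode not in ("fixed_uv", "percentile", "capped_percentile"):
            raise PipelineError(f"unknown rejection mode {self.mode!r}")
        if self.threshold_uv <= 0:
            raise PipelineError("threshold_uv must be > 0")

    def cutoff(self, ranges: np.ndarray) -> float:
        if self.mode == "fixed_uv":
            return self.threshold_uv
        pct = float(np.percentile(ranges, self.percentile))
        if self.mode == "percentile":
            return pct
        return min(pct, self.threshold_uv)


def baseline_correct(es: EpochSet) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus interval
    [-100, 0) ms. Idempotent."""
    t = es.times_ms
    base = (t >= -100.0) & (t < 0.0)
    if not base.any() or t[0] > -100.0 + 1000.0 / es.fs_hz:
        raise PipelineError("epoch window does not cover [-100, 0) ms")
    corrected = es.data - es.data[:, :, base].mean(axis=2, keepdims=True)
    out = EpochSet(
        data=corrected,
        events=list(es.events),
        subject_id=es.subject_id,
        condition=es.condition,
        fs_hz=es.fs_hz,
        window_ms=es.window_ms,
        channels=es.channels,
        ring_condition=es.ring_condition,
    )
    return out


def amplitude_ranges(
    es: EpochSet, channels: Sequence[str] | None = FRONTOCENTRAL
) -> np.ndarray:
    """Per-trial amplitude range: max minus min over samples, maximized
    across the stated channels."""
    idx = _channel_indices(es.channels, channels)
    d = es.data[:, idx, :]
    return (d.max(axis=2) - d.min(axis=2)).max(axis=1)


def reject_artifacts(
    epoch_sets: Sequence[EpochSet] | EpochSet,
    policy: RejectionPolicy | None = None,
    channels: Sequence[str] | None = FRONTOCENTRAL,
) -> tuple[list[EpochSet], dict]:
    """Drop trials whose amplitude range exceeds the policy cutoff.

    The cutoff is computed once from the pooled ranges of all given epoch
    sets (a subject's whole session), blind to trial condition/role.
    Returns the kept epoch sets and a log with the cutoff and per-condition
    retention counts.
    """
    policy = policy if policy is not None else RejectionPolicy()
    policy.validate()
    sets = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    ranges = [amplitude_ranges(es, channels) for es in sets]
    pooled = np.concatenate(ranges)
    cutoff = policy.cutoff(pooled)
    kept_sets: list[EpochSet] = []
    log: dict = {"cutoff_uv": float(cutoff), "per_set": []}
    n_total = n_kept = 0
    for es, r in zip(sets, ranges):
        keep = r <= cutoff
        if not keep.any():
            raise PipelineError("rejection cutoff removed all trials")
        kept_sets.append(es.subset(keep))
        n_total += len(keep)
        n_kept += int(keep.sum())
        log["per_set"].append(
            {
                "condition": es.condition,
                "ring_condition": es.ring_condition,
                "n_total": int(len(keep)),
                "n_kept": int(keep.sum()),
            }
        )
    log["n_total"] = n_total
    log["n_kept"] = n_kept
    log["retention"] = n_kept / n_total
    return kept_sets, log


def average_erp(
    epoch_sets: Sequence[EpochSet] | EpochSet,
    role: str | None = None,
    condition: str | None = None,
) -> ErpAverage:
    """Pointwise mean waveform over selected trials.

    Warm-up trials are always excluded. Trials may come from several epoch
    sets (blocks, ring conditions, subjects); the result is the plain mean
    over all selected trials, so it equals the trial-count-weighted
    combination of per-set averages.
    """
    sets = [epoch_sets] if isinstance(epoch_sets, EpochSet) else list(epoch_sets)
    chunks = []
    ref = None
    for es in sets:
        if condition is not None and es.condition != condition:
            continue
        if ref is None:
            ref = es
        mask = es.trial_mask(role=role)
        if mask.any():
            chunks.append(es.data[mask])
    if not chunks:
        raise PipelineError(
            f"no trials match role={role!r} condition={condition!r}"
        )
    stacked = np.concatenate(chunks, axis=0)
    return ErpAverage(
        data=stacked.mean(axis=0),
        n_trials=stacked.shape[0],
        selector={"role": role, "condition": condition},
        fs_hz=ref.fs_hz,
        window_ms=ref.window_ms,
        channels=ref.channels,
    )


def lowpass_30(
    waveform: ErpAverage | np.ndarray,
    fs_hz: float | None = None,
    cutoff_hz: float = 30.0,
    order: int = 4,
):
    """Zero-phase Butterworth low-pass (applied forward and backward).

    Used for peak identification and display; window means are extracted
    from unfiltered averages.
    """
    if isinstance(waveform, ErpAverage):
        fs = waveform.fs_hz
        filtered = lowpass_30(waveform.data, fs, cutoff_hz, order)
        return ErpAverage(
            data=filtered,
            n_trials=waveform.n_trials,
            selector=dict(waveform.selector, lowpass_hz=cutoff_hz),
            fs_hz=fs,
            window_ms=waveform.window_ms,
            channels=waveform.channels,
        )
    if fs_hz is None:
        raise PipelineError("fs_hz required for array input")
    if fs_hz <= 2 * cutoff_hz:
        raise PipelineError("sampling rate too low for the requested cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float), axis=-1)


@dataclass(frozen=True)
class PeakResult:
    latency_ms: float
    amplitude_uv: float
    at_edge: bool


def find_peak(
    erp: ErpAverage,
    polarity: str = "neg",
    search_window_ms: tuple[float, float] = (50.0, 150.0),
    channels: Sequence[str] | None = FRONTOCENTRAL,
) -> PeakResult:
    """Latency of the extremum of the channel-averaged waveform within the
    search window. Ties break to the earliest sample; an extremum on the
    window edge is flagged (peak not bracketed)."""
    wave = erp.channel_mean(channels)
    t = erp.times_ms
    mask = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    if not mask.any():
        raise PipelineError("search window outside the epoch")
    seg = wave[mask]
    tseg = t[mask]
    i = int(np.argmin(seg) if polarity == "neg" else np.argmax(seg))
    return PeakResult(
        latency_ms=float(tseg[i]),
        amplitude_uv=float(seg[i]),
        at_edge=(i == 0 or i == len(seg) - 1),
    )


def window_mean(erp: ErpAverage, window: ComponentWindow) -> float:
    """Mean amplitude over the window's channels and samples, bounds
    inclusive on the sample grid."""
    lo, hi = window.bounds()
    t = erp.times_ms
    if lo < t[0] or hi > t[-1]:
        raise PipelineError(f"window {window.name} outside the epoch")
    idx = _channel_indices(erp.channels, window.channels)
    mask = (t >= lo) & (t <= hi)
    return float(erp.data[np.ix_(idx, np.flatnonzero(mask))].mean())


def difference_wave(a: ErpAverage, b: ErpAverage) -> ErpAverage:
    """Pointwise a - b on identical grids and channels."""
    if a.data.shape != b.data.shape or a.channels != b.channels:
        raise PipelineError("grid/channel mismatch in difference wave")
    if a.fs_hz != b.fs_hz or a.window_ms != b.window_ms:
        raise PipelineError("time grid mismatch in difference wave")
    return ErpAverage(
        data=a.data - b.data,
        n_trials=min(a.n_trials, b.n_trials),
        selector={"difference": (a.selector, b.selector)},
        fs_hz=a.fs_hz,
        window_ms=a.window_ms,
        channels=a.channels,
    )


# ---------------------------------------------------------------------------
# subject exclusion


@dataclass(frozen=True)
class ExclusionCriteria:
    """Automated analogues of the study's subject-exclusion rules.

    ``behavior_sd``: a subject is a behavioral outlier when their maximum
    plus-count error is strictly greater than the across-subject mean plus
    this many SDs. ``min_retention``: minimum fraction of trials surviving
    artifact rejection for every primary ERP. The N1-absence rule is an
    automated proxy: flag when the standard-trial N1-window mean is more
    positive than ``max(n1_z * baseline_sd, n1_floor_uv)`` — an absent N1
    leaves only the slow positivity in the window.
    """

    behavior_sd: float = 2.0
    min_retention: float = 0.70
    n1_z: float = 6.0
    n1_floor_uv: float = 1.5


@dataclass
class SubjectQC:
    """Per-subject quantities feeding the exclusion rules."""

    subject_id: int
    max_count_error: float
    retention: Mapping[str, float]
    std_n1_mean_uv: float
    baseline_sd_uv: float


@dataclass
class ExclusionReport:
    flags: pd.DataFrame  # one row per subject
    criteria: ExclusionCriteria

    @property
    def included(self) -> list[int]:
        keep = ~self.flags[["behavior_outlier", "no_n1", "low_retention"]].any(
            axis=1
        )
        return [int(s) for s in self.flags.loc[keep, "subject_id"]]

    @property
    def excluded(self) -> list[int]:
        return [
            int(s)
            for s in self.flags["subject_id"]
            if int(s) not in set(self.included)
        ]


def apply_exclusions(
    qc: Sequence[SubjectQC], criteria: ExclusionCriteria | None = None
) -> ExclusionReport:
    """Evaluate all three exclusion rules across subjects.

    The behavioral rule uses a strict ">": with zero across-subject SD no
    one is excluded.
    """
    criteria = criteria if criteria is not None else ExclusionCriteria()
    errs = np.array([q.max_count_error for q in qc], dtype=float)
    thresh = errs.mean() + criteria.behavior_sd * errs.std(ddof=0)
    rows = []
    for q, err in zip(qc, errs):
        behavior = bool(err > thresh)
        low_ret = bool(
            min(q.retention.values()) < criteria.min_retention
            if q.retention
            else False
        )
        n1_cut = max(criteria.n1_z * q.baseline_sd_uv, criteria.n1_floor_uv)
        no_n1 = bool(q.std_n1_mean_uv > n1_cut)
        rows.append(
            {
                "subject_id": q.subject_id,
                "behavior_outlier": behavior,
                "no_n1": no_n1,
                "low_retention": low_ret,
                "retention_fraction": float(min(q.retention.values()))
                if q.retention
                else 1.0,
                "max_count_error": float(err),
            }
        )
    return ExclusionReport(flags=pd.DataFrame(rows), criteria=criteria)


# ---------------------------------------------------------------------------
# condition summaries

CONDITION_LABELS = ("standard", "deviant", "cascade", "norep")

CONTRASTS: dict[str, tuple[str, str, str]] = {
    # name: (window, minuend label, subtrahend label)
    "oddball_mmn": ("MMN", "deviant", "standard"),
    "cascade_corrected_mmn": ("MMN", "deviant", "cascade"),
    "norep_corrected_mmn": ("MMN", "deviant", "norep"),
    "mmn_condition_diff": ("MMN", "cascade", "norep"),
    "n1_cascade_minus_norep": ("N1", "cascade", "norep"),
}


@dataclass
class AmplitudeSummary:
    """Per-subject window means and group-level contrasts."""

    per_subject: pd.DataFrame  # subject_id, label, window, mean_uv
    contrasts: pd.DataFrame  # contrast, mean, se, ci_low, ci_high, n
    windows: dict[str, ComponentWindow]

    def effect(self, contrast: str):
        from .bayes import EffectEstimate

        row = self.contrasts.set_index("contrast").loc[contrast]
        return EffectEstimate(
            mean_diff=float(row["mean"]),
            se=float(row["se"]) if row["se"] > 0 else None,
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            n=int(row["n"]),
        )

    def group_mean(self, label: str, window: str) -> float:
        df = self.per_subject
        sel = (df["label"] == label) & (df["window"] == window)
        return float(df.loc[sel, "mean_uv"].mean())


def _group_ci(values: np.ndarray) -> tuple[float, float, float, float]:
    n = len(values)
    m = float(values.mean())
    if n < 2:
        return m, 0.0, m, m
    se = float(values.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    return m, se, m - tcrit * se, m + tcrit * se


def condition_summaries(
    subject_erps: Mapping[int, Mapping[str, ErpAverage]],
    windows: Mapping[str, ComponentWindow],
) -> AmplitudeSummary:
    """Window means per subject and condition-role, plus derived contrasts.

    ``subject_erps`` maps subject id to a mapping with keys 'standard',
    'deviant' (oddball trials) and 'cascade', 'norep' (control-tone
    trials). ``windows`` must contain 'N1' and 'MMN' ComponentWindows,
    defined beforehand from oddball data only.

    By construction the contrasts satisfy, subject by subject,
    (deviant - norep) - (deviant - cascade) = cascade - norep.
    """
    rows = []
    for sid, erps in subject_erps.items():
        for label in CONDITION_LABELS:
            if label not in erps:
                raise PipelineError(f"subject {sid} missing {label!r} ERP")
            for wname, win in windows.items():
                rows.append(
                    {
                        "subject_id": sid,
                        "label": label,
                        "window": wname,
                        "mean_uv": window_mean(erps[label], win),
                    }
                )
    per_subject = pd.DataFrame(rows)

    wide = per_subject.pivot_table(
        index="subject_id", columns=["window", "label"], values="mean_uv"
    )
    crows = []
    for cname, (wname, a, b) in CONTRASTS.items():
        vals = (wide[(wname, a)] - wide[(wname, b)]).to_numpy()
        m, se, lo, hi = _group_ci(vals)
        crows.append(
            {"contrast": cname, "mean": m, "se": se, "ci_low": lo,
             "ci_high": hi, "n": len(vals)}
        )
    # oddball MMN vs the norep-corrected MMN (attenuation of the raw MMN)
    vals = (
        (wide[("MMN", "deviant")] - wide[("MMN", "standard")])
        - (wide[("MMN", "deviant")] - wide[("MMN", "norep")])
    ).to_numpy()
    m, se, lo, hi = _group_ci(vals)
    crows.append(
        {"contrast": "oddball_vs_norep_mmn", "mean": m, "se": se,
         "ci_low": lo, "ci_high": hi, "n": len(vals)}
    )
    contrasts = pd.DataFrame(crows)
    return AmplitudeSummary(
        per_subject=per_subject, contrasts=contrasts, windows=dict(windows)
    )
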