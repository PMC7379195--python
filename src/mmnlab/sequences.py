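"""Tone-sequence generation for oddball, cascade and no-repetition blocks.

Three block types are generated over a five-tone frequency ladder
(500, 550, 605, 666, 732 Hz by default):

* **oddball** — a rare deviant (the lowest tone, 1/8 of trials) embedded in
  a stream of standards (the second tone), with the number of standards
  between successive deviants drawn from a discretized truncated normal
  distribution (mean 7, SD 2, support 3..11).
* **cascade** — the deterministic up-and-down ladder
  500, 550, 605, 666, 732, 666, 605, 550 Hz repeated throughout the block,
  so the 500-Hz control tone is equiprobable (1/8) with the 732-Hz tone and
  no tone ever repeats back to back.
* **norep** (no-repetition) — each 8-tone set is a fresh pseudorandom
  permutation of the cascade multiset, rejected and redrawn until no two
  consecutive tones (within a set, across set boundaries, and at the
  warm-up junction) share a frequency.

Every block starts with warm-up tones that are simulated but excluded from
analysis: seven standards for the oddball block, one set without the
control tone for cascade/norep blocks.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GapDist",
    "SequenceSpec",
    "ToneEvent",
    "ToneSequence",
    "SequenceStats",
    "sample_interdeviant_gaps",
    "make_oddball_sequence",
    "make_cascade_sequence",
    "make_norep_sequence",
    "sequence_stats",
]

ROLE_STANDARD = "standard"
ROLE_DEVIANT = "deviant"
ROLE_CONTROL = "control"
ROLE_OTHER = "other"
ROLE_WARMUP = "warmup"

CONDITIONS = ("oddball", "cascade", "norep")

_TSV_COLUMNS = [
    "trial_index",
    "onset_ms",
    "frequency_hz",
    "role",
    "condition",
    "set_index",
    "is_warmup",
]


class SequenceError(ValueError):
    """Invalid sequence parameters or an exhausted generation budget."""


@dataclass(frozen=True)
class GapDist:
    """Interdeviant-gap distribution: discretized normal truncated to
    [min_gap, max_gap] and renormalized.

    A "gap" is the number of standards presented between two successive
    deviants.
    """

    mean: float = 7.0
    sd: float = 2.0
    min_gap: int = 3
    max_gap: int = 11

    def validate(self) -> None:
        if self.sd <= 0:
            raise SequenceError(f"gap sd must be > 0, got {self.sd}")
        if self.min_gap > self.max_gap:
            raise SequenceError(
                f"gap min {self.min_gap} exceeds max {self.max_gap}"
            )

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer support and renormalized probability masses."""
        self.validate()
        support = np.arange(self.min_gap, self.max_gap + 1)
        mass = np.exp(-((support - self.mean) ** 2) / (2.0 * self.sd**2))
        return support, mass / mass.sum()


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters shared by all three block generators."""

    frequency_ladder: tuple[float, ...] = (500.0, 550.0, 605.0, 666.0, 732.0)
    n_trials: int = 360
    soa_ms: float = 500.0
    tone_dur_ms: float = 100.0
    deviant_index: int = 0
    gap_dist: GapDist = field(default_factory=GapDist)
    n_warmup: int = 7
    seed: int = 0

    def validate(self, condition: str | None = None) -> None:
        ladder = np.asarray(self.frequency_ladder, dtype=float)
        if len(ladder) < 2 or np.any(np.diff(ladder) <= 0):
            raise SequenceError("frequency_ladder must be strictly increasing")
        if not 0 <= self.deviant_index < len(ladder):
            raise SequenceError("deviant_index outside ladder")
        if condition == "oddball":
            g = self.gap_dist
            g.validate()
            if not (3 <= g.min_gap <= g.mean <= g.max_gap):
                raise SequenceError(
                    "oddball gaps require 3 <= min <= mean <= max, got "
                    f"({g.min_gap}, {g.mean}, {g.max_gap})"
                )
            if self.deviant_index + 1 >= len(ladder):
                raise SequenceError("no ladder position left for the standard")
        if condition in ("cascade", "norep"):
            cycle_len = 2 * len(ladder) - 2
            if self.n_trials % cycle_len:
                raise SequenceError(
                    f"n_trials={self.n_trials} not divisible by the "
                    f"{cycle_len}-tone set length"
                )

    @property
    def deviant_hz(self) -> float:
        return float(self.frequency_ladder[self.deviant_index])

    @property
    def standard_hz(self) -> float:
        return float(self.frequency_ladder[self.deviant_index + 1])

    def cycle_positions(self) -> list[int]:
        """Ladder indices of one up-and-down set (length 2L-2)."""
        n = len(self.frequency_ladder)
        return list(range(n)) + list(range(n - 2, 0, -1))


@dataclass(frozen=True)
class ToneEvent:
    trial_index: int
    onset_ms: float
    frequency_hz: float
    role: str
    condition: str
    set_index: int = -1

    @property
    def is_warmup(self) -> bool:
        return self.role == ROLE_WARMUP


@dataclass
class ToneSequence:
    """An ordered block of tone events plus the spec that generated it."""

    condition: str
    events: list[ToneEvent]
    spec: SequenceSpec | None = None

    def __len__(self) -> int:
        return len(self.events)

    @property
    def analyzed_events(self) -> list[ToneEvent]:
        return [e for e in self.events if not e.is_warmup]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency_hz for e in self.events])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "trial_index": e.trial_index,
                "onset_ms": e.onset_ms,
                "frequency_hz": e.frequency_hz,
                "role": e.role,
                "condition": e.condition,
                "set_index": e.set_index,
                "is_warmup": e.is_warmup,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=_TSV_COLUMNS)

    def to_tsv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ToneSequence":
        df = pd.read_csv(path_or_buf, sep="\t")
        events = [
            ToneEvent(
                trial_index=int(r.trial_index),
                onset_ms=float(r.onset_ms),
                frequency_hz=float(r.frequency_hz),
                role=str(r.role),
                condition=str(r.condition),
                set_index=int(r.set_index),
            )
            for r in df.itertuples()
        ]
        condition = events[0].condition if events else "oddball"
        return cls(condition=condition, events=events)


@dataclass
class SequenceStats:
    """Verification counts over a generated block."""

    proportions: dict[float, float]
    n_adjacent_repeats: int
    gap_histogram: dict[int, int] | None = None


def sample_interdeviant_gaps(
    gap_dist: GapDist, n_gaps: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw integer interdeviant gaps from the discretized truncated normal.

    Probability mass at each integer in [min_gap, max_gap] is proportional
    to the normal density there, renormalized over the support, which keeps
    the distribution symmetric about the mean when the bounds are symmetric.
    """
    if n_gaps < 1:
        raise SequenceError("n_gaps must be >= 1")
    support, p = gap_dist.pmf()
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    return rng.choice(support, size=n_gaps, p=p)


def _events_from(
    spec: SequenceSpec,
    condition: str,
    freqs: Sequence[float],
    roles: Sequence[str],
    set_indices: Sequence[int],
) -> ToneSequence:
    events = [
        ToneEvent(
            trial_index=i,
            onset_ms=i * spec.soa_ms,
            frequency_hz=float(f),
            role=r,
            condition=condition,
            set_index=s,
        )
        for i, (f, r, s) in enumerate(zip(freqs, roles, set_indices))
    ]
    return ToneSequence(condition=condition, events=events, spec=spec)


def make_oddball_sequence(spec: SequenceSpec, max_retries: int = 1000) -> ToneSequence:
    """Oddball block: rare deviants in a standard stream.

    Deviants are laid out left to right at cumulative gap positions; the
    full gap vector is redrawn (up to ``max_retries`` times) whenever the
    last deviant does not fit inside the block. The seven warm-up standards
    precede the analyzed trials, so the first deviant always has at least
    ``n_warmup + gap`` standards before it.
    """
    spec.validate("oddball")
    rng = np.random.default_rng(spec.seed)
    n_dev = spec.n_trials // 8
    for _ in range(max_retries):
        gaps = sample_interdeviant_gaps(spec.gap_dist, n_dev, rng)
        positions = np.cumsum(gaps + 1) - 1  # 0-based analyzed indices
        if positions[-1] < spec.n_trials:
            break
    else:
        raise SequenceError(
            f"could not place {n_dev} deviants in {spec.n_trials} trials "
            f"after {max_retries} retries"
        )
    analyzed = np.full(spec.n_trials, spec.standard_hz)
    analyzed[positions] = spec.deviant_hz
    roles = np.full(spec.n_trials, ROLE_STANDARD, dtype=object)
    roles[positions] = ROLE_DEVIANT

    freqs = [spec.standard_hz] * spec.n_warmup + list(analyzed)
    all_roles = [ROLE_WARMUP] * spec.n_warmup + list(roles)
    set_idx = [-1] * len(freqs)
    return _events_from(spec, "oddball", freqs, all_roles, set_idx)


def _control_roles(spec: SequenceSpec, freqs: Iterable[float]) -> list[str]:
    return [
        ROLE_CONTROL if f == spec.deviant_hz else ROLE_OTHER for f in freqs
    ]


def make_cascade_sequence(spec: SequenceSpec) -> ToneSequence:
    """Cascade block: the fixed up-and-down set repeated verbatim."""
    spec.validate("cascade")
    ladder = spec.frequency_ladder
    cycle = [ladder[i] for i in spec.cycle_positions()]
    n_sets = spec.n_trials // len(cycle)
    warm = [f for f in cycle if f != spec.deviant_hz]  # one set, control omitted

    freqs = warm + cycle * n_sets
    roles = [ROLE_WARMUP] * len(warm) + _control_roles(spec, cycle * n_sets)
    set_idx = [-1] * len(warm) + [
        k for k in range(n_sets) for _ in range(len(cycle))
    ]
    return _events_from(spec, "cascade", freqs, roles, set_idx)


def _norep_permutation(
    rng: np.random.Generator,
    items: list[float],
    prev: float | None,
    budget: int,
) -> list[float]:
    """Uniform draw among permutations with no adjacent repeats and first
    element different from ``prev``; rejection sampling."""
    arr = np.asarray(items)
    for _ in range(budget):
        p = rng.permutation(arr)
        if prev is not None and p[0] == prev:
            continue
        if np.any(p[1:] == p[:-1]):
            continue
        return [float(x) for x in p]
    raise SequenceError(
        f"no valid no-repetition permutation found in {budget} draws"
    )


def make_norep_sequence(
    spec: SequenceSpec, rejection_budget: int = 10_000
) -> ToneSequence:
    """No-repetition block: pseudorandomized sets, no consecutive repeats.

    Each analyzed set is a permutation of the cascade multiset; permutations
    are rejection-sampled so the no-repetition rule holds within sets,
    across set boundaries, and at the junction with the warm-up set.
    """
    spec.validate("norep")
    rng = np.random.default_rng(spec.seed)
    ladder = spec.frequency_ladder
    cycle = [float(ladder[i]) for i in spec.cycle_positions()]
    n_sets = spec.n_trials // len(cycle)
    warm_items = [f for f in cycle if f != spec.deviant_hz]

    warm = _norep_permutation(rng, warm_items, None, rejection_budget)
    prev = warm[-1]
    sets: list[list[float]] = []
    for _ in range(n_sets):
        s = _norep_permutation(rng, cycle, prev, rejection_budget)
        sets.append(s)
        prev = s[-1]

    freqs = warm + [f for s in sets for f in s]
    roles = [ROLE_WARMUP] * len(warm) + _control_roles(
        spec, [f for s in sets for f in s]
    )
    set_idx = [-1] * len(warm) + [
        k for k in range(n_sets) for _ in range(len(cycle))
    ]
    return _events_from(spec, "norep", freqs, roles, set_idx)


def sequence_stats(seq: ToneSequence) -> SequenceStats:
    """Exact frequency proportions, adjacent-repeat count and (for oddball)
    the interdeviant-gap histogram.

    Proportions are over analyzed (non-warm-up) events; adjacent repeats are
    counted over the full event list so set boundaries and the warm-up
    junction are included.
    """
    if not seq.events:
        raise SequenceError("empty sequence")
    analyzed = seq.analyzed_events
    counts = Counter(e.frequency_hz for e in analyzed)
    n = len(analyzed)
    proportions = {f: c / n for f, c in sorted(counts.items())}

    freqs = seq.frequencies
    n_rep = int(np.count_nonzero(freqs[1:] == freqs[:-1]))

    gap_hist = None
    if seq.condition == "oddball":
        dev_idx = [
            i for i, e in enumerate(analyzed) if e.role == ROLE_DEVIANT
        ]
        gaps = [b - a - 1 for a, b in zip(dev_idx, dev_idx[1:])]
        gap_hist = dict(sorted(Counter(gaps).items()))
    return SequenceStats(
        proportions=proportions, n_adjacent_repeats=n_rep, gap_histogram=gap_hist
    )


def generate_sequence(condition: str, spec: SequenceSpec) -> ToneSequence:
    """Dispatch on condition name."""
    if condition == "oddball":
        return make_oddball_sequence(spec)
    if condition == "cascade":
        return make_cascade_sequence(spec)
    if condition == "norep":
        return make_norep_sequence(spec)
    raise SequenceError(f"unknown condition {condition!r}")
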