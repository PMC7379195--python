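"""How often do completely random tone orders violate the no-repetition rule?

If a control block presents m distinct tones r times each in a uniformly
random order, some consecutive tones will coincide by chance. The expected
fraction of adjacent pairs that repeat has a closed form: for any adjacent
pair of a uniformly random multiset permutation of N = m*r items,

    P(repeat) = m * r * (r - 1) / (N * (N - 1)),

slightly below the with-replacement value 1/m. For 8 tones x 180
presentations this is ~12.44% — low enough that the auditory system would
likely extract a no-repetition regularity and respond to the chance
repetitions, which is why control sequences enforce the rule explicitly
instead of relying on full randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RepSimSpec",
    "RepSimResult",
    "analytic_repetition_pct",
    "simulate_repetition_pct",
]


class RepSimError(ValueError):
    pass


@dataclass(frozen=True)
class RepSimSpec:
    n_tone_types: int = 8
    reps_per_tone: int = 180
    k_sims: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tone_types, self.reps_per_tone, self.k_sims) < 1:
            raise RepSimError("all counts must be >= 1")
        if self.n_tone_types * self.reps_per_tone < 2:
            raise RepSimError("need at least two tones in the block")


@dataclass(frozen=True)
class RepSimResult:
    mean_pct: float
    sd_pct: float
    analytic_pct: float
    k_sims: int

    @property
    def se_pct(self) -> float:
        return self.sd_pct / np.sqrt(self.k_sims)


def analytic_repetition_pct(n_tone_types: int, reps_per_tone: int) -> float:
    """Expected percentage of adjacent repeats in a uniformly random
    multiset permutation: 100 * m*r*(r-1) / (N*(N-1)) with N = m*r."""
    m, r = n_tone_types, reps_per_tone
    n = m * r
    if m < 1 or r < 1 or n < 2:
        raise RepSimError("need m >= 1, r >= 1 and m*r >= 2")
    return 100.0 * m * r * (r - 1) / (n * (n - 1))


def simulate_repetition_pct(spec: RepSimSpec) -> RepSimResult:
    """Monte-Carlo estimate over k uniformly random block orderings.

    Each simulation permutes the full multiset (every tone exactly r
    times) and counts adjacent equal pairs over the N-1 within-block
    boundaries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    block = np.repeat(np.arange(spec.n_tone_types), spec.reps_per_tone)
    n_pairs = block.size - 1
    pcts = np.empty(spec.k_sims)
    for i in range(spec.k_sims):
        p = rng.permutation(block)
        pcts[i] = 100.0 * np.count_nonzero(p[1:] == p[:-1]) / n_pairs
    return RepSimResult(
        mean_pct=float(pcts.mean()),
        sd_pct=float(pcts.std(ddof=1)) if spec.k_sims > 1 else 0.0,
        analytic_pct=analytic_repetition_pct(
            spec.n_tone_types, spec.reps_per_tone
        ),
        k_sims=spec.k_sims,
    )
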