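import numpy as np
import pytest

from mmnlab import EpochSet, ToneEvent


def make_epochset(
    data: np.ndarray,
    fs_hz: float = 1024.0,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    channels: tuple[str, ...] = ("Fz", "FCz", "Cz", "M1p", "M2p"),
    condition: str = "oddball",
    roles: list[str] | None = None,
) -> EpochSet:
    """Wrap a raw (trials, channels, samples) array in an EpochSet."""
    n = data.shape[0]
    roles = roles if roles is not None else ["standard"] * n
    events = [
        ToneEvent(
            trial_index=i,
            onset_ms=i * 500.0,
            frequency_hz=550.0,
            role=roles[i],
            condition=condition,
        )
        for i in range(n)
    ]
    return EpochSet(
        data=data,
        events=events,
        subject_id=0,
        condition=condition,
        fs_hz=fs_hz,
        window_ms=window_ms,
        channels=channels[: data.shape[1]],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def times_ms():
    fs = 1024.0
    return np.arange(int(-0.1 * fs), int(0.4 * fs) + 1) / fs * 1000.0
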