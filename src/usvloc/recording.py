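"""In-memory container for one synchronized multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MultiChannelRecording:
    """Sample matrix of one microphone set.

    Parameters
    ----------
    data : (n_channels, n_samples) float array. Amplitudes are arbitrary
        linear units (kept O(1) by the simulator's 1/r reference scaling).
    sample_rate : Hz.
    label : which microphone set the channels belong to ("cam64" | "usm4");
        channel k corresponds to row k of that array's mic positions.
    """

    data: np.ndarray
    sample_rate: float
    label: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def slice_seconds(self, t0: float, t1: float) -> np.ndarray:
        """View of the samples in the local-clock interval [t0, t1)."""
        i0 = max(0, int(np.floor(t0 * self.sample_rate)))
        i1 = min(self.n_samples, int(np.ceil(t1 * self.sample_rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{t0}, {t1}) for this recording")
        return self.data[:, i0:i1]
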