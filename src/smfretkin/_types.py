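"""Small shared domain types used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StatePath:
    """Per-frame state indices on the E_FRET time base.

    ``states`` are 0-based state indices, one per donor-excitation frame,
    starting at ``t0`` (seconds) and spaced by ``frame_interval``.
    """

    states: np.ndarray
    frame_interval: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        """Frame-start times (seconds, absolute)."""
        return self.t0 + self.frame_interval * np.arange(len(self.states))

    @property
    def times_since_t0(self) -> np.ndarray:
        return self.frame_interval * np.arange(len(self.states))

    def run_lengths(self) -> list[tuple[int, int]]:
        """Run-length encoding as (state, n_frames) pairs."""
        out: list[tuple[int, int]] = []
        for s in self.states:
            s = int(s)
            if out and out[-1][0] == s:
                out[-1] = (s, out[-1][1] + 1)
            else:
                out.append((s, 1))
        return out
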