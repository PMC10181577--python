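"""Deterministic windowing of an AE recording into disjoint equal slices.

A recording is cut into ``n_windows`` contiguous, non-overlapping windows of
``floor(L / n_windows)`` samples each; the trailing remainder is dropped so
all windows have identical length (the nominal configuration, 1,000,000
samples into 10 windows of 100,000, divides evenly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wearsim import AESignal

__all__ = ["WindowSet", "window_signal"]


@dataclass
class WindowSet:
    """Equal-length, temporally ordered, disjoint windows of one recording."""

    windows: np.ndarray  # shape (n_windows, window_length)
    window_length: int
    source_id: str = ""

    def __len__(self) -> int:
        return self.windows.shape[0]

    def __iter__(self):
        return iter(self.windows)


def window_signal(
    signal: AESignal | np.ndarray, n_windows: int = 10, source_id: str = ""
) -> WindowSet:
    """Slice a signal into ``n_windows`` disjoint equal windows.

    Raises
    ------
    ValueError
        If ``n_windows < 1`` or the signal is shorter than ``n_windows``.
    """
    x = signal.samples if isinstance(signal, AESignal) else np.asarray(signal, dtype=float)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if x.size < n_windows:
        raise ValueError(
            f"signal of length {x.size} cannot be cut into {n_windows} windows"
        )
    length = x.size // n_windows
    windows = x[: n_windows * length].reshape(n_windows, length).copy()
    return WindowSet(windows=windows, window_length=length, source_id=source_id)
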