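"""Windowed per-position numeric tracks.

The shared kernel for the composition, disorder and amyloid tracks is a
plain full-window moving average: a track of length ``n`` scored with an
odd window ``w`` yields ``n - w + 1`` values, one per window, indexed by
the 1-based sequence position of the window *center*.  Truncated edge
windows are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PropensityProfile:
    """A windowed per-position numeric track.

    Attributes
    ----------
    start : int
        1-based sequence position of the first scored window center,
        i.e. ``(window + 1) // 2`` for a full-length track.
    window : int
        Odd window size used to compute the track.
    values : numpy.ndarray
        One finite value per scoreable position.
    """

    start: int
    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.window % 2 != 1:
            raise ValueError(f"window size must be odd, got {self.window}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        """1-based window-center positions, one per value."""
        return self.start + np.arange(len(self.values))

    def to_tsv(self) -> str:
        """Two-column export: position, value."""
        lines = ["position\tvalue"]
        lines += [f"{p}\t{v:.10g}" for p, v in zip(self.positions, self.values)]
        return "\n".join(lines) + "\n"


def window_average(values: np.ndarray, window: int, start: int | None = None) -> PropensityProfile:
    """Full-window moving average of a numeric track.

    ``output[i]`` is the arithmetic mean of ``values[i .. i+window-1]``;
    only full windows are scored.

    Parameters
    ----------
    values : array-like
        Numeric track, length >= ``window``.
    window : int
        Odd window size.
    start : int, optional
        1-based center position of the first window; defaults to
        ``(window + 1) // 2`` (a track starting at sequence position 1).
    """
    values = np.asarray(values, dtype=float)
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window size must be a positive odd integer, got {window}")
    if values.ndim != 1:
        raise ValueError("track must be one-dimensional")
    if len(values) < window:
        raise ValueError(f"track of length {len(values)} shorter than window {window}")
    means = np.lib.stride_tricks.sliding_window_view(values, window).mean(axis=1)
    if start is None:
        start = (window + 1) // 2
    return PropensityProfile(start=start, window=window, values=means)


def shrinking_window_average(profile: PropensityProfile, window: int) -> PropensityProfile:
    """Second-pass smoothing whose window shrinks symmetrically at edges.

    Every input position receives an output value: at index ``i`` the
    half-width is ``min((window-1)//2, i, n-1-i)``, so interior positions
    get the full window and edge positions a symmetric truncation.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window size must be a positive odd integer, got {window}")
    v = profile.values
    n = len(v)
    half = (window - 1) // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = v[i - h: i + h + 1].mean()
    return PropensityProfile(start=profile.start, window=window, values=out)
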