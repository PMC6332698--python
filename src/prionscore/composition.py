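"""Composition-based prion propensity with intrinsic-disorder gating.

The composition term follows the PAPA approach: per-residue prion
propensities (a scale derived from Sup35 prion-domain mutagenesis) are
averaged over 41-residue windows, the window scores are averaged again
over a 41-window of windows, and the sequence score is the maximum of
this doubly-averaged track over positions predicted disordered.

Disorder is gated with a FoldIndex-style index computed on the same
windows::

    index = 2.785 * <H> - |<q>| - 1.151

where ``<H>`` is the mean Kyte-Doolittle hydropathy rescaled to [0, 1]
and ``<q>`` the mean net charge (K, R = +1; D, E = -1; others 0).
Negative index values predict disorder.  When no window is disordered
the composition term falls back to the scale minimum (a floor) and the
result is flagged: the method targets disordered prion-like domains but
must still return a defined value for fully ordered inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .profiles import PropensityProfile, shrinking_window_average, window_average
from .scales import PropensityScale, load_hydropathy, load_prion_propensity
from .seqio import ProteinRecord

#: Default window for both propensity averaging and the disorder index.
DEFAULT_WINDOW = 41

# FoldIndex constants.
_FOLDINDEX_H_COEF = 2.785
_FOLDINDEX_OFFSET = 1.151

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

SecondPassMode = Literal["shrink", "strict"]


@dataclass(frozen=True)
class CompositionResult:
    """Outcome of disorder-gated composition scoring for one sequence.

    ``score`` is the maximum doubly-averaged propensity over windows
    whose disorder index is negative; ``position`` is the 1-based center
    of the winning window (ties broken toward the lowest position).
    When no window passes the disorder gate, ``score`` is the scale
    minimum and ``floored`` is set.
    """

    score: float
    position: int | None
    floored: bool
    profile: PropensityProfile
    disorder: PropensityProfile
    disordered_mask: np.ndarray

    @property
    def disordered_span(self) -> tuple[int, int] | None:
        """Residue span (1-based, inclusive) of the contiguous disordered
        window run containing the winning window, or ``None`` if floored."""
        if self.floored or self.position is None:
            return None
        idx = int(self.position - self.profile.start)
        mask = self.disordered_mask
        lo = idx
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        hi = idx
        while hi < len(mask) - 1 and mask[hi + 1]:
            hi += 1
        half = (self.profile.window - 1) // 2
        first_center = int(self.profile.positions[lo])
        last_center = int(self.profile.positions[hi])
        return first_center - half, last_center + half


def foldindex_profile(
    record: ProteinRecord | str,
    window: int = DEFAULT_WINDOW,
    hydropathy: PropensityScale | None = None,
) -> PropensityProfile:
    """Windowed FoldIndex-style disorder index; negative predicts disorder."""
    sequence = record.sequence if isinstance(record, ProteinRecord) else record
    if hydropathy is None:
        hydropathy = load_hydropathy()
    raw = hydropathy.encode(sequence)
    lo, hi = hydropathy.min, hydropathy.max
    rescaled = (raw - lo) / (hi - lo)
    charge = np.array([_CHARGE.get(aa, 0.0) for aa in sequence])
    mean_h = window_average(rescaled, window).values
    mean_q = window_average(charge, window).values
    index = _FOLDINDEX_H_COEF * mean_h - np.abs(mean_q) - _FOLDINDEX_OFFSET
    return PropensityProfile(start=(window + 1) // 2, window=window, values=index)


def composition_score(
    record: ProteinRecord | str,
    scale: PropensityScale | None = None,
    window: int = DEFAULT_WINDOW,
    second_pass: SecondPassMode = "shrink",
    hydropathy: PropensityScale | None = None,
) -> CompositionResult:
    """Disorder-gated, doubly window-averaged composition propensity.

    Parameters
    ----------
    record : ProteinRecord or str
        Validated sequence, at least ``window + (window - 1) // 2``
        residues in practice (the 60-residue input minimum guarantees
        at least 20 full windows at the default window of 41).
    scale : PropensityScale, optional
        Per-residue prion propensity scale; the shipped Sup35-derived
        scale by default.
    second_pass : {"shrink", "strict"}
        Edge handling of the second averaging pass.  ``"shrink"``
        (default) shrinks the window symmetrically so every first-pass
        window receives a value; ``"strict"`` scores only full second
        windows and requires ``len(sequence) >= 2*window - 1``.
    """
    sequence = record.sequence if isinstance(record, ProteinRecord) else record
    if scale is None:
        scale = load_prion_propensity()
    per_residue = scale.encode(sequence)
    first = window_average(per_residue, window)
    if second_pass == "shrink":
        second = shrinking_window_average(first, window)
        disorder = foldindex_profile(sequence, window, hydropathy)
    elif second_pass == "strict":
        inner = window_average(first.values, window, start=first.start + (window - 1) // 2)
        disorder_full = foldindex_profile(sequence, window, hydropathy)
        half = (window - 1) // 2
        disorder = PropensityProfile(
            start=inner.start, window=window,
            values=disorder_full.values[half: len(disorder_full) - half],
        )
        second = inner
    else:
        raise ValueError(f"unknown second-pass mode {second_pass!r}")

    mask = disorder.values < 0.0
    if not mask.any():
        return CompositionResult(
            score=scale.min, position=None, floored=True,
            profile=second, disorder=disorder, disordered_mask=mask,
        )
    candidates = np.where(mask, second.values, -np.inf)
    best = int(np.argmax(candidates))  # argmax returns the first (lowest) tie
    return CompositionResult(
        score=float(second.values[best]),
        position=int(second.positions[best]),
        floored=False,
        profile=second,
        disorder=disorder,
        disordered_mask=mask,
    )
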