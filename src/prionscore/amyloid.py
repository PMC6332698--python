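"""Amyloid-core detection with a hexapeptide scoring matrix.

Short amyloidogenic stretches inside disordered prion-like domains act
as nucleation cores of the aggregation reaction.  Following the pWALTZ
approach, every 21-residue stretch is scored as the mean of its 16
overlapping hexapeptide scores under a position-specific scoring matrix,
and the best stretch's raw score is mapped to [0, 100] by linear min-max
normalization against the matrix's achievable extreme hexapeptide sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scales import AmyloidMatrix, load_amyloid_matrix
from .seqio import ProteinRecord, SequenceError

#: Number of residues in the scored amyloid core.
DEFAULT_CORE_LENGTH = 21

HEX_LENGTH = 6


@dataclass(frozen=True)
class AmyloidCoreResult:
    """Best-scoring amyloid core of one sequence.

    ``score`` is min-max normalized to [0, 100]; ``start`` is the
    1-based position of the core's first residue in the *full* sequence
    (ties broken toward the lowest start); ``raw`` is the unnormalized
    mean hexapeptide score.  ``region`` records the residue span
    searched, and ``region_fallback`` is set when a supplied search
    region was unusable (too short) and the whole sequence was scored
    instead.
    """

    score: float
    start: int
    core: str
    raw: float
    region: tuple[int, int]
    region_fallback: bool = False


def hexapeptide_score(hexapeptide: str, matrix: AmyloidMatrix | None = None) -> float:
    """Sum of matrix entries for one 6-residue peptide."""
    if matrix is None:
        matrix = load_amyloid_matrix()
    if len(hexapeptide) != HEX_LENGTH:
        raise SequenceError(
            f"hexapeptide must have exactly {HEX_LENGTH} residues, got {len(hexapeptide)}"
        )
    idx = matrix.encode(hexapeptide)
    return float(matrix.scores[np.arange(HEX_LENGTH), idx].sum())


def _hex_track(sequence: str, matrix: AmyloidMatrix) -> np.ndarray:
    """Hexapeptide scores for every start position (length ``L - 5``)."""
    idx = matrix.encode(sequence)
    n = len(sequence) - HEX_LENGTH + 1
    if n < 1:
        raise SequenceError("sequence shorter than a hexapeptide")
    starts = np.lib.stride_tricks.sliding_window_view(idx, HEX_LENGTH)
    return matrix.scores[np.arange(HEX_LENGTH), starts].sum(axis=1)


def amyloid_core(
    record: ProteinRecord | str,
    matrix: AmyloidMatrix | None = None,
    core_length: int = DEFAULT_CORE_LENGTH,
    region: tuple[int, int] | None = None,
) -> AmyloidCoreResult:
    """Locate and score the best ``core_length``-residue amyloid core.

    Parameters
    ----------
    record : ProteinRecord or str
        Validated sequence, at least ``core_length`` residues.
    region : (int, int), optional
        1-based inclusive residue span to restrict the search to
        (typically the disordered region from composition scoring).
        A region shorter than ``core_length`` triggers a whole-sequence
        fallback, flagged in the result.
    """
    sequence = record.sequence if isinstance(record, ProteinRecord) else record
    if matrix is None:
        matrix = load_amyloid_matrix()
    if core_length < HEX_LENGTH:
        raise ValueError(f"core length must be >= {HEX_LENGTH}, got {core_length}")
    if len(sequence) < core_length:
        raise SequenceError(
            f"sequence of length {len(sequence)} shorter than core length {core_length}"
        )

    fallback = False
    span = (1, len(sequence))
    if region is not None:
        lo, hi = region
        lo = max(1, lo)
        hi = min(len(sequence), hi)
        if hi - lo + 1 >= core_length:
            span = (lo, hi)
        else:
            fallback = True
    sub = sequence[span[0] - 1: span[1]]

    hex_scores = _hex_track(sub, matrix)
    per_window = core_length - HEX_LENGTH + 1  # hexapeptides per core window
    window_scores = np.lib.stride_tricks.sliding_window_view(hex_scores, per_window).mean(axis=1)
    best = int(np.argmax(window_scores))  # lowest start on ties
    raw = float(window_scores[best])
    normalized = 100.0 * (raw - matrix.min_anchor) / (matrix.max_anchor - matrix.min_anchor)
    start = span[0] + best
    return AmyloidCoreResult(
        score=float(normalized),
        start=start,
        core=sequence[start - 1: start - 1 + core_length],
        raw=raw,
        region=span,
        region_fallback=fallback,
    )
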