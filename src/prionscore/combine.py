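"""Linear combination of the composition and amyloid terms.

The final aggregation-propensity score of a sequence is a weighted
linear blend of two normalized terms::

    score = max(floor, w_c * (c - c_offset) / c_divisor
                     + w_a * (a - a_offset) / a_divisor
                     + intercept)

where ``c`` is the disorder-gated composition propensity and ``a`` the
amyloid-core score on its native 0-100 scale.  Scores below 0.45 mark
low aggregation propensity, scores above 0.78 high; the band in between
is "increased".  Scores may exceed 1.0 — the scale is open above.

The weights are configuration, not code: they can be refit against any
panel of sequences with published/measured scores via :func:`calibrate`
(closed-form least squares), and the fitted parameters round-trip
through a plain key=value params file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .amyloid import DEFAULT_CORE_LENGTH, AmyloidCoreResult, amyloid_core
from .composition import DEFAULT_WINDOW, CompositionResult, composition_score
from .scales import AmyloidMatrix, PropensityScale, load_amyloid_matrix, load_prion_propensity
from .seqio import ProteinRecord, validate_record

ClassLabel = Literal["low", "increased", "high"]

#: Classification thresholds on the combined score.
THETA_LOW = 0.45
THETA_HIGH = 0.78


class CalibrationError(ValueError):
    """Raised when a calibration problem is degenerate."""


@dataclass(frozen=True)
class CombinationParams:
    """Weights, normalizations and thresholds of the linear combination.

    The composition term is normalized by an affine map (default:
    divide by the propensity-scale maximum so a maximally prion-prone
    disordered window maps near 1); the amyloid term by its 0-100
    native span.  ``theta_low``/``theta_high`` are the published
    classification thresholds and are not meant to be refit.
    """

    w_c: float = 0.5
    w_a: float = 0.5
    c_offset: float = 0.0
    c_divisor: float = field(default_factory=lambda: load_prion_propensity().max)
    a_offset: float = 0.0
    a_divisor: float = 100.0
    intercept: float = 0.0
    floor: float = 0.0
    theta_low: float = THETA_LOW
    theta_high: float = THETA_HIGH

    def __post_init__(self) -> None:
        if self.w_c < 0 or self.w_a < 0 or self.w_c + self.w_a <= 0:
            raise ValueError("weights must be non-negative with a positive sum")
        if self.c_divisor <= 0 or self.a_divisor <= 0:
            raise ValueError("normalization divisors must be positive")
        if not self.theta_low < self.theta_high:
            raise ValueError("theta_low must be below theta_high")

    def norm_c(self, c: float | np.ndarray) -> float | np.ndarray:
        return (c - self.c_offset) / self.c_divisor

    def norm_a(self, a: float | np.ndarray) -> float | np.ndarray:
        return (a - self.a_offset) / self.a_divisor

    def to_file(self, path: str | Path, provenance: str = "") -> None:
        lines = ["# combination parameters for the combined aggregation-propensity score"]
        if provenance:
            lines += [f"# {line}" for line in provenance.splitlines()]
        for key in ("w_c", "w_a", "c_offset", "c_divisor", "a_offset",
                    "a_divisor", "intercept", "floor", "theta_low", "theta_high"):
            lines.append(f"{key} = {getattr(self, key)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "CombinationParams":
        kwargs: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value.strip())
        return cls(**kwargs)


def combine(c: float, a: float, params: CombinationParams | None = None) -> float:
    """Combined score from a raw composition term and a raw 0-100 amyloid term."""
    if params is None:
        params = CombinationParams()
    if not (np.isfinite(c) and np.isfinite(a)):
        raise ValueError("composition and amyloid terms must be finite")
    raw = (
        params.w_c * params.norm_c(c)
        + params.w_a * params.norm_a(a)
        + params.intercept
    )
    return float(max(params.floor, raw))


def classify(score: float, params: CombinationParams | None = None) -> ClassLabel:
    """Three-class label from a combined score.

    The thresholds themselves belong to the middle class: the published
    inequalities are strict (``< 0.45`` low, ``> 0.78`` high), so a
    score exactly at a threshold is labeled ``"increased"``.
    """
    if params is None:
        params = CombinationParams()
    if score < params.theta_low:
        return "low"
    if score > params.theta_high:
        return "high"
    return "increased"


@dataclass(frozen=True)
class ScoreBundle:
    """Full scoring outcome for one sequence."""

    id: str
    composition_raw: float
    composition_norm: float
    amyloid_raw: float
    amyloid_norm: float
    combined: float
    label: ClassLabel
    core_start: int
    core_sequence: str
    composition_position: int | None
    composition_floored: bool
    region_fallback: bool
    clamped: bool
    delta: float | None = None
    impact: str | None = None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "composition_raw": self.composition_raw,
            "composition_norm": self.composition_norm,
            "amyloid_raw": self.amyloid_raw,
            "amyloid_norm": self.amyloid_norm,
            "combined": self.combined,
            "label": self.label,
            "core_start": self.core_start,
            "core_sequence": self.core_sequence,
            "composition_position": self.composition_position,
            "composition_floored": self.composition_floored,
            "region_fallback": self.region_fallback,
            "clamped": self.clamped,
            "delta": self.delta,
            "impact": self.impact,
        }


@dataclass(frozen=True)
class ScoringConfig:
    """Everything needed to score sequences end to end."""

    scale: PropensityScale | None = None
    matrix: AmyloidMatrix | None = None
    window: int = DEFAULT_WINDOW
    core_length: int = DEFAULT_CORE_LENGTH
    couple_region: bool = True

    def resolved(self) -> "ScoringConfig":
        return replace(
            self,
            scale=self.scale or load_prion_propensity(),
            matrix=self.matrix or load_amyloid_matrix(),
        )


def score_record(
    record: ProteinRecord,
    params: CombinationParams | None = None,
    config: ScoringConfig | None = None,
) -> ScoreBundle:
    """Score one validated record end to end.

    With region coupling (the default) the amyloid-core search is
    restricted to the contiguous disordered region around the
    composition argmax, falling back to the whole sequence when gating
    leaves no usable region.
    """
    params = params or CombinationParams()
    config = (config or ScoringConfig()).resolved()
    validate_record(record)
    comp = composition_score(record, scale=config.scale, window=config.window)
    region = comp.disordered_span if config.couple_region else None
    amy = amyloid_core(record, matrix=config.matrix, core_length=config.core_length,
                       region=region)
    combined = combine(comp.score, amy.score, params)
    raw = (
        params.w_c * params.norm_c(comp.score)
        + params.w_a * params.norm_a(amy.score)
        + params.intercept
    )
    return ScoreBundle(
        id=record.id,
        composition_raw=comp.score,
        composition_norm=float(params.norm_c(comp.score)),
        amyloid_raw=amy.score,
        amyloid_norm=float(params.norm_a(amy.score)),
        combined=combined,
        label=classify(combined, params),
        core_start=amy.start,
        core_sequence=amy.core,
        composition_position=comp.position,
        composition_floored=comp.floored,
        region_fallback=amy.region_fallback or (config.couple_region and region is None),
        clamped=raw < params.floor,
    )


def _impact_text(bundle: ScoreBundle, ref_id: str) -> str:
    """Fixed three-tier phrasing keyed to class and delta sign."""
    delta = bundle.delta or 0.0
    if abs(delta) < 5e-3:
        direction = f"does not change the predicted aggregation propensity relative to {ref_id}"
    elif delta > 0:
        direction = f"increases the predicted aggregation propensity relative to {ref_id} (+{delta:.2f})"
    else:
        direction = f"decreases the predicted aggregation propensity relative to {ref_id} ({delta:.2f})"
    tier = {
        "low": "low overall aggregation propensity",
        "increased": "increased overall aggregation propensity",
        "high": "high overall aggregation propensity",
    }[bundle.label]
    return f"{bundle.id}: score {bundle.combined:.2f} ({tier}); {direction}."


def compare_sequences(
    reference: ProteinRecord,
    variants: Sequence[ProteinRecord],
    params: CombinationParams | None = None,
    config: ScoringConfig | None = None,
) -> tuple[ScoreBundle, list[ScoreBundle]]:
    """Score a reference and its variants; annotate each variant with
    the score difference to the reference and a textual impact statement.

    Bundles are returned in input order; validation errors name the
    offending record.
    """
    params = params or CombinationParams()
    ref_bundle = score_record(reference, params, config)
    out: list[ScoreBundle] = []
    for rec in variants:
        b = score_record(rec, params, config)
        b = replace(b, delta=b.combined - ref_bundle.combined)
        b = replace(b, impact=_impact_text(b, reference.id))
        out.append(b)
    return ref_bundle, out


def single_mutation_scan(
    record: ProteinRecord,
    position: int,
    params: CombinationParams | None = None,
    config: ScoringConfig | None = None,
) -> list[ScoreBundle]:
    """Saturation scan of one residue position.

    Returns exactly 20 bundles: the wild type first (delta 0), then the
    19 substitutions in alphabetical order of the substituted residue,
    each annotated with its score difference to the wild type.
    """
    from .seqio import enumerate_substitutions  # local to avoid cycle at import

    params = params or CombinationParams()
    validate_record(record)
    record.residue(position)  # range check before any scoring
    wt, variants = compare_sequences(record, enumerate_substitutions(record, position),
                                     params, config)
    wt = replace(wt, delta=0.0, impact=_impact_text(replace(wt, delta=0.0), record.id))
    return [wt] + variants


def calibrate(
    anchors: Sequence[tuple[ProteinRecord, float]],
    free: Sequence[str] = ("w_c", "w_a"),
    params: CombinationParams | None = None,
    config: ScoringConfig | None = None,
) -> tuple[CombinationParams, np.ndarray]:
    """Least-squares fit of the free combination parameters to anchors.

    Each anchor pairs a sequence with a published combined score.  The
    composition and amyloid terms are computed for every anchor, and
    the free parameters among ``{"w_c", "w_a", "intercept"}`` are fit in
    closed form (normal equations via ``numpy.linalg.lstsq``); fixed
    parameters keep their current values.  Returns the fitted params and
    the per-anchor residuals (fit minus published).

    Raises
    ------
    CalibrationError
        With fewer than 2 anchors, identical published scores, or a
        rank-deficient design (anchors indistinguishable in a fitted
        dimension).
    """
    params = params or CombinationParams()
    allowed = {"w_c", "w_a", "intercept"}
    free = tuple(free)
    if not free or any(f not in allowed for f in free):
        raise CalibrationError(f"free parameters must be a non-empty subset of {sorted(allowed)}")
    if len(anchors) < 2:
        raise CalibrationError("calibration requires at least 2 anchors")
    published = np.array([s for _, s in anchors], dtype=float)
    if np.allclose(published, published[0]):
        raise CalibrationError("anchors must have at least 2 distinct published scores")

    cn = np.empty(len(anchors))
    an = np.empty(len(anchors))
    cfg = (config or ScoringConfig()).resolved()
    for i, (rec, _) in enumerate(anchors):
        b = score_record(rec, params, cfg)
        cn[i] = b.composition_norm
        an[i] = b.amyloid_norm

    columns = {"w_c": cn, "w_a": an, "intercept": np.ones(len(anchors))}
    design = np.column_stack([columns[f] for f in free])
    fixed = np.zeros(len(anchors))
    for name in allowed - set(free):
        fixed += getattr(params, name) * columns[name]
    target = published - fixed

    solution, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < len(free):
        raise CalibrationError(
            "rank-deficient calibration: anchors do not distinguish all free parameters"
        )
    fitted = replace(params, **dict(zip(free, (float(x) for x in solution))))
    predictions = design @ solution + fixed
    residuals = predictions - published
    return fitted, residuals
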