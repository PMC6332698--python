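"""Synthetic prion-like-domain sequence generation.

Test fixtures and offline examples need sequences that look like real
prion-like domains: long, intrinsically disordered, Q/N-rich and
depleted in charged and hydrophobic residues.  The generator samples
residues i.i.d. from a configurable background composition (default:
a Q/N-rich disordered profile modeled on yeast prion domains) and can
embed a designed amyloidogenic 21-mer at a chosen position, so paired
fixtures with and without a nucleation core differ only there.

What this emulates — composition bias and a localized amyloid core.
What it does not — positional grammar, oligopeptide repeats, or the
full-length context of real prion-like proteins flanking the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scales import AmyloidMatrix, load_amyloid_matrix
from .seqio import MIN_LENGTH, STANDARD_AA, ProteinRecord

#: Q/N-rich disordered background composition (fractions; normalized on use).
#: Modeled on the composition of yeast prion domains: Q/N dominant, G/S/Y
#: abundant, charged and strongly hydrophobic residues rare.
DEFAULT_PRLD_COMPOSITION: dict[str, float] = {
    "A": 0.055, "C": 0.005, "D": 0.020, "E": 0.020, "F": 0.030,
    "G": 0.115, "H": 0.020, "I": 0.010, "K": 0.030, "L": 0.020,
    "M": 0.020, "N": 0.160, "P": 0.060, "Q": 0.170, "R": 0.030,
    "S": 0.100, "T": 0.040, "V": 0.010, "W": 0.005, "Y": 0.080,
}


#: Prion-poor disordered background: enriched in the charged and
#: structure-breaking residues (K, P, E, D) that suppress prion propensity
#: while remaining disordered.
PRION_POOR_COMPOSITION: dict[str, float] = {
    "A": 0.050, "C": 0.005, "D": 0.060, "E": 0.080, "F": 0.005,
    "G": 0.105, "H": 0.020, "I": 0.005, "K": 0.130, "L": 0.020,
    "M": 0.010, "N": 0.080, "P": 0.120, "Q": 0.080, "R": 0.050,
    "S": 0.105, "T": 0.045, "V": 0.005, "W": 0.005, "Y": 0.020,
}

#: Prion-prone background: strongly Q/N/Y-rich, depleted in charge.
PRION_RICH_COMPOSITION: dict[str, float] = {
    "A": 0.040, "C": 0.010, "D": 0.0025, "E": 0.0025, "F": 0.060,
    "G": 0.065, "H": 0.020, "I": 0.020, "K": 0.005, "L": 0.015,
    "M": 0.040, "N": 0.180, "P": 0.020, "Q": 0.200, "R": 0.005,
    "S": 0.105, "T": 0.030, "V": 0.020, "W": 0.010, "Y": 0.150,
}


@dataclass(frozen=True)
class SyntheticPrLDSpec:
    """Recipe for one synthetic prion-like-domain sequence.

    ``core`` is an optional amyloidogenic stretch inserted verbatim with
    its first residue at 1-based ``core_position``.
    """

    length: int = 120
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRLD_COMPOSITION)
    )
    core: str | None = None
    core_position: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < MIN_LENGTH:
            raise ValueError(f"length must be >= {MIN_LENGTH}, got {self.length}")
        keys = set(self.composition)
        if not keys <= set(STANDARD_AA):
            raise ValueError(f"non-standard residues in composition: {sorted(keys - set(STANDARD_AA))}")
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=0.02) or any(v < 0 for v in self.composition.values()):
            raise ValueError(f"composition frequencies must be non-negative and sum to 1, got {total:.4f}")
        if self.core is not None:
            pos = self.core_position
            if pos is None or pos < 1 or pos + len(self.core) - 1 > self.length:
                raise ValueError("embedded core must fit inside the sequence")
            if not set(self.core) <= set(STANDARD_AA):
                raise ValueError("embedded core contains non-standard residues")


def generate_synthetic_prld(spec: SyntheticPrLDSpec) -> ProteinRecord:
    """Sample one sequence from the spec, reproducibly by seed."""
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.composition)
    probs = np.array([spec.composition[r] for r in residues], dtype=float)
    probs = probs / probs.sum()
    seq = "".join(rng.choice(list(residues), size=spec.length, p=probs))
    if spec.core is not None:
        pos = spec.core_position
        seq = seq[: pos - 1] + spec.core + seq[pos - 1 + len(spec.core):]
    tag = "" if spec.core is None else f"_core{spec.core_position}"
    return ProteinRecord(
        id=f"synthetic_prld_len{spec.length}_seed{spec.seed}{tag}",
        sequence=seq,
        description="synthetic Q/N-rich prion-like domain",
    )


def synthetic_anchor_panel(
    n: int = 20, seed: int = 900, lengths: tuple[int, ...] = (90, 100, 110, 120, 130)
) -> list[ProteinRecord]:
    """A calibration panel of synthetic variants spanning aggregation
    propensities.

    Emulates the shape of an experimental calibration set: the
    background composition is interpolated from prion-poor to
    prion-prone across the panel, and every second sequence carries an
    embedded amyloidogenic core, so the composition and amyloid terms
    vary with substantial independence and a two-weight linear fit is
    well conditioned.  Deterministic given ``seed``.
    """
    core = high_scoring_core()
    panel: list[ProteinRecord] = []
    for i in range(n):
        t = i / (n - 1) if n > 1 else 0.5
        comp = {
            aa: (1 - t) * PRION_POOR_COMPOSITION[aa] + t * PRION_RICH_COMPOSITION[aa]
            for aa in PRION_POOR_COMPOSITION
        }
        length = lengths[i % len(lengths)]
        kwargs: dict = {}
        if i % 2:
            kwargs = {"core": core, "core_position": 10 + (3 * i) % (length - 35)}
        panel.append(
            generate_synthetic_prld(
                SyntheticPrLDSpec(length=length, seed=seed + i, composition=comp, **kwargs)
            )
        )
    return panel


def high_scoring_core(
    matrix: AmyloidMatrix | None = None, length: int = 21
) -> str:
    """A designed high-amyloid stretch: the matrix's best hexapeptide tiled
    to the requested length.  Not guaranteed globally optimal, but scores
    near the matrix maximum — useful for paired fixtures."""
    if matrix is None:
        matrix = load_amyloid_matrix()
    best_hex = "".join(
        STANDARD_AA[int(np.argmax(matrix.scores[j]))] for j in range(matrix.scores.shape[0])
    )
    return (best_hex * (length // len(best_hex) + 1))[:length]
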