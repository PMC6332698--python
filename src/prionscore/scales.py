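"""Reference scoring tables shipped as package data.

Two kinds of tables live here: per-residue scales (prion propensity,
hydropathy) stored as two-column TSV with ``#`` comment headers, and the
6x20 hexapeptide amyloid position-specific scoring matrix with its
min/max normalization anchors.  Swapping a scale is a configuration
option, never a code change: every loader accepts an external path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .seqio import STANDARD_AA, AlphabetError

PathLike = Union[str, Path]

_DATA_PACKAGE = "prionscore.data"

PAPA_SCALE_FILE = "papa_propensity.tsv"
HYDROPATHY_FILE = "kyte_doolittle.tsv"
AMYLOID_MATRIX_FILE = "amyloid_pssm_synthetic.tsv"


def _read_data_text(name: str) -> str:
    return resources.files(_DATA_PACKAGE).joinpath(name).read_text()


@dataclass(frozen=True)
class PropensityScale:
    """A per-residue numeric scale over the 20 standard amino acids."""

    values: Mapping[str, float]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            missing = sorted(set(STANDARD_AA) - keys)
            extra = sorted(keys - set(STANDARD_AA))
            raise ValueError(
                f"scale {self.name!r} must have exactly the 20 standard residues; "
                f"missing={missing} extra={extra}"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise AlphabetError(f"residue {residue!r} not in scale {self.name!r}") from None

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to its per-residue scale values."""
        return np.array([self[aa] for aa in sequence], dtype=float)

    @classmethod
    def from_text(cls, text: str, name: str = "unnamed") -> "PropensityScale":
        values: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"bad scale line in {name!r}: {line!r}")
            values[parts[0].upper()] = float(parts[1])
        return cls(values=values, name=name)

    @classmethod
    def from_file(cls, path: PathLike) -> "PropensityScale":
        path = Path(path)
        return cls.from_text(path.read_text(), name=path.stem)


def load_prion_propensity(path: PathLike | None = None) -> PropensityScale:
    """The default prion propensity scale (Sup35 mutagenesis-derived)."""
    if path is not None:
        return PropensityScale.from_file(path)
    return PropensityScale.from_text(_read_data_text(PAPA_SCALE_FILE), name="prion_propensity")


def load_hydropathy(path: PathLike | None = None) -> PropensityScale:
    """The Kyte-Doolittle hydropathy scale (raw, unrescaled)."""
    if path is not None:
        return PropensityScale.from_file(path)
    return PropensityScale.from_text(_read_data_text(HYDROPATHY_FILE), name="kyte_doolittle")


@dataclass(frozen=True)
class AmyloidMatrix:
    """Position-specific scores for residues at each of 6 hexapeptide positions.

    ``scores`` is a (6, 20) array whose columns follow the alphabetical
    residue order of :data:`~prionscore.seqio.STANDARD_AA`.  The min/max
    anchors are the extreme achievable hexapeptide sums; they are stored
    in the matrix file rather than recomputed so that normalized scores
    stay stable across matrix revisions.
    """

    scores: np.ndarray
    min_anchor: float
    max_anchor: float
    name: str = "unnamed"
    _index: Mapping[str, int] = field(
        default_factory=lambda: {aa: i for i, aa in enumerate(STANDARD_AA)}, repr=False
    )

    def __post_init__(self) -> None:
        if self.scores.shape != (6, len(STANDARD_AA)):
            raise ValueError(
                f"amyloid matrix must be 6x{len(STANDARD_AA)}, got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"amyloid matrix {self.name!r} contains non-finite entries")
        if not self.min_anchor < self.max_anchor:
            raise ValueError("min anchor must be strictly below max anchor")

    def residue_index(self, residue: str) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise AlphabetError(
                f"residue {residue!r} not scorable by matrix {self.name!r}"
            ) from None

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to residue column indices."""
        return np.array([self.residue_index(aa) for aa in sequence], dtype=np.intp)

    @classmethod
    def from_text(cls, text: str, name: str = "unnamed") -> "AmyloidMatrix":
        header: list[str] | None = None
        rows: list[list[float]] = []
        anchors: tuple[float, float] | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "residue":
                header = [p.upper() for p in parts[1:]]
            elif parts[0] == "anchors":
                anchors = (float(parts[1]), float(parts[2]))
            else:
                rows.append([float(p) for p in parts[1:]])
        if header is None or anchors is None or len(rows) != 6:
            raise ValueError(f"malformed amyloid matrix file {name!r}")
        scores = np.array(rows, dtype=float)
        # Reorder columns to the canonical alphabet if the file differs.
        order = [header.index(aa) for aa in STANDARD_AA]
        scores = scores[:, order]
        return cls(scores=scores, min_anchor=anchors[0], max_anchor=anchors[1], name=name)

    @classmethod
    def from_file(cls, path: PathLike) -> "AmyloidMatrix":
        path = Path(path)
        return cls.from_text(path.read_text(), name=path.stem)


def load_amyloid_matrix(path: PathLike | None = None) -> AmyloidMatrix:
    """The default hexapeptide amyloid matrix (synthetic, package data)."""
    if path is not None:
        return AmyloidMatrix.from_file(path)
    return AmyloidMatrix.from_text(
        _read_data_text(AMYLOID_MATRIX_FILE), name="amyloid_pssm_synthetic"
    )
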