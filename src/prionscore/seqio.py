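"""FASTA parsing/writing, sequence validation and variant construction.

Every scoring routine in this package consumes :class:`ProteinRecord`
objects produced here.  Validation enforces the input contract of the
scoring pipeline: sequences must be at least 60 residues long and use
only the 20 standard proteinogenic amino acids.  Residue numbering is
1-based throughout, matching UniProt variant notation (e.g. ``D290V``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard proteinogenic amino acids, alphabetical one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: Minimum accepted sequence length.
MIN_LENGTH = 60


class SequenceError(ValueError):
    """Base class for all sequence input errors."""


class FastaFormatError(SequenceError):
    """Input is not parseable FASTA (e.g. no header line)."""


class DuplicateIdError(SequenceError):
    """Two records in one collection share an identifier."""


class LengthError(SequenceError):
    """Sequence shorter than the 60-residue minimum."""


class AlphabetError(SequenceError):
    """Sequence contains a character outside the 20-letter alphabet."""


class MutationError(SequenceError):
    """A mutation specification does not match the target sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier token (first word of the FASTA header).
    sequence : str
        Upper-case amino-acid sequence.
    description : str
        Free text following the identifier in the header; preserved
        but unused by the scoring pipeline.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"record id must be a non-empty token, got {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Return the residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise MutationError(
                f"position {position} outside sequence {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single-residue substitution in UniProt-style notation.

    ``MutationSpec.parse("D290V")`` means: residue 290 (1-based) is D in
    the reference and becomes V in the variant.
    """

    position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        for res in (self.from_residue, self.to_residue):
            if res not in STANDARD_AA_SET:
                raise MutationError(f"non-standard residue {res!r} in mutation spec")

    @property
    def notation(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        m = _MUTATION_RE.match(text.strip().upper())
        if m is None:
            raise MutationError(f"cannot parse mutation notation {text!r}")
        return cls(position=int(m.group(2)), from_residue=m.group(1), to_residue=m.group(3))


def _as_handle(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, Path):
        return io.StringIO(source.read_text())
    if isinstance(source, str):
        # A path-looking short string without '>' is treated as a file path.
        if source.strip() and "\n" not in source and not source.startswith(">") \
                and Path(source).is_file():
            return io.StringIO(Path(source).read_text())
        return io.StringIO(source)
    return source


def parse_fasta(source: Union[str, Path, TextIO]) -> list[ProteinRecord]:
    """Parse multi-FASTA text into a list of :class:`ProteinRecord`.

    Sequence lines are concatenated and upper-cased; residue validation
    is deferred to :func:`validate_record`.  Ids must be unique within
    the parsed collection.

    Raises
    ------
    FastaFormatError
        If the input is empty or contains no ``>`` header.
    DuplicateIdError
        If two records share an id (the id is named in the message).
    """
    handle = _as_handle(source)
    text = handle.read()
    if not text.strip():
        raise FastaFormatError("empty input: expected FASTA text")
    if ">" not in text:
        raise FastaFormatError("no FASTA header line ('>') found in input")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in input")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=description)
        )
    if not records:
        raise FastaFormatError("no records parsed from FASTA input")
    return records


def write_fasta(records: Iterable[ProteinRecord], destination: Union[str, Path, TextIO]) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")
    else:
        SeqIO.write(seqrecords, destination, "fasta")


def validate_record(record: ProteinRecord, min_length: int = MIN_LENGTH) -> ProteinRecord:
    """Validate a record against the pipeline input contract.

    Returns the record unchanged when valid.  Validation is idempotent.

    Raises
    ------
    LengthError
        If the sequence is shorter than ``min_length`` (default 60).
    AlphabetError
        If any character is outside the 20-letter standard alphabet;
        the message names the first offending position and character.
    """
    if len(record.sequence) < min_length:
        raise LengthError(
            f"sequence {record.id!r} has {len(record.sequence)} residues; "
            f"at least {min_length} are required"
        )
    for i, ch in enumerate(record.sequence, start=1):
        if ch not in STANDARD_AA_SET:
            raise AlphabetError(
                f"sequence {record.id!r} contains non-standard character "
                f"{ch!r} at position {i}; only the 20 standard amino acids are allowed"
            )
    return record


def apply_mutation(record: ProteinRecord, spec: MutationSpec) -> ProteinRecord:
    """Apply a single-residue substitution, returning a new record.

    The returned sequence differs from the input at exactly one position
    and the id is suffixed with the mutation notation.

    Raises
    ------
    MutationError
        If the position is out of range or the reference residue does
        not match (the observed residue is reported).
    """
    observed = record.residue(spec.position)
    if observed != spec.from_residue:
        raise MutationError(
            f"mutation {spec.notation}: sequence {record.id!r} has "
            f"{observed!r} at position {spec.position}, not {spec.from_residue!r}"
        )
    seq = record.sequence
    mutated = seq[: spec.position - 1] + spec.to_residue + seq[spec.position:]
    return ProteinRecord(
        id=f"{record.id}_{spec.notation}",
        sequence=mutated,
        description=record.description,
    )


def enumerate_substitutions(record: ProteinRecord, position: int) -> list[ProteinRecord]:
    """All 19 single-residue substitutions at a 1-based position.

    Records are returned in alphabetical order of the substituted
    residue; each differs from the input at exactly the given position.
    """
    wild_type = record.residue(position)
    variants = []
    for aa in STANDARD_AA:
        if aa == wild_type:
            continue
        spec = MutationSpec(position=position, from_residue=wild_type, to_residue=aa)
        variants.append(apply_mutation(record, spec))
    return variants
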