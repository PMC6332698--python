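"""Calibration anchor tables.

An anchor pairs a protein variant with a published combined
aggregation-propensity score.  Anchor tables are TSV with columns
``id``, ``accession``, ``mutation`` and ``published_score``; sequences
are resolved from FASTA files (one per accession) in a sequence
directory, with single-residue variants derived from the wild type by
the stated mutation.  The shipped table lists published scores for
human hnRNP prion-like protein variants; the sequences themselves are
not bundled and must be fetched by accession (see
``scripts/fetch_anchors.py``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .seqio import MutationSpec, ProteinRecord, apply_mutation, parse_fasta

ANCHOR_TABLE_FILE = "anchor_scores.tsv"


@dataclass(frozen=True)
class AnchorRow:
    id: str
    accession: str
    mutation: str  # "-" for wild type, else UniProt-style notation (e.g. D314V)
    published_score: float


class AnchorResolutionError(FileNotFoundError):
    """An anchor's sequence could not be resolved from the sequence directory."""


def load_anchor_table(path: str | Path | None = None) -> list[AnchorRow]:
    """Read an anchor TSV ('#' comment lines allowed); shipped table by default."""
    if path is None:
        text = resources.files("prionscore.data").joinpath(ANCHOR_TABLE_FILE).read_text()
        import io

        frame = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "accession", "mutation", "published_score"}
    if not required <= set(frame.columns):
        raise ValueError(f"anchor table must have columns {sorted(required)}")
    return [
        AnchorRow(
            id=str(r.id), accession=str(r.accession),
            mutation=str(r.mutation), published_score=float(r.published_score),
        )
        for r in frame.itertuples()
    ]


def resolve_anchor_sequences(
    rows: list[AnchorRow], sequence_dir: str | Path
) -> list[tuple[ProteinRecord, float]]:
    """Build (record, published score) pairs from accession FASTA files.

    Each accession must exist as ``<accession>.fasta`` in
    ``sequence_dir``; variants are constructed by applying the row's
    mutation to the wild-type sequence.

    Raises
    ------
    AnchorResolutionError
        Naming the first accession whose FASTA file is missing.
    """
    sequence_dir = Path(sequence_dir)
    cache: dict[str, ProteinRecord] = {}
    anchors: list[tuple[ProteinRecord, float]] = []
    for row in rows:
        if row.accession not in cache:
            fasta = sequence_dir / f"{row.accession}.fasta"
            if not fasta.exists():
                raise AnchorResolutionError(
                    f"sequence for accession {row.accession!r} not found at {fasta}; "
                    "fetch anchor sequences first (scripts/fetch_anchors.py)"
                )
            cache[row.accession] = parse_fasta(fasta)[0]
        wt = cache[row.accession]
        if row.mutation in ("-", "", "wt"):
            record = ProteinRecord(id=row.id, sequence=wt.sequence, description=wt.description)
        else:
            record = apply_mutation(wt, MutationSpec.parse(row.mutation))
            record = ProteinRecord(id=row.id, sequence=record.sequence,
                                   description=record.description)
        anchors.append((record, row.published_score))
    return anchors
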