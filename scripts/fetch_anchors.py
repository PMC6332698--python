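#!/usr/bin/env python
"""Fetch the anchor sequences referenced by the shipped anchor table.

Downloads each accession's FASTA from UniProt into ``data/anchors/``
(repository root) so that anchor-based calibration and the
published-score reproduction check can run.  Requires network access;
the sequences are deliberately not bundled with the package.

Usage: python scripts/fetch_anchors.py [--dest data/anchors]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from prionscore.anchors import load_anchor_table

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path,
                        default=Path(__file__).resolve().parent.parent / "data" / "anchors")
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)

    accessions = sorted({row.accession for row in load_anchor_table()})
    failures = 0
    for acc in accessions:
        target = args.dest / f"{acc}.fasta"
        if target.exists():
            print(f"{acc}: already present")
            continue
        url = UNIPROT_FASTA.format(accession=acc)
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                target.write_bytes(resp.read())
            print(f"{acc}: fetched")
        except Exception as exc:
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
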