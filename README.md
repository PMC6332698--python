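# prionscore

Mutation-impact scoring for prion-like proteins.

Around 1% of human proteins carry a disordered, low-complexity
prion-like domain (PrLD). Point mutations in PrLDs — hnRNPA1 D314V,
hnRNPDL D378N and similar disease-linked changes — can switch these
domains from dynamic, liquid-like assembly to solid amyloid
aggregation. `prionscore` estimates the impact of such mutations by
blending two complementary sequence signals into one calibrated score:

- **Composition term** *c*: per-residue prion propensities (a scale
  derived from Sup35 prion-domain mutagenesis, as used by the PAPA
  predictor) are averaged over 41-residue sliding windows, smoothed by
  a second 41-window pass, and gated by a FoldIndex-style disorder
  index (`2.785·⟨H⟩ − |⟨q⟩| − 1.151`; negative = disordered). The term
  is the maximal doubly-averaged propensity over disordered windows.
- **Amyloid term** *a*: every 21-residue stretch is scored as the mean
  of its 16 overlapping hexapeptide scores under a position-specific
  scoring matrix (pWALTZ-style amyloid-core detection), min–max
  normalized to [0, 100]; by default the search is restricted to the
  disordered region around the composition maximum.

The combined score is the clamped linear blend

```
score = max(0, w_c · c/c_div + w_a · a/100 + b)
```

classified as **low** (< 0.45), **increased**, or **high** (> 0.78)
aggregation propensity. The weights are configuration: they can be
refit against any panel of variants with measured or published scores
(`calibrate`, closed-form least squares). The shipped hexapeptide
matrix is a synthetic stand-in with the documented 6×20-plus-anchors
structure (see `docs/methods.md`).

Audience: protein scientists triaging candidate PrLD variants, and
anyone engineering synthetic prion-like sequences with tuned
aggregation propensity.

## Worked example

Score a synthetic Q/N-rich domain and its core-carrying twin:

```python
from prionscore import (SyntheticPrLDSpec, generate_synthetic_prld,
                        high_scoring_core, score_record)

plain = generate_synthetic_prld(SyntheticPrLDSpec(length=120, seed=3))
cored = generate_synthetic_prld(
    SyntheticPrLDSpec(length=120, seed=3, core=high_scoring_core(), core_position=50))

for rec in (plain, cored):
    b = score_record(rec)
    print(f"{rec.id}: c={b.composition_raw:.3f} a={b.amyloid_raw:.1f} "
          f"combined={b.combined:.2f} ({b.label})")
```

prints

```
synthetic_prld_len120_seed3: c=-0.072 a=55.9 combined=0.24 (low)
synthetic_prld_len120_seed3_core50: c=0.047 a=80.3 combined=0.49 (increased)
```

The embedded amyloidogenic 21-mer raises the amyloid term from 55.9 to
80.3 and moves the variant across the 0.45 threshold: the background
domain is predicted non-aggregating, the cored twin has increased
aggregation propensity.

From the shell, the same pipeline runs as:

```bash
prionscore simulate --length 120 --seed 3 --out wt.fasta
prionscore scan --seq wt.fasta --pos 60 --out scan_out
prionscore compare --ref wt.fasta --variants mutants.fasta --out cmp_out
```

`scan` writes a 20-row saturation table (wild type + all 19
substitutions at position 60), a FASTA of the generated mutants, a
human-readable `report.txt`, a schema-versioned `report.json` and a
score chart with the 0.45/0.78 guide lines.

Calibration against published anchors uses
`prionscore calibrate --sequences data/anchors/` after fetching the
anchor sequences by accession (`python scripts/fetch_anchors.py`;
requires network — the sequences are not bundled).

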