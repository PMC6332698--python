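# Methods

## Model

`prionscore` predicts the impact of amino-acid changes on the
aggregation propensity of prion-like proteins. The working assumptions
are those of the composition-plus-core view of PrLD aggregation:

1. Prion-like behavior requires an intrinsically disordered,
   low-complexity domain whose *overall composition* sets a baseline
   aggregation propensity.
2. Conversion to the amyloid state is nucleated by a short, localized
   *amyloid core* inside that disordered region, so single mutations
   can have effects far larger than their compositional footprint.

Each sequence therefore receives two terms.

### Composition term

Per-residue prion propensities come from a scale derived from
saturation mutagenesis of the Sup35 yeast prion domain (the scale used
by the PAPA predictor; shipped as `data/papa_propensity.tsv` with
provenance header). The term is computed as:

- first pass: mean propensity over every full 41-residue window
  (window centers are 1-based sequence positions; truncated edge
  windows are never scored);
- second pass: the window scores are averaged again over a 41-window
  of windows. Near the profile edges the second window shrinks
  symmetrically (half-width `min(20, i, n−1−i)`) so every first-pass
  window receives a value; a strict full-window mode is available via
  `composition_score(..., second_pass="strict")`;
- disorder gating: a FoldIndex-style index
  `2.785·⟨H⟩ − |⟨q⟩| − 1.151` is computed on the same 41-residue
  windows, with ⟨H⟩ the mean Kyte–Doolittle hydropathy rescaled to
  [0, 1] and ⟨q⟩ the mean net charge (K, R = +1; D, E = −1). Windows
  with negative index are predicted disordered;
- the term is the maximum doubly-averaged propensity over disordered
  windows, ties broken toward the lowest position. If *no* window is
  disordered the term falls back to the scale minimum and the result
  is flagged (`floored`): the method targets disordered PrLDs but must
  return a defined value for fully ordered inputs.

Double averaging is linear, so adding a constant to the scale shifts
the score by that constant and positive rescaling scales it — both
properties are tested.

### Amyloid term

Every 21-residue stretch is scored as the *mean* of its 16 overlapping
hexapeptide scores under a 6×20 position-specific scoring matrix; the
mean (rather than the sum) keeps core scores stable if the core length
is changed. The best stretch's raw score is mapped to [0, 100] by
linear min–max normalization against the matrix's extreme achievable
hexapeptide sums. The anchors are stored in the matrix file, not
recomputed, so normalized scores stay comparable across matrix
revisions. Ties break toward the lowest start.

By default the search is restricted to the contiguous disordered
window run containing the composition maximum (expanded to full
residue coordinates), mirroring the biological claim that the relevant
cores sit inside the PrLD; when that region is shorter than 21
residues, or when gating floors the composition term, the whole
sequence is searched and the result flagged (`region_fallback`). The
coupling is a config flag (`ScoringConfig.couple_region`,
`--couple-region/--whole-sequence` on the CLI).

**The shipped matrix is synthetic.** The published amyloid hexapeptide
matrix is not redistributable here, so
`data/amyloid_pssm_synthetic.tsv` is a constructed stand-in: a
per-residue amyloidogenicity ranking (F/I/V/W/Y high; P/K/E/D low)
modulated by asymmetric per-position factors so scores are
position-sensitive. It has the exact structure the scoring code
expects (6×20 values plus a min/max anchors line) and is swappable via
`load_amyloid_matrix(path)` without code changes. Absolute amyloid
scores from the default matrix are therefore internally consistent but
not comparable with published pWALTZ values.

### Combined score and classes

```
score = max(floor, w_c·(c − c_off)/c_div + w_a·(a − a_off)/a_div + b)
```

Defaults: `w_c = w_a = 0.5`, `c_div` = the propensity-scale maximum
(0.8387…, so a maximally prion-prone disordered window maps near 1),
`a_div = 100`, offsets and intercept 0, floor 0. These defaults are
this package's own parameterization choice: they weight the two
normalized terms equally and reproduce the qualitative behavior of the
published score (non-prionic ordered sequences clamp to exactly 0 via
the floor — the clamp is flagged when it fires). The published weights
were fit to the intracellular aggregation of an experimental hnRNPA2
variant panel that is not redistributable; with the anchor sequences
fetched by accession, `calibrate` refits any subset of
`{w_c, w_a, intercept}` in closed form (normal equations via
`numpy.linalg.lstsq`; rank deficiency and degenerate anchor sets raise
`CalibrationError`).

Classification uses the published thresholds: **low** < 0.45,
**high** > 0.78, **increased** between. The published inequalities are
strict, so a score exactly at a threshold belongs to the middle class.
Scores above 1.0 are legal and meaningful (more aggregation-prone than
the strongest calibration variant); the scale is open above. Variant
reports carry both the absolute class and Δ versus the reference, so
either reading of "increased" (absolute band vs. above-reference) is
recoverable.

Human-readable output rounds scores to 2 decimals; `report.json`
keeps full precision.

## Evaluation metrics

`prionscore.metrics` implements the standard benchmarking panel for
aggregation predictors: sensitivity, specificity, precision, accuracy
and MCC from the 4-cell confusion matrix (predicted class =
score ≥ threshold, default 0.45, configurable); R² as squared Pearson
r with its two-tailed t-test p-value; Spearman ρ with average ranks on
ties; and percentage-error summaries. For the % errors both series are
min–max rescaled to [0, 1] before differencing (per-variant error =
100·(predicted − observed) on that common scale; mean, sample SD,
SEM = SD/√n). This rescaling is this package's definition — the
original transformation is not published in enough detail to certify
numerical identity — and is recorded in the report metadata so
alternative definitions can be compared. Zero-denominator ratios and
zero-variance correlations are reported as `nan` and rendered "–".

## Synthetic data

`generate_synthetic_prld` samples residues i.i.d. from a background
composition (default: a Q/N-rich disordered profile modeled on yeast
prion domains — Q+N ≈ 33%, G/S/Y abundant, charge and strong
hydrophobics rare) and can embed an amyloidogenic 21-mer verbatim.
`synthetic_anchor_panel` builds calibration panels that emulate an
experimental variant set spanning non-aggregating to strongly
aggregating: the background is interpolated from a prion-poor
(K/P/E/D-enriched) to a prion-prone (Q/N/Y-rich) composition across
the panel and every second sequence carries an embedded core, so the
composition and amyloid terms vary with enough independence for a
two-weight least-squares fit to be well conditioned.

The generator emulates composition bias and a localized core. It does
*not* emulate positional grammar, oligopeptide repeats, isoform
context, or the folded flanking domains of real prion-like proteins —
so passing tests demonstrate algorithmic correctness and calibration
behavior, not predictive accuracy on real proteomes.

## Numerical and design choices

- Window sizes: 41 (composition and disorder; the published default of
  the composition predictor), 21 (amyloid core), 6 (hexapeptide). The
  60-residue input minimum guarantees ≥ 20 full 41-windows.
- All window means are float64; oracle tests require agreement with
  direct-summation enumeration within 1e-12.
- Ties in any argmax resolve to the lowest sequence position; output
  ordering is deterministic everywhere (scan rows: wild type first,
  then alphabetical by substituted residue).
- The job identifier in reports is derived from a content hash of the
  inputs and parameters, not wall-clock time, so identical runs yield
  byte-identical `report.json`; the timestamp appears only in
  `report.txt`.
- Validation: ≥ 60 residues, 20-letter alphabet only; lower-case input
  is upper-cased; any other character (including gaps and whitespace
  inside sequence lines) is rejected with position and character named.
- Problem sizes in the test suite and acceptance script (200 oracle
  sequences of length 60–200, 20-anchor panels, 100 noise replicates)
  were chosen to exercise every code path at tight tolerances while
  keeping the default run fast on a laptop.

## Known limitations

- The default combination weights are a documented package choice, not
  the published fit; quantitative reproduction of published
  variant scores additionally requires the published hexapeptide
  matrix and the anchor sequences, neither of which is bundled.
- Only single-residue substitutions are first-class (`MutationSpec`);
  insertions, deletions and multi-site variants can be scored by
  supplying the full variant sequence in compare mode.
- No alternative disorder predictors; the FoldIndex-style gate is the
  only one implemented.
- Nucleotide input, ambiguity codes and alignments are out of scope.
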