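import numpy as np
import pytest
from hypothesis import given, strategies as st

from prionscore.combine import (
    CalibrationError,
    CombinationParams,
    ScoringConfig,
    calibrate,
    classify,
    combine,
    compare_sequences,
    score_record,
    single_mutation_scan,
)
from prionscore.estimators import PrionFeaturizer
from prionscore.seqio import ProteinRecord
from prionscore.synthetic import SyntheticPrLDSpec, generate_synthetic_prld


def synthetic_panel(n, seed0=100, length=100):
    return [generate_synthetic_prld(SyntheticPrLDSpec(length=length, seed=seed0 + i))
            for i in range(n)]


class TestCombine:
    def test_zero_terms_give_zero(self):
        p = CombinationParams(c_offset=0.0)
        assert combine(0.0, 0.0, p) == 0.0

    def test_monotone_in_amyloid_term_over_grid(self):
        p = CombinationParams()
        scores = [combine(0.1, a, p) for a in np.linspace(0, 100, 25)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_monotone_in_composition_term_over_grid(self):
        p = CombinationParams()
        scores = [combine(c, 40.0, p) for c in np.linspace(-1.5, 0.85, 25)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_floor_clamps_negative_blends(self):
        p = CombinationParams()
        assert combine(-1.5, 0.0, p) == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CombinationParams(w_c=-0.1)
        with pytest.raises(ValueError):
            CombinationParams(w_c=0.0, w_a=0.0)
        with pytest.raises(ValueError):
            CombinationParams(a_divisor=0.0)
        with pytest.raises(ValueError):
            CombinationParams(theta_low=0.8, theta_high=0.5)

    def test_params_file_round_trip(self, tmp_path):
        p = CombinationParams(w_c=0.37, w_a=0.61, intercept=0.02)
        path = tmp_path / "params.txt"
        p.to_file(path, provenance="unit test")
        assert CombinationParams.from_file(path) == p


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [(0.44, "low"), (0.45, "increased"), (0.78, "increased"), (0.79, "high"),
         (0.34, "low"), (0.93, "high"), (0.0, "low"), (1.30, "high")],
    )
    def test_threshold_boundaries(self, score, label):
        assert classify(score) == label

    @given(st.floats(min_value=0.0, max_value=5.0, allow_nan=False))
    def test_partition_is_exhaustive_and_exclusive(self, score):
        label = classify(score)
        assert label in {"low", "increased", "high"}
        assert (label == "low") == (score < 0.45)
        assert (label == "high") == (score > 0.78)


class TestCalibrate:
    def test_noiseless_recovery_of_known_weights(self):
        panel = synthetic_panel(12)
        truth = CombinationParams(w_c=0.31, w_a=0.84)
        anchors = [(r, score_record(r, truth).combined) for r in panel]
        fitted, residuals = calibrate(anchors, free=("w_c", "w_a"))
        assert fitted.w_c == pytest.approx(0.31, abs=1e-9)
        assert fitted.w_a == pytest.approx(0.84, abs=1e-9)
        assert np.abs(residuals).max() < 1e-9

    def test_single_weight_fit_matches_closed_form_ratio(self):
        panel = synthetic_panel(6, seed0=300)
        feats = PrionFeaturizer().transform(panel)
        params = CombinationParams(w_c=0.0, w_a=1.0)
        published = [0.2, 0.5, 0.8, 0.3, 0.6, 0.4]
        anchors = list(zip(panel, published))
        fitted, _ = calibrate(anchors, free=("w_a",), params=params)
        an = feats[:, 1] / params.a_divisor
        expected = float(np.dot(an, published) / np.dot(an, an))
        assert fitted.w_a == pytest.approx(expected, abs=1e-9)

    def test_rank_deficiency_detected(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=90, seed=1))
        anchors = [(rec, 0.2), (rec, 0.9)]  # identical features, distinct scores
        with pytest.raises(CalibrationError, match="rank"):
            calibrate(anchors, free=("w_c", "w_a"))

    def test_degenerate_anchor_sets_rejected(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=90, seed=2))
        with pytest.raises(CalibrationError):
            calibrate([(rec, 0.5)])
        other = generate_synthetic_prld(SyntheticPrLDSpec(length=90, seed=3))
        with pytest.raises(CalibrationError, match="distinct"):
            calibrate([(rec, 0.5), (other, 0.5)])

    def test_noisy_recovery_improves_with_anchor_count(self):
        """Weight RMSE shrinks as the anchor panel grows (sigma fixed)."""
        from prionscore.synthetic import synthetic_anchor_panel

        rng = np.random.default_rng(77)
        truth = CombinationParams(w_c=0.4, w_a=0.7)

        def rmse(n_anchors, reps=20):
            panel = synthetic_anchor_panel(n_anchors, seed=500)
            feats = PrionFeaturizer().transform(panel)
            clean = np.array([combine(c, a, truth) for c, a in feats])
            errs = []
            for _ in range(reps):
                noisy = clean + rng.normal(0, 0.05, n_anchors)
                fitted, _ = calibrate(list(zip(panel, noisy)), free=("w_c", "w_a"))
                errs.append((fitted.w_c - 0.4) ** 2 + (fitted.w_a - 0.7) ** 2)
            return np.sqrt(np.mean(errs))

        assert rmse(40) < rmse(6)


class TestCompareAndScan:
    def test_self_comparison_has_zero_delta(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=4))
        ref, variants = compare_sequences(rec, [rec])
        assert variants[0].delta == pytest.approx(0.0)
        assert variants[0].combined == pytest.approx(ref.combined)
        assert "does not change" in variants[0].impact

    def test_variant_order_preserved_under_permutation(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=5))
        vs = synthetic_panel(3, seed0=600)
        _, fwd = compare_sequences(rec, vs)
        _, rev = compare_sequences(rec, vs[::-1])
        assert [b.id for b in fwd] == [b.id for b in rev][::-1]
        assert {b.id: b.combined for b in fwd} == {b.id: b.combined for b in rev}

    def test_scan_returns_twenty_rows_wild_type_first(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=6))
        rows = single_mutation_scan(rec, 50)
        assert len(rows) == 20
        assert rows[0].id == rec.id
        assert rows[0].delta == 0.0
        subs = [r.id.rsplit("_", 1)[-1][-1] for r in rows[1:]]
        assert subs == sorted(subs)

    def test_scan_wild_type_row_matches_compare_self_row(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=6))
        scan_wt = single_mutation_scan(rec, 50)[0]
        _, [self_row] = compare_sequences(rec, [rec])
        assert scan_wt.combined == pytest.approx(self_row.combined)
        assert scan_wt.label == self_row.label

    def test_scan_rejects_out_of_range_position(self):
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=6))
        with pytest.raises(Exception):
            single_mutation_scan(rec, 101)

    def test_proline_to_phenylalanine_style_swap_raises_score(self):
        """Replacing an aggregation-blocking residue at the amyloid core with
        the most amyloidogenic one must not lower the combined score."""
        rec = generate_synthetic_prld(SyntheticPrLDSpec(length=100, seed=8))
        rows = single_mutation_scan(rec, score_record(rec).core_start + 3)
        by_res = {r.id[-1]: r for r in rows[1:]}
        wt = rows[0]
        if "F" in by_res:
            assert by_res["F"].combined >= wt.combined - 1e-9
        if "P" in by_res:
            assert by_res["P"].combined <= by_res["F"].combined + 1e-9
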