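"""scikit-learn style estimators wrapping the scoring pipeline.

``PrionFeaturizer`` turns protein records into the two-column feature
matrix (composition term, amyloid term) the combined score is built on;
``AggregationScorer`` is the calibrated linear combination itself, with
``fit`` performing the closed-form anchor calibration and ``predict``
returning combined scores.  Both compose with sklearn pipelines and
model selection; the module-level functions in :mod:`prionscore.combine`
are thin wrappers over the same machinery.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .combine import CalibrationError, CombinationParams, ScoringConfig, classify, score_record
from .seqio import ProteinRecord


def _as_records(X: Sequence) -> list[ProteinRecord]:
    records = []
    for i, x in enumerate(X):
        if isinstance(x, ProteinRecord):
            records.append(x)
        elif isinstance(x, str):
            records.append(ProteinRecord(id=f"seq{i + 1}", sequence=x.upper()))
        else:
            raise TypeError(f"expected ProteinRecord or str, got {type(x).__name__}")
    return records


class PrionFeaturizer(TransformerMixin, BaseEstimator):
    """Transform sequences into (composition, amyloid) feature pairs.

    A stateless transformer: ``fit`` only records the input dimension.
    ``transform`` returns an ``(n, 2)`` float array whose first column
    is the raw disorder-gated composition propensity and second column
    the 0-100 amyloid-core score.

    Parameters
    ----------
    window : int
        Odd window for composition and disorder averaging.
    core_length : int
        Length of the scored amyloid core.
    couple_region : bool
        Restrict the amyloid search to the disordered region around the
        composition argmax (whole-sequence fallback when gating fails).
    """

    def __init__(self, window: int = 41, core_length: int = 21, couple_region: bool = True):
        self.window = window
        self.core_length = core_length
        self.couple_region = couple_region

    def _config(self) -> ScoringConfig:
        return ScoringConfig(
            window=self.window, core_length=self.core_length,
            couple_region=self.couple_region,
        ).resolved()

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        config = self._config()
        params = CombinationParams()
        out = np.empty((len(X), 2), dtype=float)
        for i, rec in enumerate(_as_records(X)):
            b = score_record(rec, params, config)
            out[i, 0] = b.composition_raw
            out[i, 1] = b.amyloid_raw
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(["composition_term", "amyloid_term"], dtype=object)


class AggregationScorer(RegressorMixin, BaseEstimator):
    """Calibrated linear blend of composition and amyloid terms.

    ``fit(X, y)`` takes sequences (records or strings) and their
    published/measured combined scores and solves the free parameters in
    closed form; ``predict`` returns combined scores and
    ``predict_class`` the three-class labels (low / increased / high).

    Parameters
    ----------
    w_c, w_a : float
        Initial (or fixed) weights of the normalized composition and
        amyloid terms.
    fit_params : tuple of str
        Subset of ``{"w_c", "w_a", "intercept"}`` solved during ``fit``.
    theta_low, theta_high : float
        Classification thresholds (published values 0.45 and 0.78).
    """

    def __init__(
        self,
        w_c: float = 0.5,
        w_a: float = 0.5,
        intercept: float = 0.0,
        c_offset: float = 0.0,
        c_divisor: float | None = None,
        a_divisor: float = 100.0,
        floor: float = 0.0,
        theta_low: float = 0.45,
        theta_high: float = 0.78,
        fit_params: tuple = ("w_c", "w_a"),
        window: int = 41,
        core_length: int = 21,
        couple_region: bool = True,
    ):
        self.w_c = w_c
        self.w_a = w_a
        self.intercept = intercept
        self.c_offset = c_offset
        self.c_divisor = c_divisor
        self.a_divisor = a_divisor
        self.floor = floor
        self.theta_low = theta_low
        self.theta_high = theta_high
        self.fit_params = fit_params
        self.window = window
        self.core_length = core_length
        self.couple_region = couple_region

    def _combination_params(self) -> CombinationParams:
        kwargs = dict(
            w_c=self.w_c, w_a=self.w_a, intercept=self.intercept,
            c_offset=self.c_offset, a_divisor=self.a_divisor,
            floor=self.floor, theta_low=self.theta_low, theta_high=self.theta_high,
        )
        if self.c_divisor is not None:
            kwargs["c_divisor"] = self.c_divisor
        return CombinationParams(**kwargs)

    def _scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            window=self.window, core_length=self.core_length,
            couple_region=self.couple_region,
        ).resolved()

    def fit(self, X, y):
        from .combine import calibrate

        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        anchors = list(zip(_as_records(X), y))
        fitted, residuals = calibrate(
            anchors, free=tuple(self.fit_params),
            params=self._combination_params(), config=self._scoring_config(),
        )
        self.params_ = fitted
        self.w_c_ = fitted.w_c
        self.w_a_ = fitted.w_a
        self.intercept_ = fitted.intercept
        self.residuals_ = residuals
        self.n_features_in_ = 1
        return self

    def _params_for_predict(self) -> CombinationParams:
        check_is_fitted(self, "params_")
        return self.params_

    def predict(self, X) -> np.ndarray:
        params = self._params_for_predict()
        config = self._scoring_config()
        return np.array(
            [score_record(r, params, config).combined for r in _as_records(X)], dtype=float
        )

    def predict_class(self, X) -> np.ndarray:
        params = self._params_for_predict()
        return np.array([classify(s, params) for s in self.predict(X)], dtype=object)
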