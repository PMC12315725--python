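"""scikit-learn style estimators over the library stages.

These wrap the functional layer so the cleaning, connectivity and modeling
stages compose with sklearn pipelines and model selection: transformers
expose ``transform`` over per-subject data, model classes expose
``fit``/``predict`` with fitted attributes carrying a trailing underscore.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import connectivity as conn
from . import models as mdl
from . import preprocess as prep

__all__ = ["TimeSeriesCleaner", "ConnectivityExtractor",
           "SegregationExtractor", "AgeTrendModel", "ValenceBiasModel"]


class TimeSeriesCleaner(TransformerMixin, BaseEstimator):
    """Motion QC and denoising of per-subject ROI time series.

    ``transform`` maps a list of ``(ts_runs, motion_runs)`` pairs to a list
    of cleaning dicts (cleaned runs, frame selection, RMS-FD, masks);
    subjects failing the frame budget carry ``runs=None``.  Stateless
    (``fit`` only validates parameters), like a preprocessing transformer.
    """

    def __init__(self, tr=1.0, fd_threshold=0.2, min_segment=5,
                 min_run_frames=50, budget=800, low_hz=0.009, high_hz=0.08,
                 fd_lowpass_hz=0.1, interp_method="linear", random_state=0):
        self.tr = tr
        self.fd_threshold = fd_threshold
        self.min_segment = min_segment
        self.min_run_frames = min_run_frames
        self.budget = budget
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.fd_lowpass_hz = fd_lowpass_hz
        self.interp_method = interp_method
        self.random_state = random_state

    def fit(self, X, y=None):
        if not 0 < self.low_hz < self.high_hz < 0.5 / self.tr:
            raise ValueError("require 0 < low_hz < high_hz < Nyquist")
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else None
        return self

    def transform(self, X):
        self.fit(X)
        rng = np.random.default_rng(self.random_state)
        out = []
        for ts_runs, motion_runs in X:
            out.append(prep.clean_subject(
                ts_runs, motion_runs, tr=self.tr,
                fd_threshold=self.fd_threshold, min_segment=self.min_segment,
                min_run_frames=self.min_run_frames, budget=self.budget,
                low_hz=self.low_hz, high_hz=self.high_hz,
                fd_lowpass_hz=self.fd_lowpass_hz,
                interp_method=self.interp_method,
                tissue_rng=np.random.default_rng(rng.integers(2**31))))
        return out


class ConnectivityExtractor(TransformerMixin, BaseEstimator):
    """Cleaned runs -> thresholded Fisher-z matrices on the analysis ROIs."""

    def __init__(self, labels14=None, threshold=True):
        self.labels14 = labels14
        self.threshold = threshold

    def fit(self, X, y=None):
        if self.labels14 is None:
            raise ValueError("labels14 (the 14-network ROI labeling) is required")
        self.labels_, self.keep_ = conn.merge_networks(self.labels14)
        return self

    def transform(self, X):
        if not hasattr(self, "labels_"):
            self.fit(X)
        out = []
        for cleaned in X:
            if cleaned["runs"] is None:
                out.append(None)
                continue
            z, _ = conn.subject_connectivity(
                cleaned["runs"], cleaned["selection"].masks, self.labels14,
                threshold=self.threshold)
            out.append(z)
        return out


class SegregationExtractor(TransformerMixin, BaseEstimator):
    """Fisher-z matrices -> per-network measures (Zw, Zb, pairwise, S)."""

    def __init__(self, labels14=None):
        self.labels14 = labels14

    def fit(self, X, y=None):
        if self.labels14 is None:
            raise ValueError("labels14 (the 14-network ROI labeling) is required")
        self.labels_, self.keep_ = conn.merge_networks(self.labels14)
        return self

    def transform(self, X):
        if not hasattr(self, "labels_"):
            self.fit(X)
        return [None if z is None else conn.network_measures(z, self.labels_)
                for z in X]


class AgeTrendModel(RegressorMixin, BaseEstimator):
    """Linear-or-quadratic standardized-age model of one network measure.

    ``fit(X, y)`` takes a single-column X of standardized age; in ``auto``
    mode the quadratic term is kept only when significant at ``alpha``.
    """

    def __init__(self, quadratic="auto", alpha=0.05):
        self.quadratic = quadratic
        self.alpha = alpha

    def fit(self, X, y):
        a = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        self.result_ = mdl.fit_age_model(y, a, quadratic=self.quadratic)
        self.coef_ = self.result_.params.drop("Intercept").values
        self.intercept_ = float(self.result_.params["Intercept"])
        self.is_quadratic_ = "age_z2" in self.result_.terms
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        a = np.asarray(X, dtype=float).reshape(-1)
        out = self.intercept_ + self.result_.params["age_z"] * a
        if self.is_quadratic_:
            out = out + self.result_.params["age_z2"] * a**2
        return out


class ValenceBiasModel(RegressorMixin, BaseEstimator):
    """Valence bias from DMN pairwise connectivity with age forced in.

    ``fit(X, y)`` expects a DataFrame with an ``age_z`` column plus the
    candidate connectivity columns, and a bias outcome in percentage
    points.  Fitting runs AIC backward elimination (age never a candidate),
    then age-moderation screening; retained interactions get simple slopes
    and a Johnson-Neyman interval.

    Attributes: ``elimination_trace_``, ``selected_terms_``, ``result_``
    (final FitResult), ``interactions_``, ``moderation_``.
    """

    def __init__(self, alpha=0.05, change_in_estimate=None, age_scale=None):
        self.alpha = alpha
        self.change_in_estimate = change_in_estimate
        self.age_scale = age_scale

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if "age_z" not in X.columns:
            raise ValueError("X must contain an 'age_z' column")
        forced = X[["age_z"]]
        candidates = X.drop(columns="age_z")
        y = np.asarray(y, dtype=float)
        self.elimination_trace_, _ = mdl.backward_eliminate(
            y, candidates, forced, change_in_estimate=self.change_in_estimate)
        self.selected_terms_ = [t for t in self.elimination_trace_.final_terms
                                if t != "age_z"]
        self.result_, self.interactions_ = mdl.screen_interactions(
            y, X[self.selected_terms_], forced, alpha=self.alpha)
        self.moderation_ = {
            name: mdl.johnson_neyman(self.result_, name.split(":")[0], name,
                                     alpha=self.alpha, age_scale=self.age_scale)
            for name in self.interactions_}
        self.coef_ = self.result_.params.drop("Intercept").values
        self.intercept_ = float(self.result_.params["Intercept"])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = pd.DataFrame(X).copy()
        for name in self.interactions_:
            term, mod = name.split(":")
            X[name] = X[term] * X[mod]
        cols = [t for t in self.result_.terms if t != "Intercept"]
        return self.intercept_ + X[cols].values @ self.result_.params[cols].values
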