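"""Scikit-learn estimator wrapping the calibrate-freeze-score pipeline.

``PathwayActivityModel`` is a classifier: ``fit`` performs the full
calibration protocol on ground-truth labelled samples (per-probeset
discretisation thresholds, Laplace-smoothed CPT estimation, freezing),
``decision_function`` returns the pathway activity score (log2odds that the
transcription complex is active) and ``predict``/``predict_proba`` apply the
decision threshold / return the posterior.  It composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import calibration as _calibration
from .calibration import CalibrationSet
from .io import Sample
from .model import (
    ACTIVE,
    INACTIVE,
    PathwayModel,
    ProbesetNode,
    TargetGeneNode,
    evidence_from_intensities,
    infer_activity,
)

__all__ = ["PathwayActivityModel"]


class PathwayActivityModel(ClassifierMixin, BaseEstimator):
    """Bayesian-network pathway activity classifier.

    Parameters
    ----------
    skeleton:
        Optional uncalibrated :class:`~pathscore.model.PathwayModel` giving
        the gene/probeset structure.  When None, every input feature becomes
        its own up-regulated single-probeset target gene (a naive-Bayes-like
        flat signature).
    pseudocount:
        Laplace smoothing for CPT estimation.
    prior_active:
        Prior probability that the pathway is active; None keeps the
        skeleton's prior (0.5 for a flat skeleton).
    p_up_given_active, p_up_given_inactive:
        Relation-(i) probabilities used when building a flat skeleton.
    evidence_mode:
        "soft" (logistic weights) or "hard" (threshold discretisation).
    decision_threshold:
        log2odds threshold for :meth:`predict`; active iff score > threshold.

    Attributes
    ----------
    model_ : PathwayModel
        The frozen, calibrated network.
    classes_ : ndarray
        The two class labels; the entry corresponding to the pathway-active
        state is ``positive_class_``.
    """

    def __init__(
        self,
        skeleton: PathwayModel | None = None,
        *,
        pseudocount: float = 1.0,
        prior_active: float | None = None,
        p_up_given_active: float = 0.90,
        p_up_given_inactive: float = 0.10,
        evidence_mode: str = "soft",
        soft_scale: float = 1.0,
        decision_threshold: float = 0.0,
    ) -> None:
        self.skeleton = skeleton
        self.pseudocount = pseudocount
        self.prior_active = prior_active
        self.p_up_given_active = p_up_given_active
        self.p_up_given_inactive = p_up_given_inactive
        self.evidence_mode = evidence_mode
        self.soft_scale = soft_scale
        self.decision_threshold = decision_threshold

    # -- helpers ----------------------------------------------------------

    def _feature_names(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        X = np.asarray(X)
        return [f"ps{j}" for j in range(X.shape[1])]

    def _as_samples(self, X, feature_names: list[str], prefix: str) -> list[Sample]:
        if isinstance(X, pd.DataFrame):
            values = X.to_numpy(dtype=float)
            ids = [str(i) for i in X.index]
            if len(set(ids)) != len(ids):
                ids = [f"{prefix}{i}" for i in range(len(ids))]
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-dimensional (samples x probesets)")
            ids = [f"{prefix}{i}" for i in range(values.shape[0])]
        if values.shape[1] != len(feature_names):
            raise ValueError(
                f"X has {values.shape[1]} features, expected {len(feature_names)}"
            )
        samples = []
        for sid, row in zip(ids, values):
            intens = {
                ps: float(v)
                for ps, v in zip(feature_names, row)
                if not np.isnan(v)
            }
            samples.append(Sample(sid, intens))
        return samples

    def _flat_skeleton(self, feature_names: list[str]) -> PathwayModel:
        genes = [
            TargetGeneNode(
                gene_symbol=ps,
                direction="up_regulated",
                p_up_given_active=self.p_up_given_active,
                p_up_given_inactive=self.p_up_given_inactive,
                probesets=[ProbesetNode(probeset_id=ps, soft_scale=self.soft_scale)],
            )
            for ps in feature_names
        ]
        return PathwayModel(
            pathway_name="pathway",
            target_genes=genes,
            prior_active=0.5 if self.prior_active is None else self.prior_active,
        )

    def _resolve_labels(self, y) -> tuple[np.ndarray, object]:
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required, got {list(classes)}")
        if set(map(str, classes)) == {ACTIVE, INACTIVE}:
            positive = classes[[str(c) == ACTIVE for c in classes].index(True)]
        else:
            positive = classes[1]
        return classes, positive

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        """Calibrate on labelled samples and freeze the model.

        ``X`` is samples x probesets (DataFrame columns name the probesets);
        ``y`` holds two classes — the strings "active"/"inactive", or any
        two labels of which the larger (per numpy ordering) is taken as the
        pathway-active class.
        """
        feature_names = self._feature_names(X)
        samples = self._as_samples(X, feature_names, prefix="train_")
        self.classes_, self.positive_class_ = self._resolve_labels(y)
        y = np.asarray(y)
        if len(samples) != y.size:
            raise ValueError("X and y have inconsistent lengths")
        labels = {
            s.sample_id: (ACTIVE if label == self.positive_class_ else INACTIVE)
            for s, label in zip(samples, y)
        }
        calib = CalibrationSet(samples=samples, labels=labels)
        skeleton = self.skeleton.copy() if self.skeleton is not None else self._flat_skeleton(feature_names)
        if self.skeleton is not None:
            missing = [ps for ps in skeleton.probeset_ids if ps not in feature_names]
            if missing:
                raise ValueError(f"X lacks skeleton probesets: {missing}")
            if self.prior_active is not None:
                skeleton.set_prior(self.prior_active)
        skeleton = _calibration.set_discretization_thresholds(skeleton, calib)
        fitted = _calibration.fit_probeset_cpts(skeleton, calib, self.pseudocount)
        self.model_ = _calibration.freeze(fitted)
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = len(feature_names)
        return self

    def activity_results(self, X):
        """Full per-sample :class:`~pathscore.model.ActivityResult` objects."""
        check_is_fitted(self, "model_")
        feature_names = list(self.feature_names_in_)
        samples = self._as_samples(X, feature_names, prefix="test_")
        results = []
        for s in samples:
            evidence = evidence_from_intensities(
                self.model_, s.intensities, mode=self.evidence_mode
            )
            results.append(infer_activity(self.model_, evidence))
        return results

    def decision_function(self, X):
        """Pathway activity score (log2odds of the active state) per sample."""
        return np.array([r.log2odds for r in self.activity_results(X)])

    def predict_proba(self, X):
        p_active = np.array([r.probability_active for r in self.activity_results(X)])
        proba = np.column_stack([1.0 - p_active, p_active])
        # column order must follow classes_
        if self.classes_[1] != self.positive_class_:
            proba = proba[:, ::-1]
        return proba

    def predict(self, X):
        scores = self.decision_function(X)
        active = scores > self.decision_threshold
        negative = next(c for c in self.classes_ if c != self.positive_class_)
        return np.where(active, self.positive_class_, negative)
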