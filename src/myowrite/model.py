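"""Model/Results front-end for one intra-subject recognition experiment.

``WordRecognitionModel`` wraps a labelled feature matrix and a classifier
choice; ``fit()`` performs the balanced 70/30 split, 5-fold
cross-validation on the training share, final training and test-set
prediction, and returns a ``WordRecognitionResults`` carrying metrics with
and without majority-vote smoothing plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify, postprocess
from .features import FeatureMatrix, FeatureParams, build_feature_matrix
from .preprocess import FilterSpec, bandpass, detect_segments
from .synth import EmgRecording


class WordRecognitionModel:
    """Intra-subject word recognition from a windowed EMG feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Labelled windows x (features x channels) table.
    classifier : {"KNN", "SVM", "LDA"}
    train_frac, n_folds : split design (balanced per class).
    mv_m : even vote count of the majority-voting post-processor.
    C, k : SVM cost and KNN neighbour count.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        classifier: str = "KNN",
        train_frac: float = 0.7,
        n_folds: int = 5,
        mv_m: int = 4,
        C: float = 1.0,
        k: int = 2,
    ):
        self.features = features
        self.classifier = classifier.upper()
        self.train_frac = train_frac
        self.n_folds = n_folds
        self.mv_m = mv_m
        self.C = C
        self.k = k

    @classmethod
    def from_recordings(
        cls,
        recordings: list[EmgRecording],
        feature_set: str = "ALL",
        classifier: str = "KNN",
        params: FeatureParams = FeatureParams(),
        filter_spec: FilterSpec = FilterSpec(),
        use_truth_segments: bool = False,
        **kwargs,
    ) -> "WordRecognitionModel":
        """Band-pass, segment and featurise raw recordings, then build the model."""
        filtered = [bandpass(r, filter_spec) for r in recordings]
        if use_truth_segments:
            segments = [r.truth_segments or [] for r in filtered]
        else:
            segments = [detect_segments(r) for r in filtered]
        fm = build_feature_matrix(filtered, segments, feature_set, params)
        return cls(fm, classifier=classifier, **kwargs)

    def _hyper(self) -> dict:
        if self.classifier == "SVM":
            return {"C": self.C}
        if self.classifier == "KNN":
            return {"k": self.k}
        return {}

    def fit(self, seed: int = 0) -> "WordRecognitionResults":
        fm = self.features
        plan = classify.balanced_split(
            fm.y, train_frac=self.train_frac, n_folds=self.n_folds, seed=seed
        )
        hyper = self._hyper()
        cv_acc = classify.cross_validate(
            self.classifier, fm.X, fm.y, plan, **hyper
        )
        model = classify.fit(
            self.classifier, fm.X.iloc[plan.train_indices], fm.y[plan.train_indices],
            **hyper,
        )
        X_test = fm.X.iloc[plan.test_indices].reset_index(drop=True)
        prov_test = fm.provenance.iloc[plan.test_indices].reset_index(drop=True)
        stream = classify.predict(model, X_test, provenance=prov_test)
        y_test = fm.y[plan.test_indices][stream.provenance["source_row"].to_numpy()]
        labels = np.unique(fm.y)
        metrics = postprocess.score(y_test, stream, labels=labels)
        smoothed = postprocess.majority_vote(stream, M=self.mv_m)
        metrics_mv = postprocess.score(y_test, smoothed, labels=labels)
        return WordRecognitionResults(
            model=self,
            trained=model,
            split=plan,
            cv_accuracies=cv_acc,
            y_test=y_test,
            stream=stream,
            stream_mv=smoothed,
            metrics=metrics,
            metrics_mv=metrics_mv,
        )


@dataclass
class WordRecognitionResults:
    """Fit artefacts: split plan, trained classifier, streams and metrics."""

    model: WordRecognitionModel
    trained: classify.TrainedModel
    split: classify.SplitPlan
    cv_accuracies: list[float]
    y_test: np.ndarray
    stream: postprocess.DecisionStream
    stream_mv: postprocess.DecisionStream
    metrics: postprocess.MetricsReport
    metrics_mv: postprocess.MetricsReport

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    @property
    def accuracy_mv(self) -> float:
        return self.metrics_mv.accuracy

    def timing(self) -> postprocess.MvTiming:
        return postprocess.mv_timing(self.model.mv_m, self.stream.update_period)

    def predictions_frame(self) -> pd.DataFrame:
        out = self.stream.provenance.copy()
        out["true_label"] = self.y_test
        out["predicted_label"] = self.stream.votes
        out["predicted_label_mv"] = self.stream_mv.votes
        return out

    def summary(self) -> str:
        m, mv = self.metrics, self.metrics_mv
        t = self.timing()
        lines = [
            "Word recognition results",
            "=" * 58,
            f"classifier      : {self.model.classifier} {self.model._hyper()}",
            f"feature set     : {self.model.features.feature_set.name} "
            f"({self.model.features.X.shape[1]} columns)",
            f"windows         : {self.model.features.n_windows} total, "
            f"{len(self.split.train_indices)} train / {len(self.split.test_indices)} test",
            f"classes         : {len(np.unique(self.model.features.y))}",
            f"cv accuracy     : {np.mean(self.cv_accuracies):.3f} "
            f"(folds: {', '.join(f'{a:.3f}' for a in self.cv_accuracies)})",
            "-" * 58,
            f"{'':16s}  {'raw':>8s}  {'MV':>8s}",
            f"{'accuracy':16s}  {m.accuracy:8.3f}  {mv.accuracy:8.3f}",
            f"{'F1 (macro)':16s}  {m.f1_macro:8.3f}  {mv.f1_macro:8.3f}",
            f"{'MCC (macro)':16s}  {m.mcc_macro:8.3f}  {mv.mcc_macro:8.3f}",
            "-" * 58,
            f"MV timing       : M={self.model.mv_m}, input {t.input_rate:.2f} Hz, "
            f"latency {t.latency * 1e3:.0f} ms, output {t.output_rate:.2f} Hz",
        ]
        return "\n".join(lines)
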