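"""The bias-correction classifier: training, cross-validation, genome scan.

The production model is an elastic-net penalized logistic regression
(mixing parameter l1_ratio = 0.5, up to 10,000 solver iterations) on
standardized window-profile features; random-forest and gradient-boosting
baselines are available through the same interface.  The trained model is
applied to every 200 bp bin genome-wide; the per-bin probability of being a
genuinely marked region is the corrected signal.  Scores below 0.5 may be
floored to 0 for browser visualization.

Feature standardization uses means/SDs computed on the training rows and is
stored with the model: elastic-net penalties are scale-sensitive, and
prediction must standardize new data with the *training* statistics.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, FeatureRecipe, featurize_bins
from .tracks import GenomeLayout, GenomicBin, SignalTrack, tile_genome

MODEL_FORMAT_VERSION = 1
MODEL_KINDS = ("logistic_elasticnet", "random_forest", "gbm")

# registry so further model families (e.g. neural nets) can be plugged in
_ESTIMATOR_BUILDERS = {}


def register_model_kind(name):
    def deco(fn):
        _ESTIMATOR_BUILDERS[name] = fn
        return fn

    return deco


@register_model_kind("logistic_elasticnet")
def _build_lr(seed, C=1.0, l1_ratio=0.5, max_iter=10000, **_):
    return LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=l1_ratio,
        C=C,
        max_iter=max_iter,
        random_state=seed,
    )


@register_model_kind("random_forest")
def _build_rf(seed, n_estimators=100, **_):
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)


@register_model_kind("gbm")
def _build_gbm(seed, **_):
    return GradientBoostingClassifier(random_state=seed)


@dataclass
class BiasModel:
    """Trained classifier + feature recipe + standardization statistics."""

    model_kind: str
    estimator: object
    recipe: FeatureRecipe
    feature_mean: np.ndarray | None
    feature_sd: np.ndarray | None
    mark_name: str = ""
    training_provenance: dict = field(default_factory=dict)

    @property
    def standardize(self) -> bool:
        return self.feature_mean is not None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.feature_mean) / self.feature_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Probability that each row is a genuinely marked region (in [0, 1])."""
        proba = self.estimator.predict_proba(self._transform(np.asarray(X)))[:, 1]
        return proba


@dataclass
class ScoreTrack:
    """Per-bin corrected scores over the genome-wide 200 bp tiling."""

    bins: list[GenomicBin]
    scores: np.ndarray
    floored: bool = False
    floor_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.scores):
            raise ValueError("bins and scores differ in length")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def floor(self) -> "ScoreTrack":
        """Zero out sub-threshold scores (visualization convention)."""
        s = np.where(self.scores < self.floor_threshold, 0.0, self.scores)
        return ScoreTrack(self.bins, s, floored=True, floor_threshold=self.floor_threshold)


@dataclass
class CVReport:
    k: int
    fold_accuracies: list[float]
    mean_accuracy: float
    params: dict

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.fold_accuracies):
            raise ValueError("accuracies must lie in [0, 1]")


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    seed: int,
    standardize: bool,
    **hyperparams,
):
    if model_kind not in _ESTIMATOR_BUILDERS:
        raise ValueError(f"unknown model kind {model_kind!r}; known: {sorted(_ESTIMATOR_BUILDERS)}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    mean = sd = None
    Xt = X
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant features pass through as 0
        Xt = (X - mean) / sd
    est = _ESTIMATOR_BUILDERS[model_kind](seed, **hyperparams)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(Xt, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                f"{model_kind} did not converge within the iteration budget",
                stacklevel=2,
            )
    return est, mean, sd, converged


def train(
    features: FeatureMatrix,
    model_kind: str = "logistic_elasticnet",
    seed: int = 0,
    standardize: bool = True,
    mark_name: str = "",
    **hyperparams,
) -> BiasModel:
    """Fit a bias classifier on a labeled feature matrix.

    Deterministic given ``seed``.  Standardization statistics are computed on
    the training rows and stored with the model.
    """
    if features.y is None:
        raise ValueError("feature matrix carries no labels")
    est, mean, sd, converged = _fit(
        features.X, features.y, model_kind, seed, standardize, **hyperparams
    )
    return BiasModel(
        model_kind=model_kind,
        estimator=est,
        recipe=features.recipe,
        feature_mean=mean,
        feature_sd=sd,
        mark_name=mark_name,
        training_provenance={
            "n_rows": int(len(features.X)),
            "n_true": int((features.y == 1).sum()),
            "seed": int(seed),
            "standardize": standardize,
            "hyperparams": dict(hyperparams),
            "converged": converged,
        },
    )


def cross_validate(
    features: FeatureMatrix,
    model_kind: str = "logistic_elasticnet",
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
    **hyperparams,
) -> CVReport:
    """Stratified k-fold cross-validation reporting per-fold accuracy.

    Standardization statistics are re-estimated inside each training fold so
    no information leaks from held-out rows.
    """
    if features.y is None:
        raise ValueError("feature matrix carries no labels")
    y = features.y
    class_counts = pd.Series(y).value_counts()
    if k > class_counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {class_counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(features.X, y):
        est, mean, sd, _ = _fit(
            features.X[train_idx], y[train_idx], model_kind, seed, standardize, **hyperparams
        )
        Xt = features.X[test_idx]
        if mean is not None:
            Xt = (Xt - mean) / sd
        accs.append(float((est.predict(Xt) == y[test_idx]).mean()))
    return CVReport(
        k=k,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        params={"model_kind": model_kind, "seed": seed, **hyperparams},
    )


def predict_genome(
    model: BiasModel,
    tracks: Mapping[str, SignalTrack],
    layout: GenomeLayout,
    fasta=None,
    floor: bool = False,
    chunk_rows: int = 100_000,
) -> ScoreTrack:
    """Score every 200 bp bin of the genome with the trained model."""
    missing = [r for r in model.recipe.ordered_roles if r not in tracks]
    if missing:
        raise ValueError(f"missing tracks for roles: {missing}")
    if any(t.layout.included_chroms != layout.included_chroms for t in tracks.values()):
        warnings.warn("track layouts differ from the prediction layout")
    bins = tile_genome(layout, model.recipe.bin_width)
    scores = np.empty(len(bins))
    for lo in range(0, len(bins), chunk_rows):
        chunk = bins[lo : lo + chunk_rows]
        X = featurize_bins(chunk, tracks, model.recipe, fasta=fasta)
        scores[lo : lo + len(chunk)] = model.predict(X)
    st = ScoreTrack(bins, scores)
    return st.floor() if floor else st


def predict_bins(
    model: BiasModel,
    bins: Sequence[GenomicBin],
    tracks: Mapping[str, SignalTrack],
    fasta=None,
) -> np.ndarray:
    """Score an explicit list of bins (subset of the genome tiling)."""
    X = featurize_bins(list(bins), tracks, model.recipe, fasta=fasta)
    return model.predict(X)


def save_model(model: BiasModel, path) -> None:
    payload = {
        "format": "tn5shadow-bias-model",
        "format_version": MODEL_FORMAT_VERSION,
        "model_kind": model.model_kind,
        "estimator": model.estimator,
        "recipe": model.recipe.to_dict(),
        "feature_mean": model.feature_mean,
        "feature_sd": model.feature_sd,
        "mark_name": model.mark_name,
        "training_provenance": model.training_provenance,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> BiasModel:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except Exception as exc:
        raise ValueError(f"{path} is not a readable model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "tn5shadow-bias-model":
        raise ValueError(f"{path} is not a tn5shadow model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload.get('format_version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return BiasModel(
        model_kind=payload["model_kind"],
        estimator=payload["estimator"],
        recipe=FeatureRecipe.from_dict(payload["recipe"]),
        feature_mean=payload["feature_mean"],
        feature_sd=payload["feature_sd"],
        mark_name=payload["mark_name"],
        training_provenance=payload["training_provenance"],
    )
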