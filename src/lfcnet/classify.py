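"""Guilty-vs-innocent trial classification on network coherence features.

Each trial's feature vector collects its P300-processing-period (3#)
divisional WC values on the band's selected lying connections, so the
feature dimension equals the network's connection count.  Classification
uses an RBF-kernel SVM with an exhaustive (C, gamma) grid -- C in
2^-5..2^5 (11 points), gamma in 2^-5..2^12 (18 points) -- tuned per outer
fold by stratified 5-fold cross-validation inside the training fold, then
evaluated with stratified 10-fold cross-validation over trials.

Sensitivity is the fraction of guilty trials classified guilty;
specificity the analogous fraction of innocent trials.  "Training"
figures are resubstitution on each training fold.  Feature columns are
standardised with statistics fitted on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE = "guilty"
NEGATIVE = "innocent"


@dataclass(frozen=True)
class ClassifierConfig:
    c_grid: tuple[float, ...] = tuple(2.0**k for k in range(-5, 6))  # 11 values
    gamma_grid: tuple[float, ...] = tuple(2.0**k for k in range(-5, 13))  # 18
    folds: int = 10
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (self.c_grid, self.gamma_grid):
            if len(grid) == 0 or list(grid) != sorted(grid):
                raise ValueError("grids must be nonempty and strictly increasing")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FeatureTable:
    """Trials x selected-connection WC features with labels and subjects."""

    X: np.ndarray  # (n_trials, n_connections), values in [0, 1]
    y: np.ndarray  # labels, 'guilty'/'innocent'
    subjects: np.ndarray
    connections: list[str]  # column pair labels

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.connections):
            raise ValueError("X must be trials x connections")
        if len(self.y) != len(self.X) or len(self.subjects) != len(self.X):
            raise ValueError("labels/subjects must align with rows")


def extract_features(
    divisional: pd.DataFrame,
    connections: list[tuple[str, str]] | list[str],
    band: str,
    period: str = "3#",
) -> FeatureTable:
    """Per-trial WC values on the selected connections of one band.

    One row per trial; column j is the trial's ``period`` WC on
    connection j.  Raises on an empty connection list (empty network).
    """
    if len(connections) == 0:
        raise ValueError("empty network: no connections to extract features from")
    labels = [c if isinstance(c, str) else f"{c[0]}-{c[1]}" for c in connections]
    sub = divisional[
        (divisional["band"] == band)
        & (divisional["period"] == period)
        & (divisional["pair"].isin(labels))
    ]
    wide = sub.pivot_table(index="trial", columns="pair", values="wc")
    missing = [l for l in labels if l not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"divisional table lacks values for connections {missing}")
    wide = wide[labels]
    meta = (
        divisional.drop_duplicates("trial").set_index("trial").loc[wide.index]
    )
    return FeatureTable(
        X=wide.to_numpy(dtype=np.float64),
        y=meta["group"].to_numpy(),
        subjects=meta["subject"].to_numpy(),
        connections=labels,
    )


def _make_model(C: float, gamma: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma, cache_size=200)),
        ]
    )


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    rng_seed: int,
) -> tuple[Pipeline, tuple[float, float]]:
    """Grid search scored by inner stratified CV, refit on the full fold.

    Ties are broken toward the smallest C, then the smallest gamma (the
    grid is scanned C-major in ascending order).
    """
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training fold contains a single class")
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=rng_seed
    )
    combos = [(C, g) for C in config.c_grid for g in config.gamma_grid]
    correct = np.zeros(len(combos), dtype=int)
    for tr, va in inner.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xva = scaler.transform(X[tr]), scaler.transform(X[va])
        for k, (C, gamma) in enumerate(combos):
            svm = SVC(kernel="rbf", C=C, gamma=gamma, cache_size=200)
            svm.fit(Xtr, y[tr])
            correct[k] += int((svm.predict(Xva) == y[va]).sum())
    # argmax keeps the first maximum: smaller C, then smaller gamma, wins ties
    C, gamma = combos[int(np.argmax(correct))]
    model = _make_model(C, gamma)
    model.fit(X, y)
    return model, (C, gamma)


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) in percent."""
    pos = y_true == POSITIVE
    neg = y_true == NEGATIVE
    sens = 100.0 * (y_pred[pos] == POSITIVE).mean() if pos.any() else np.nan
    spec = 100.0 * (y_pred[neg] == NEGATIVE).mean() if neg.any() else np.nan
    return float(sens), float(spec)


@dataclass
class ClassificationReport:
    """Per-fold and aggregate training/testing sensitivity and specificity."""

    folds: pd.DataFrame  # fold, C, gamma, train_sens, train_spec, test_sens, test_spec

    def aggregate(self) -> pd.DataFrame:
        cols = ["train_sens", "train_spec", "test_sens", "test_spec"]
        return self.folds[cols].agg(["mean", "std"])

    @property
    def test_sensitivity(self) -> float:
        return float(self.folds["test_sens"].mean())

    @property
    def test_specificity(self) -> float:
        return float(self.folds["test_spec"].mean())

    def table_text(self) -> str:
        agg = self.aggregate()

        def ms(col):
            return f"{agg.loc['mean', col]:.2f} +- {agg.loc['std', col]:.2f}"

        return (
            "phase      sensitivity       specificity\n"
            f"training   {ms('train_sens'):<17} {ms('train_spec')}\n"
            f"testing    {ms('test_sens'):<17} {ms('test_spec')}\n"
        )

    def to_dict(self) -> dict:
        agg = self.aggregate()
        return {
            "per_fold": self.folds.to_dict(orient="records"),
            "mean": {c: float(agg.loc["mean", c]) for c in agg.columns},
            "sd": {c: float(agg.loc["std", c]) for c in agg.columns},
        }


def cross_validate(
    features: FeatureTable, config: ClassifierConfig | None = None
) -> ClassificationReport:
    """Stratified 10-fold CV with per-fold grid tuning.

    Every trial appears in exactly one test fold; per-fold training rates
    are resubstitution on the training fold.  Deterministic for a fixed
    (features, seed).
    """
    config = config or ClassifierConfig()
    counts = pd.Series(features.y).value_counts()
    if (counts < config.folds).any():
        raise ValueError("need at least `folds` trials per class")
    outer = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    rows = []
    for f, (tr, te) in enumerate(outer.split(features.X, features.y)):
        model, (C, gamma) = tune_and_train(
            features.X[tr], features.y[tr], config, rng_seed=config.seed + f
        )
        tr_sens, tr_spec = _rates(features.y[tr], model.predict(features.X[tr]))
        te_sens, te_spec = _rates(features.y[te], model.predict(features.X[te]))
        rows.append(
            {
                "fold": f,
                "C": C,
                "gamma": gamma,
                "train_sens": tr_sens,
                "train_spec": tr_spec,
                "test_sens": te_sens,
                "test_spec": te_spec,
            }
        )
    return ClassificationReport(folds=pd.DataFrame(rows))
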