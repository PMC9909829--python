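"""Mass classification: feature selection, SVM training, grouped LOO-CV.

The classifier operates on per-pixel feature vectors but is evaluated per
mass: cross-validation withholds all 25 site pixels of one mass together
(they share a patient and a pathology label, so splitting them would leak),
trains on the remaining masses, predicts the held-out pixels, and
aggregates the pixel votes into a single high-risk/low-risk call.

Feature selection is filter-style: the absolute standardized mean
difference between classes, computed on mass-level feature averages so
that a mass with 25 pixels does not count 25 times.  Inside every CV fold,
normalization statistics, the feature ranking and the classifier are all
refit on the training masses only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "SelectionResult",
    "ClassifierSpec",
    "MassPrediction",
    "rank_features",
    "train_classifier",
    "aggregate_mass_call",
    "grouped_loo_cv",
]

logger = logging.getLogger(__name__)

_SCORE_EPS = 1e-12  # keeps a perfect separator's score finite

LABEL_CODES = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class SelectionResult:
    """Ranked features with scores and the selected top-k subset."""

    ranked: tuple            # feature names, best first
    scores: tuple            # matching scores
    selected: tuple          # top-k names

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.ranked):
            raise ValueError("selected features must be a subset of ranked")
        if not all(np.isfinite(s) for s in self.scores):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class ClassifierSpec:
    """Margin-classifier settings; defaults suit ~4 features, ~10^3 pixel rows."""

    kernel: str = "linear"
    c: float = 1.0
    class_weight: str | None = None  # None or "balanced"
    n_features: int = 4
    per_fold_selection: bool = True  # refit ranking inside each CV fold

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if not self.c > 0:
            raise ValueError("regularization strength must be > 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass(frozen=True)
class MassPrediction:
    """Aggregated call for one mass."""

    mass_id: str
    dog_id: str
    true_label: str           # "benign" | "malignant"
    votes: int                # pixels predicted malignant
    n_pixels: int
    malignant_fraction: float
    predicted: str            # "high-risk" | "low-risk"

    def __post_init__(self) -> None:
        if self.votes > self.n_pixels:
            raise ValueError("votes cannot exceed pixel count")

    @property
    def predicted_label(self) -> str:
        return "malignant" if self.predicted == "high-risk" else "benign"

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


def rank_features(table: FeatureTable, k: int = 4) -> SelectionResult:
    """Rank features by |standardized mean difference| at mass level.

    Pixel values are averaged per mass first; the score is
    |mean_malignant - mean_benign| / pooled s.d. of the mass-level values.
    Ties break lexicographically by feature name.  Requires at least two
    masses per class.
    """
    labels = table.mass_labels()
    classes = labels.value_counts()
    if len(classes) < 2:
        raise ValueError("feature ranking needs both classes present")

    mass_means = table.data.groupby("mass_id", sort=True)[table.feature_columns].mean()
    mal = mass_means.loc[labels[labels == "malignant"].index]
    ben = mass_means.loc[labels[labels == "benign"].index]
    diff = (mal.mean() - ben.mean()).abs()
    n1, n0 = len(mal), len(ben)
    # a singleton class contributes no variance (ddof=1 would give NaN)
    pooled_var = (
        (n1 - 1) * mal.var(ddof=1).fillna(0.0)
        + (n0 - 1) * ben.var(ddof=1).fillna(0.0)
    ) / max(n1 + n0 - 2, 1)
    pooled_sd = np.sqrt(pooled_var)
    scores = diff / (pooled_sd + _SCORE_EPS)
    scores = scores.fillna(0.0)

    order = sorted(scores.index, key=lambda name: (-scores[name], name))
    k = min(k, len(order))
    return SelectionResult(
        ranked=tuple(order),
        scores=tuple(float(scores[name]) for name in order),
        selected=tuple(order[:k]),
    )


def train_classifier(x: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> SVC:
    """Fit the maximum-margin classifier on pixel rows (y: 0 benign, 1 malignant)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = SVC(kernel=spec.kernel, C=spec.c, class_weight=spec.class_weight)
    model.fit(np.asarray(x, dtype=float), y)
    return model


def aggregate_mass_call(
    pixel_predictions: np.ndarray,
    mass_id: str,
    dog_id: str,
    true_label: str,
    tau: float = 0.5,
) -> MassPrediction:
    """Combine pixel votes into a mass-level high-risk/low-risk call.

    The mass is called high-risk iff the malignant-vote fraction is >= tau;
    a fraction exactly at the threshold goes high-risk, so ties err toward
    flagging possible malignancy rather than clearing it.
    """
    votes_arr = np.asarray(pixel_predictions, dtype=int)
    if votes_arr.size == 0:
        raise ValueError("need at least one pixel prediction")
    votes = int(votes_arr.sum())
    n = int(votes_arr.size)
    fraction = votes / n
    predicted = "high-risk" if fraction >= tau else "low-risk"
    return MassPrediction(
        mass_id=mass_id,
        dog_id=dog_id,
        true_label=true_label,
        votes=votes,
        n_pixels=n,
        malignant_fraction=fraction,
        predicted=predicted,
    )


def grouped_loo_cv(
    table: FeatureTable,
    spec: ClassifierSpec = ClassifierSpec(),
    tau: float = 0.5,
    return_audit: bool = False,
):
    """Leave-one-mass-out cross-validation over a control-integrated table.

    One iteration per mass: the held-out mass's pixels form the test set;
    normalization statistics, the feature ranking and the classifier are fit
    on the remaining masses only, the test pixels are transformed with the
    training statistics, predicted, and aggregated into a mass call.  A
    training fold that collapses to a single class predicts that class and
    logs a warning.  Output order (and content) is independent of the input
    row order.

    With ``return_audit=True`` also returns, per fold, the train/test row
    indices actually used, for leakage audits.
    """
    if table.state != "control-integrated":
        raise ValueError("grouped_loo_cv expects a control-integrated table")
    data = table.data
    mass_ids = sorted(data["mass_id"].unique())
    if len(mass_ids) < 3:
        raise ValueError("grouped LOO-CV needs at least 3 masses")
    all_labels = table.mass_labels()
    if all_labels.nunique() < 2:
        raise ValueError("grouped LOO-CV needs both classes in the cohort")

    fixed_selection = None
    if not spec.per_fold_selection:
        # single ranking on the full table (mirrors a published final
        # feature set; per-fold refit is the leakage-free default)
        fixed_selection = rank_features(table, spec.n_features)

    predictions: list[MassPrediction] = []
    audit: list[dict] = []
    for test_mass in mass_ids:
        test_rows = data.index[data["mass_id"] == test_mass]
        train_rows = data.index[data["mass_id"] != test_mass]
        assert len(test_rows.intersection(train_rows)) == 0
        train_table = FeatureTable(data.loc[train_rows].copy(), table.state)
        test_table = FeatureTable(data.loc[test_rows].copy(), table.state)
        dog_id = test_table.data["dog_id"].iloc[0]
        true_label = test_table.data["label"].iloc[0]

        train_labels = train_table.mass_labels()
        if train_labels.nunique() < 2:
            only = train_labels.unique()[0]
            logger.warning(
                "fold %s: training masses all %s; predicting the training class",
                test_mass, only,
            )
            pixel_pred = np.full(len(test_rows), LABEL_CODES[only])
        else:
            # ranking by standardized mean difference is invariant to the
            # per-feature affine z-score, so it is computed on the raw
            # control-integrated values; only the selected columns are then
            # z-scored with training statistics
            if fixed_selection is not None:
                selection = fixed_selection
            else:
                selection = rank_features(train_table, spec.n_features)
            cols = list(selection.selected)
            x_train = train_table.data[cols].to_numpy(dtype=float)
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0, ddof=1)
            sd_safe = np.where(sd > 0, sd, 1.0)
            x_train = (x_train - mu) / sd_safe
            x_test = (test_table.data[cols].to_numpy(dtype=float) - mu) / sd_safe
            zero_var = sd == 0
            x_train[:, zero_var] = 0.0
            x_test[:, zero_var] = 0.0
            y_train = train_table.data["label"].map(LABEL_CODES).to_numpy()
            model = train_classifier(x_train, y_train, spec)
            pixel_pred = model.predict(x_test)

        predictions.append(
            aggregate_mass_call(pixel_pred, test_mass, dog_id, true_label, tau)
        )
        if return_audit:
            audit.append(
                {"test_mass": test_mass,
                 "test_rows": list(test_rows),
                 "train_rows": list(train_rows)}
            )
    if return_audit:
        return predictions, audit
    return predictions
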