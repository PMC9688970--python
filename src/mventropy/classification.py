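"""SVM texture classification on multiscale entropy features.

The evaluation harness follows the standard protocol for entropy-based
texture descriptors: each image is reduced to its multiscale entropy
profile, an SVM is trained on a random stratified train/test split of the
profiles, and the accuracy (percentage of correctly classified test images)
is averaged over repeated splits.

Features are standardized inside each split using training statistics only,
so no test information leaks into the fit.  Rows containing an undefined
entropy value are excluded up front (and counted in the report) rather than
imputed: an undefined sample entropy carries no texture information to fill
in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError
from .multiscale import MultiscaleProfile

__all__ = ["FeatureTable", "ClassificationReport", "split", "evaluate"]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix with ids and class labels.

    Build one with :meth:`from_profiles` to apply the undefined-row
    exclusion policy, or directly from arrays.
    """

    ids: tuple[str, ...]
    labels: tuple[str, ...]
    features: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.float64)
        if feats.ndim != 2:
            raise ParameterError("features must be a 2-D (samples x features) array")
        if not (len(self.ids) == len(self.labels) == feats.shape[0]):
            raise ParameterError("ids, labels and feature rows must align")
        if np.isnan(feats).any():
            raise ParameterError(
                "undefined (NaN) feature values may not enter the classifier; "
                "use FeatureTable.from_profiles to exclude such rows"
            )
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        counts = pd.Series(self.labels).value_counts()
        if len(counts) < 2:
            raise ParameterError("need at least 2 classes")
        if counts.min() < 2:
            raise ParameterError(
                f"every class needs >= 2 samples; smallest has {counts.min()}"
            )

    @classmethod
    def from_profiles(
        cls,
        ids,
        labels,
        profiles: "list[MultiscaleProfile] | np.ndarray",
    ) -> "FeatureTable":
        """Assemble a table from multiscale profiles, dropping undefined rows."""
        if len(profiles) and isinstance(profiles[0], MultiscaleProfile):
            rows = np.vstack([p.values for p in profiles])
        else:
            rows = np.asarray(profiles, dtype=np.float64)
        keep = ~np.isnan(rows).any(axis=1)
        excluded = int((~keep).sum())
        return cls(
            ids=tuple(np.asarray(ids, dtype=object)[keep]),
            labels=tuple(np.asarray(labels, dtype=object)[keep]),
            features=rows[keep],
            n_excluded=excluded,
        )

    def __len__(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i}" for i in range(self.features.shape[1])]
        frame = pd.DataFrame(self.features, columns=cols)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "sample_id", self.ids)
        return frame


@dataclass(frozen=True)
class ClassificationReport:
    """Per-split and mean accuracy (%), with the settings that produced them."""

    accuracies: tuple[float, ...]
    mean_accuracy: float
    seed: int
    classifier: str
    n_samples: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracies_percent": list(self.accuracies),
            "mean_accuracy_percent": self.mean_accuracy,
            "seed": self.seed,
            "classifier": self.classifier,
            "n_samples": self.n_samples,
            "n_excluded": self.n_excluded,
        }


def split(
    table: FeatureTable,
    train_frac: float = 0.75,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random stratified train/test index splits.

    Train and test are disjoint and exhaustive; the class proportions of the
    full table are preserved in each part (up to rounding).  The same seed
    yields identical splits, and rows are addressed through a canonical
    (label, sample_id) ordering so the result does not depend on the row
    order of the table.
    """
    if not (0.0 < train_frac < 1.0):
        raise ParameterError(f"train_frac={train_frac} must lie in (0, 1)")
    if n_repeats < 1:
        raise ParameterError(f"n_repeats={n_repeats} must be >= 1")
    n = len(table)
    if int(round(n * (1.0 - train_frac))) < 1 or n - int(n * train_frac) < 1:
        raise ParameterError("split would leave an empty test set")
    labels = np.asarray(table.labels)
    order = np.lexsort((np.asarray(table.ids), labels))
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    return [
        (order[train], order[test])
        for train, test in splitter.split(table.features[order], labels[order])
    ]


def evaluate(
    table: FeatureTable,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    train_frac: float = 0.75,
    n_repeats: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Fit an SVM per split and report accuracy = 100 * correct / total.

    When ``splits`` is omitted, :func:`split` is called with the given
    ``train_frac``/``n_repeats``/``seed``.  Standardization statistics are
    estimated on the training fold only.
    """
    if splits is None:
        splits = split(table, train_frac=train_frac, n_repeats=n_repeats, seed=seed)
    labels = np.asarray(table.labels)
    accuracies = []
    for train_idx, test_idx in splits:
        if len(np.unique(labels[train_idx])) < 2:
            raise ParameterError("training fold degenerated to a single class")
        model = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=C, gamma=gamma))
        model.fit(table.features[train_idx], labels[train_idx])
        pred = model.predict(table.features[test_idx])
        accuracies.append(100.0 * float(np.mean(pred == labels[test_idx])))
    desc = f"SVC(kernel={kernel!r}, C={C}, gamma={gamma!r}) + StandardScaler"
    return ClassificationReport(
        accuracies=tuple(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        seed=seed,
        classifier=desc,
        n_samples=len(table),
        n_excluded=table.n_excluded,
    )
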