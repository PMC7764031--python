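"""SVM evaluation of channel selections under k-fold cross-validation.

Protocol: instances (trial-seconds pooled over all subjects) are
shuffled with a seed, partitioned into k stratified folds, and for
each fold a feature selector is fit on the training portion only —
so data-driven selection never sees the held-out fold.  Both
partitions are restricted to the selected columns, standardized by
training-fold statistics, and scored with an RBF-kernel SVM.

Channel sets are compared on their per-fold accuracies with a
two-sided Welch t-test; differences with p <= 0.05 are called
significant.  The reference gain is reported in percentage points
with the convention positive = reference better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bands import FeatureMatrix
from .selection import (
    FixedChannelSet,
    FixedSetSelector,
    ReversedCorrelationSelector,
    get_fixed_set,
)

__all__ = [
    "CVReport",
    "ComparisonReport",
    "crossval_pipeline",
    "compare_sets",
    "run_comparison_experiment",
    "ALPHA",
]

#: Significance level for channel-set comparisons.
ALPHA = 0.05


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome for one channel set and one emotion."""

    emotion: str
    channel_set_id: str
    fold_accuracies: tuple
    k: int
    seed: int
    fold_selections: tuple = ()  # per-fold selected feature names

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self):
        return {
            "emotion": self.emotion,
            "channel_set_id": self.channel_set_id,
            "k": self.k,
            "seed": self.seed,
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "fold_selections": [list(s) for s in self.fold_selections],
        }

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


@dataclass(frozen=True)
class ComparisonReport:
    """Channel sets compared against a reference selection."""

    emotion: str
    reference_id: str
    rows: tuple  # dicts: id, mean_accuracy, gain_pp, p_value, significant

    def to_frame(self) -> pd.DataFrame:
        cols = ["id", "mean_accuracy", "gain_pp", "p_value", "significant"]
        return pd.DataFrame(list(self.rows), columns=cols)

    def to_csv(self, path):
        frame = self.to_frame().rename(
            columns={"id": "method", "mean_accuracy": "ACC",
                     "gain_pp": "gain", "p_value": "p-value"}
        )
        frame.to_csv(path, index=False, float_format="%.6g")

    def to_dict(self):
        return {
            "emotion": self.emotion,
            "reference_id": self.reference_id,
            "rows": list(self.rows),
        }


def fold_partition(n_instances: int, k: int, seed: int, y):
    """Stratified fold assignment as a function of (n, k, seed) only.

    Instances are shuffled with the seed, then dealt into k stratified
    folds; every channel set evaluated in one experiment shares this
    partition.  Returns a list of (train_idx, test_idx) in original
    index space.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_instances:
        raise ValueError("more folds than instances")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_instances)
    skf = StratifiedKFold(n_splits=k, shuffle=False)
    y_perm = np.asarray(y)[perm]
    return [(perm[tr], perm[te]) for tr, te in skf.split(perm[:, None], y_perm)]


def _make_selector(selector, X: FeatureMatrix):
    """Normalize a selector spec into (estimator_or_None, id string)."""
    if selector is None or selector == "none":
        return None, "None"
    if isinstance(selector, FixedChannelSet):
        return FixedSetSelector(selector, feature_names=X.feature_names), selector.id
    if isinstance(selector, str):
        if selector.lower().startswith("rca"):
            n = int(selector.split(":", 1)[1]) if ":" in selector else 3
            sel = ReversedCorrelationSelector(
                n_features_to_select=n, feature_names=X.feature_names
            )
            return sel, f"RCA({n})"
        return _make_selector(get_fixed_set(selector), X)
    if isinstance(selector, ReversedCorrelationSelector):
        return selector, f"RCA({selector.n_features_to_select})"
    if isinstance(selector, FixedSetSelector):
        return selector, "fixed"
    raise ValueError(f"unrecognized selector {selector!r}")


def crossval_pipeline(
    X: FeatureMatrix,
    y,
    selector=None,
    k: int = 10,
    seed: int = 0,
    emotion: str = "valence",
    svm_c: float = 1.0,
    svm_gamma="scale",
    standardize: bool = True,
) -> CVReport:
    """Evaluate one channel selection with a k-fold RBF-SVM protocol.

    Parameters
    ----------
    X : FeatureMatrix
        Pooled instances over subjects.
    y : array of {0, 1}, length n_instances
        Binary emotion labels per instance.
    selector : None | "rca:N" | FixedChannelSet | set id | estimator
        Fit on training folds only (data-driven selectors never see
        the held-out fold).
    k, seed : folding parameters; the partition depends only on
        (n_instances, k, seed).
    svm_c, svm_gamma : SVC hyperparameters (RBF kernel).  The defaults
        C=1 and gamma="scale" (1 / (n_features * var)) are deliberate,
        documented choices; no hyperparameter search is performed.
    standardize : z-score columns by training-fold statistics.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(y) != X.n_instances:
        raise ValueError("label length does not match instances")

    sel_proto, set_id = _make_selector(selector, X)
    folds = fold_partition(X.n_instances, k, seed, y)
    accs, selections = [], []
    for train_idx, test_idx in folds:
        X_tr, X_te = X.values[train_idx], X.values[test_idx]
        if sel_proto is not None:
            from sklearn.base import clone

            sel = clone(sel_proto)
            if sel.feature_names is None:
                sel.feature_names = X.feature_names
            sel.fit(X_tr)
            X_tr, X_te = sel.transform(X_tr), sel.transform(X_te)
            selections.append(tuple(getattr(sel, "selected_names_", ())))
        else:
            selections.append(tuple(X.feature_names))
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = SVC(C=svm_c, kernel="rbf", gamma=svm_gamma)
        clf.fit(X_tr, y[train_idx])
        accs.append(float(clf.score(X_te, y[test_idx])))
    return CVReport(
        emotion=emotion,
        channel_set_id=set_id,
        fold_accuracies=tuple(accs),
        k=k,
        seed=seed,
        fold_selections=tuple(selections),
    )


def _welch_p(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) < 1e-12 and b.std(ddof=1) < 1e-12:
        # degenerate zero-variance folds: identical means are a perfect
        # tie, different means an unambiguous difference
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_sets(reference: CVReport, others, paired: bool = False) -> ComparisonReport:
    """Compare channel sets to a reference on per-fold accuracies.

    Gain is ``reference mean - other mean`` in percentage points
    (positive = reference better).  p-values come from a two-sided
    Welch t-test over fold accuracies (``paired=True`` switches to a
    paired t-test on the shared fold partition).
    """
    rows = [
        {
            "id": reference.channel_set_id,
            "mean_accuracy": reference.mean_accuracy,
            "gain_pp": None,
            "p_value": None,
            "significant": None,
        }
    ]
    for rep in others:
        if rep is None:
            continue
        if rep.k != reference.k or rep.emotion != reference.emotion:
            raise ValueError("reports differ in k or emotion; not comparable")
        if rep.seed != reference.seed:
            raise ValueError("reports use different fold seeds; not comparable")
        a = np.asarray(reference.fold_accuracies, float)
        b = np.asarray(rep.fold_accuracies, float)
        if paired:
            if np.allclose(a, b):
                p = 1.0
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = _welch_p(a, b)
        rows.append(
            {
                "id": rep.channel_set_id,
                "mean_accuracy": rep.mean_accuracy,
                "gain_pp": 100.0 * (reference.mean_accuracy - rep.mean_accuracy),
                "p_value": p,
                "significant": bool(p <= ALPHA),
            }
        )
    return ComparisonReport(reference.emotion, reference.channel_set_id, tuple(rows))


def run_comparison_experiment(
    X: FeatureMatrix,
    ratings: pd.DataFrame,
    emotions=("valence", "arousal"),
    sets=("CHS1", "CHS2", "CHS3", "CHS4", "CHS5", "CHS6", "CHS7"),
    n_select: int = 3,
    k: int = 10,
    seed: int = 0,
    include_all_channels: bool = True,
    **cv_kwargs,
):
    """Full comparison: reversed-correlation selection vs baselines.

    For each emotion, evaluates the RCA(n_select) pipeline (the
    reference), the all-channels baseline, and every requested fixed
    set applicable to that emotion (non-applicable sets appear as
    blank rows, mirroring the convention of leaving cells empty when
    a literature set targets the other emotion).

    Returns ``{emotion: (ComparisonReport, {set_id: CVReport})}``.
    """
    from .recording import binarize_ratings

    results = {}
    for emotion in emotions:
        labels = binarize_ratings(ratings, emotion)
        y = X.instance_labels(labels)
        if np.isnan(np.asarray(y, float)).any():
            raise ValueError("instances without a rating present")
        ref = crossval_pipeline(
            X, y, selector=f"rca:{n_select}", k=k, seed=seed, emotion=emotion,
            **cv_kwargs,
        )
        reports = {ref.channel_set_id: ref}
        others, blanks = [], []
        if include_all_channels:
            rep = crossval_pipeline(
                X, y, selector=None, k=k, seed=seed, emotion=emotion, **cv_kwargs
            )
            others.append(rep)
            reports[rep.channel_set_id] = rep
        for set_id in sets:
            fset = get_fixed_set(set_id) if isinstance(set_id, str) else set_id
            if not fset.applicable(emotion):
                blanks.append(fset.id)
                continue
            rep = crossval_pipeline(
                X, y, selector=fset, k=k, seed=seed, emotion=emotion, **cv_kwargs
            )
            others.append(rep)
            reports[rep.channel_set_id] = rep
        comparison = compare_sets(ref, others)
        rows = list(comparison.rows) + [
            {"id": b, "mean_accuracy": None, "gain_pp": None,
             "p_value": None, "significant": None}
            for b in blanks
        ]
        results[emotion] = (
            ComparisonReport(emotion, ref.channel_set_id, tuple(rows)),
            reports,
        )
    return results
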