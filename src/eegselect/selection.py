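"""Reversed-correlation feature selection and fixed literature channel sets.

The reversed-correlation algorithm (RCA) is an unsupervised greedy
selector for redundant feature sets such as band-electrode EEG
features.  It first picks the feature with the lowest mean absolute
Pearson correlation to all other features; each subsequent step adds
the candidate with the lowest mean absolute correlation to the
already-selected set.  Class labels are never consulted, which makes
the selector usable on unlabeled or uncertainly labeled data.

Redundancy is treated as a magnitude notion: a perfectly
anti-correlated feature is fully redundant, so the criterion uses
|Pearson r| by default (signed mode available for sensitivity
analysis).

Fixed three-feature band-electrode sets proposed in the emotion-EEG
literature (CHS1..CHS7) are provided as baselines for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .bands import FeatureMatrix

__all__ = [
    "SelectionResult",
    "FixedChannelSet",
    "FIXED_SETS",
    "correlation_matrix",
    "drop_constant",
    "rca_select",
    "get_fixed_set",
    "ReversedCorrelationSelector",
    "FixedSetSelector",
]

_TIE_TOL = 1e-12  # ties within this margin resolve to the lower column index


# ---------------------------------------------------------------------------
# Fixed literature channel sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedChannelSet:
    """A published three-feature band-electrode selection."""

    id: str
    source: str
    emotions: frozenset
    features: tuple

    def applicable(self, emotion: str) -> bool:
        return emotion in self.emotions


_BOTH = frozenset({"valence", "arousal"})

FIXED_SETS = {
    s.id: s
    for s in (
        FixedChannelSet("CHS1", "Koelstra et al.", frozenset({"valence"}),
                        ("PO4_theta", "FC6_beta", "Cz_beta")),
        FixedChannelSet("CHS2", "Koelstra et al.", frozenset({"arousal"}),
                        ("CP6_theta", "Cz_alpha", "FC2_beta")),
        FixedChannelSet("CHS3", "Koelstra et al.", frozenset({"valence"}),
                        ("FC2_beta", "FC6_beta", "Cz_beta")),
        FixedChannelSet("CHS4", "Soroush et al.", frozenset({"arousal"}),
                        ("PO4_beta", "FC1_beta", "FC6_beta")),
        FixedChannelSet("CHS5", "Soroush et al.", frozenset({"valence"}),
                        ("FC6_beta", "P4_theta", "PO4_theta")),
        FixedChannelSet("CHS6", "Frantzidis et al.", _BOTH,
                        ("Cz_beta", "Fz_beta", "Pz_beta")),
        FixedChannelSet("CHS7", "Frantzidis et al.", _BOTH,
                        ("Cz_theta", "Fz_theta", "Pz_theta")),
    )
}


def get_fixed_set(set_id: str) -> FixedChannelSet:
    """Look up a literature channel set by id (``CHS1``..``CHS7``)."""
    key = set_id.upper()
    if key not in FIXED_SETS:
        raise KeyError(f"unknown channel set {set_id!r}; known: {sorted(FIXED_SETS)}")
    return FIXED_SETS[key]


# ---------------------------------------------------------------------------
# Correlation utilities
# ---------------------------------------------------------------------------

def _as_array(X):
    if isinstance(X, FeatureMatrix):
        return X.values, list(X.feature_names)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (instances x features)")
    return X, [f"f{i}" for i in range(X.shape[1])]


def correlation_matrix(X, absolute: bool = True) -> np.ndarray:
    """Pairwise Pearson correlations between feature columns.

    Returns a symmetric matrix with unit diagonal; entries are
    |r| under the default absolute convention.  Zero-variance columns
    make Pearson undefined and raise (drop them first with
    :func:`drop_constant`).
    """
    values, names = _as_array(X)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 instances")
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance columns: {bad}")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return np.abs(corr) if absolute else corr


def drop_constant(X: FeatureMatrix):
    """Remove zero-variance feature columns.

    Returns ``(reduced_matrix, dropped_names)``; raises if every
    column is constant.
    """
    values, names = _as_array(X)
    keep = values.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all feature columns are constant")
    dropped = [n for n, k in zip(names, keep) if not k]
    if isinstance(X, FeatureMatrix):
        kept_names = [n for n, k in zip(names, keep) if k]
        return FeatureMatrix(values[:, keep], kept_names, X.meta), dropped
    return values[:, keep], dropped


# ---------------------------------------------------------------------------
# The greedy selector
# ---------------------------------------------------------------------------

def _greedy_order(corr: np.ndarray, n_select: int, tie_tol: float = _TIE_TOL):
    """Greedy minimum-mean-correlation ordering on a precomputed matrix.

    Step 1 minimizes the mean correlation to all *other* columns;
    step i>1 minimizes the mean correlation to the selected set.
    Ties within ``tie_tol`` resolve to the lower column index.
    Returns (order, scores).
    """
    p = corr.shape[0]
    crit = corr
    order, scores = [], []
    remaining = np.ones(p, dtype=bool)

    if p == 1:
        return [0], [0.0]
    first = crit.sum(axis=0) - 1.0  # exclude the unit diagonal
    first /= p - 1
    idx = _argmin_tied(first, tie_tol)
    order.append(idx)
    scores.append(float(first[idx]))
    remaining[idx] = False

    while len(order) < n_select:
        cand = np.flatnonzero(remaining)
        mean_to_sel = crit[np.ix_(cand, order)].mean(axis=1)
        j = cand[_argmin_tied(mean_to_sel, tie_tol)]
        order.append(int(j))
        scores.append(float(crit[j, order[:-1]].mean()))
        remaining[j] = False
    return order, scores


def _argmin_tied(values, tie_tol):
    best = values.min()
    return int(np.flatnonzero(values <= best + tie_tol)[0])


@dataclass(frozen=True)
class SelectionResult:
    """Ordered outcome of a greedy reversed-correlation run."""

    selected: tuple
    scores: tuple
    n_requested: int
    dropped_constant: tuple = ()

    def to_dict(self):
        return {
            "n": self.n_requested,
            "selected": list(self.selected),
            "scores": list(self.scores),
            "dropped_constant": list(self.dropped_constant),
        }


class ReversedCorrelationSelector(SelectorMixin, BaseEstimator):
    """Unsupervised greedy selector of the least mutually correlated features.

    Parameters
    ----------
    n_features_to_select : int
        Size of the selected subset (the user chooses it; no search
        over subset sizes is performed).
    absolute : bool, default True
        Use |Pearson r| as the redundancy measure.  ``False`` switches
        to signed correlations for sensitivity analysis.
    tie_tol : float
        Criterion ties within this margin resolve to the lower column
        index, making the selection deterministic.

    Attributes
    ----------
    support_ : bool mask over input columns.
    selection_order_ : column indices in selection order.
    scores_ : winning criterion value at each step.
    selected_names_ : feature names in selection order (when the input
        carries names).
    dropped_constant_ : names of zero-variance columns excluded before
        selection (Pearson is undefined for them; they are never
        selected).
    """

    def __init__(self, n_features_to_select=3, absolute=True, tie_tol=_TIE_TOL,
                 feature_names=None):
        self.n_features_to_select = n_features_to_select
        self.absolute = absolute
        self.tie_tol = tie_tol
        self.feature_names = feature_names

    def fit(self, X, y=None):
        values, names = _as_array(X)
        if hasattr(X, "columns"):  # pandas DataFrame
            values = np.asarray(X, dtype=np.float64)
            names = [str(c) for c in X.columns]
        if self.feature_names is not None:
            if len(self.feature_names) != values.shape[1]:
                raise ValueError("feature_names length does not match X")
            names = list(self.feature_names)
        n, p = values.shape
        if n < 2:
            raise ValueError("need at least 2 instances")
        n_sel = int(self.n_features_to_select)
        sd = values.std(axis=0)
        variable = np.flatnonzero(sd > 0)
        if n_sel < 1:
            raise ValueError("n_features_to_select must be >= 1")
        if n_sel > variable.size:
            raise ValueError(
                f"requested {n_sel} features but only {variable.size} "
                "non-constant columns are available"
            )
        corr = correlation_matrix(values[:, variable], absolute=self.absolute)
        order_local, scores = _greedy_order(corr, n_sel, self.tie_tol)
        order = [int(variable[i]) for i in order_local]

        self.n_features_in_ = p
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.selection_order_ = list(order)
        self.scores_ = list(scores)
        self.selected_names_ = [names[i] for i in order]
        self.dropped_constant_ = [names[i] for i in range(p) if sd[i] == 0]
        mask = np.zeros(p, dtype=bool)
        mask[order] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            tuple(self.selected_names_),
            tuple(self.scores_),
            int(self.n_features_to_select),
            tuple(self.dropped_constant_),
        )

    def _more_tags(self):
        return {"allow_nan": False, "requires_y": False}


class FixedSetSelector(SelectorMixin, BaseEstimator):
    """Select a fixed list of named feature columns.

    Requires named input (a :class:`FeatureMatrix`, a DataFrame, or
    ``feature_names`` passed explicitly).
    """

    def __init__(self, features, feature_names=None):
        self.features = features
        self.feature_names = feature_names

    def fit(self, X, y=None):
        if self.feature_names is not None:
            names = list(self.feature_names)
            p = len(names)
        elif isinstance(X, FeatureMatrix):
            names, p = X.feature_names, X.n_features
        elif hasattr(X, "columns"):
            names, p = [str(c) for c in X.columns], X.shape[1]
        else:
            raise ValueError("FixedSetSelector needs named features")
        wanted = list(
            self.features.features
            if isinstance(self.features, FixedChannelSet)
            else self.features
        )
        missing = [f for f in wanted if f not in names]
        if missing:
            raise KeyError(f"features not present in input: {missing}")
        self.n_features_in_ = p
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self.selected_names_ = wanted
        mask = np.zeros(p, dtype=bool)
        for f in wanted:
            mask[names.index(f)] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def rca_select(X, n: int, absolute: bool = True) -> SelectionResult:
    """Run the reversed-correlation selector on a feature matrix.

    Thin functional wrapper over :class:`ReversedCorrelationSelector`;
    zero-variance columns are excluded up front and reported in the
    result.
    """
    sel = ReversedCorrelationSelector(n_features_to_select=n, absolute=absolute)
    sel.fit(X)
    return sel.result()
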