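"""Random-forest out-of-bag permutation importance on augmented matrices.

Feature importance follows Breiman's original procedure: each tree is grown
on a bootstrap sample; for every feature the tree's accuracy on its own
out-of-bag (OOB) samples is compared with the accuracy after permuting that
feature's values among the OOB samples; the per-feature decreases are
averaged over all trees (a tree that never splits on a feature contributes a
decrease of zero, since permuting an unused feature cannot change its
predictions).

This is deliberately not impurity-based importance and not whole-dataset
permutation importance: the per-tree OOB bookkeeping is what makes the
original/knockoff comparison fair, so it is computed explicitly on top of
:class:`sklearn.tree.DecisionTreeClassifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["OOBImportanceForest", "AugmentedDesign", "augment"]


def _seed_sequence(random_state) -> np.random.SeedSequence:
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    return np.random.SeedSequence(random_state)


@dataclass
class AugmentedDesign:
    """[X, X~] with the bookkeeping needed to undo pair scrambling.

    ``matrix`` has ``2p`` columns; column ``j`` and column ``p + j`` hold the
    original/knockoff pair for metabolite ``j``, in an order recorded by
    ``swapped``: when ``swapped[j]`` is True the knockoff sits in column ``j``
    and the original in column ``p + j``.
    """

    matrix: np.ndarray = field(repr=False)
    swapped: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[1] // 2

    def split_scores(self, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Un-scramble a length-2p score vector into (original, knockoff)."""
        scores = np.asarray(scores)
        if scores.shape[0] != 2 * self.n_pairs:
            raise ValueError("score vector length does not match the design")
        p = self.n_pairs
        first, second = scores[:p].copy(), scores[p:].copy()
        orig = np.where(self.swapped, second, first)
        ko = np.where(self.swapped, first, second)
        return orig, ko


def augment(
    X: np.ndarray,
    X_knockoff: np.ndarray,
    *,
    swap: bool = True,
    random_state=None,
) -> AugmentedDesign:
    """Column-wise concatenation of originals and knockoffs.

    With ``swap=True`` (default) each original/knockoff pair is placed in a
    random order, so any position bias of the downstream learner cannot
    systematically favour originals; the permutation is recorded and undone
    by :meth:`AugmentedDesign.split_scores`.  ``swap=False`` reproduces the
    plain ``[X, X~]`` ordering.
    """
    X = np.asarray(X, dtype=float)
    Xk = np.asarray(X_knockoff, dtype=float)
    if X.shape != Xk.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs knockoffs {Xk.shape}")
    p = X.shape[1]
    if swap:
        rng = np.random.default_rng(random_state)
        swapped = rng.random(p) < 0.5
    else:
        swapped = np.zeros(p, dtype=bool)
    left = np.where(swapped[None, :], Xk, X)
    right = np.where(swapped[None, :], X, Xk)
    return AugmentedDesign(matrix=np.hstack([left, right]), swapped=swapped)


class OOBImportanceForest(BaseEstimator):
    """Random-forest classifier scored by per-tree OOB permutation importance.

    Parameters
    ----------
    n_trees : int
        Number of trees (default 1000).
    mtry : int or None
        Features tried at each split; ``None`` uses ``round(sqrt(n_features))``.
    class_weight : None or "balanced"
        Passed to every tree.
    abs_mode : {"abs-of-mean", "mean-of-abs"}
        How the nonnegative importance ``Z`` is formed from the per-tree
        accuracy decreases: the absolute value of the across-tree mean
        (default), or the mean of absolute per-tree decreases.
    random_state : int, SeedSequence or None
        Seeds bootstrap draws, tree construction and OOB permutations; a
        fixed seed makes the fit bit-reproducible.

    Attributes
    ----------
    raw_importances_ : ndarray of shape (n_features,)
        Signed mean OOB accuracy decrease per feature.
    importances_ : ndarray of shape (n_features,)
        Nonnegative importance ``Z`` per ``abs_mode``.
    oob_accuracy_ : float
        Mean per-tree baseline OOB accuracy.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        mtry: int | None = None,
        class_weight: str | None = None,
        abs_mode: str = "abs-of-mean",
        random_state=None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.class_weight = class_weight
        self.abs_mode = abs_mode
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.abs_mode not in ("abs-of-mean", "mean-of-abs"):
            raise ValueError(f"unknown abs_mode {self.abs_mode!r}")
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute before fitting")
        y = np.asarray(y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.shape[0] < 2:
            raise ValueError("y must contain at least 2 classes")
        n, p = X.shape

        mtry = self.mtry if self.mtry is not None else max(1, round(np.sqrt(p)))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must lie in [1, {p}], got {mtry}")

        root = _seed_sequence(self.random_state)
        tree_seeds = root.spawn(self.n_trees)

        decrease_sum = np.zeros(p)
        abs_decrease_sum = np.zeros(p)
        acc_sum = 0.0
        n_scored = 0
        all_idx = np.arange(n)

        for child in tree_seeds:
            rng = np.random.default_rng(child)
            boot = rng.integers(0, n, size=n)
            oob_mask = np.ones(n, dtype=bool)
            oob_mask[boot] = False
            oob = all_idx[oob_mask]
            if oob.size == 0:
                continue
            tree = DecisionTreeClassifier(
                max_features=mtry,
                class_weight=self.class_weight,
                random_state=int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)),
            ).fit(X[boot], y_enc[boot])

            Xo = np.ascontiguousarray(X[oob])
            yo = y_enc[oob]
            m = oob.size
            base = float(np.mean(tree.predict(Xo, check_input=False) == yo))
            acc_sum += base
            n_scored += 1

            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            if used.size == 0:
                continue
            # one batched predict per tree: stack a permuted copy per used feature
            big = np.tile(Xo, (used.size, 1))
            for k, f in enumerate(used):
                big[k * m : (k + 1) * m, f] = Xo[rng.permutation(m), f]
            preds = tree.predict(big, check_input=False).reshape(used.size, m)
            acc_perm = (preds == yo[None, :]).mean(axis=1)
            d = base - acc_perm
            decrease_sum[used] += d
            abs_decrease_sum[used] += np.abs(d)

        if n_scored == 0:
            raise RuntimeError("no tree had out-of-bag samples; increase n_samples")

        self.classes_ = classes
        self.n_features_in_ = p
        self.mtry_ = mtry
        self.oob_accuracy_ = acc_sum / n_scored
        self.raw_importances_ = decrease_sum / n_scored
        if self.abs_mode == "abs-of-mean":
            self.importances_ = np.abs(self.raw_importances_)
        else:
            self.importances_ = abs_decrease_sum / n_scored
        return self

    def feature_importances(self) -> np.ndarray:
        check_is_fitted(self, "importances_")
        return self.importances_
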