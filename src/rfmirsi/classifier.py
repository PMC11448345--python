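"""Bagged decision-tree forest for spectral collagen classification.

A random forest in the classic bagged-ensemble sense: each of ``n_trees``
(default 50) CART trees is grown on a bootstrap resample of the training
set, with ``mtry`` randomly chosen candidate features at every split
(default ⌈√F⌉, i.e. 21 for the 405-band spectral axis). Trees are grown to
purity (Gini splits, no depth limit, minimum leaf size 1). The collagen
probability of a spectrum is the fraction of trees voting collagen, so
probabilities live on the lattice {0, 1/n_trees, …, 1}.

Out-of-bag (OOB) bookkeeping is retained per tree: the OOB error — each
sample classified by majority vote of only the trees that did not see it —
serves as an internal cross-validation estimate, and feature importance is
the mean increase in per-tree OOB error when a feature's values are
permuted among that tree's OOB samples. An exact drop-feature-and-refit
importance is available for comparison (``importance_by_refit``); it costs
one full training per feature.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from rfmirsi.labels import TrainingSet

__all__ = [
    "CollagenForest",
    "default_mtry",
    "train",
    "predict_proba",
    "permutation_importance",
    "top_predictors",
]


def default_mtry(n_features: int) -> int:
    """Candidate features per split: ⌈√F⌉ (21 for F=405)."""
    if n_features < 1:
        raise ValueError("feature count must be ≥ 1")
    return math.ceil(math.sqrt(n_features))


class CollagenForest:
    """Bagged decision-tree ensemble with OOB bookkeeping.

    Parameters
    ----------
    n_trees : int
        Ensemble size; 50 by default (500 gives no perceptible advantage
        on this task).
    mtry : int or None
        Candidate features per split; ``None`` → ⌈√F⌉ at fit time.
    seed : int
        Seeds both the bootstrap resampling and the tree growth.

    Fitted attributes (trailing underscore) appear after :meth:`fit`:
    ``trees_``, ``oob_indices_``, ``oob_error_``, ``n_features_``,
    ``feature_wavenumbers_``.
    """

    def __init__(self, n_trees: int = 50, mtry: int | None = None, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be ≥ 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed

    def get_params(self) -> dict:
        return {"n_trees": self.n_trees, "mtry": self.mtry, "seed": self.seed}

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_wavenumbers: np.ndarray | None = None,
    ) -> "CollagenForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be N×F with matching y")
        n, f = X.shape
        if feature_wavenumbers is not None and len(feature_wavenumbers) != f:
            raise ValueError("feature_wavenumbers length must equal feature count")
        mtry = self.mtry if self.mtry is not None else default_mtry(f)
        if mtry > f:
            raise ValueError(f"mtry={mtry} exceeds feature count {f}")

        rng = np.random.default_rng(self.seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_indices_: list[np.ndarray] = []
        yi = y.astype(int)
        all_idx = np.arange(n)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(all_idx, boot, assume_unique=False)
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], yi[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)

        self.n_features_ = f
        self.mtry_ = mtry
        self.feature_wavenumbers_ = (
            np.asarray(feature_wavenumbers, dtype=float)
            if feature_wavenumbers is not None
            else np.arange(f, dtype=float)
        )
        self._X_train = X
        self._y_train = y
        self.oob_error_ = self._compute_oob_error()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise RuntimeError("forest is not fitted")

    def _compute_oob_error(self) -> float:
        """Aggregated OOB error: majority vote over trees not trained on a sample."""
        n = len(self._y_train)
        votes_pos = np.zeros(n)
        votes_tot = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if len(oob) == 0:
                continue
            pred = tree.predict(self._X_train[oob])
            votes_pos[oob] += pred
            votes_tot[oob] += 1
        covered = votes_tot > 0
        pred_pos = votes_pos[covered] / votes_tot[covered] > 0.5
        return float(np.mean(pred_pos != self._y_train[covered]))

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Collagen probability per spectrum: the tree-vote fraction."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected N×{self.n_features_} spectra, got shape {X.shape}"
            )
        votes = np.zeros(len(X))
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / self.n_trees

    def predict(self, X: np.ndarray, p: float = 0.5) -> np.ndarray:
        """Hard labels at a probability threshold (strict >)."""
        return self.predict_proba(X) > p

    # -- importance --------------------------------------------------------

    def permutation_importance(
        self, seed: int = 0, normalize: bool = False
    ) -> np.ndarray:
        """Per-feature mean increase in per-tree OOB error under permutation.

        For each tree, the feature's values are shuffled among that tree's
        OOB samples only; the increase over the tree's baseline OOB error is
        averaged across trees. With ``normalize`` the mean is divided by the
        standard deviation of the per-tree increases.
        """
        self._check_fitted()
        if not self.oob_indices_ or all(len(o) == 0 for o in self.oob_indices_):
            raise RuntimeError("no OOB samples retained")
        rng = np.random.default_rng(seed)
        deltas = np.zeros((self.n_trees, self.n_features_))
        for t, (tree, oob) in enumerate(zip(self.trees_, self.oob_indices_)):
            if len(oob) == 0:
                continue
            # float32 C-order buffer: lets each per-feature predict reuse the
            # array without a full conversion copy; only the permuted column
            # is touched and restored
            Xo = np.ascontiguousarray(self._X_train[oob], dtype=np.float32)
            yo = self._y_train[oob].astype(int)
            base_err = np.mean(tree.predict(Xo) != yo)
            for f in range(self.n_features_):
                saved = Xo[:, f].copy()
                Xo[:, f] = saved[rng.permutation(len(oob))]
                deltas[t, f] = np.mean(tree.predict(Xo) != yo) - base_err
                Xo[:, f] = saved
        mean = deltas.mean(axis=0)
        if normalize:
            sd = deltas.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            return mean / sd
        return mean

    def importance_by_refit(self) -> np.ndarray:
        """Drop-feature-and-refit importance: ΔOOB error without each feature."""
        self._check_fitted()
        base = self.oob_error_
        out = np.zeros(self.n_features_)
        for f in range(self.n_features_):
            keep = np.delete(np.arange(self.n_features_), f)
            sub = CollagenForest(
                n_trees=self.n_trees,
                mtry=min(self.mtry_, self.n_features_ - 1),
                seed=self.seed,
            )
            sub.fit(self._X_train[:, keep], self._y_train)
            out[f] = sub.oob_error_ - base
        return out


# ---------------------------------------------------------------------------
# Functional surface


def train(
    ts: TrainingSet, n_trees: int = 50, mtry: int | None = None, seed: int = 0
) -> CollagenForest:
    """Fit a :class:`CollagenForest` on a training set."""
    model = CollagenForest(n_trees=n_trees, mtry=mtry, seed=seed)
    model.fit(ts.X, ts.y, feature_wavenumbers=ts.wavenumbers)
    model.training_tissue_ids_ = set(ts.provenance["tissue_id"].unique())
    return model


def predict_proba(model: CollagenForest, spectra: np.ndarray) -> np.ndarray:
    return model.predict_proba(spectra)


def permutation_importance(
    model: CollagenForest, seed: int = 0, normalize: bool = False
) -> np.ndarray:
    return model.permutation_importance(seed=seed, normalize=normalize)


def top_predictors(
    importance: np.ndarray, wavenumbers: np.ndarray, k: int = 20
) -> list[tuple[float, float]]:
    """The k highest-importance bands as (wavenumber, score), descending.

    Ties are broken by the lower wavenumber first.
    """
    importance = np.asarray(importance, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if len(importance) != len(wavenumbers):
        raise ValueError("importance and wavenumber lengths differ")
    if k > len(importance):
        warnings.warn(
            f"k={k} exceeds feature count {len(importance)}; clamping", stacklevel=2
        )
        k = len(importance)
    # lexsort: last key is primary → descending importance, then ascending ν.
    order = np.lexsort((wavenumbers, -importance))
    return [(float(wavenumbers[i]), float(importance[i])) for i in order[:k]]
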