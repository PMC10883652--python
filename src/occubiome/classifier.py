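"""Occupation classification: Bayesian-multiplicative zero replacement and
recursive feature elimination over random-forest ensembles.

The model-construction stack is, per sample type and annotation:

1. prevalence filter (features detected in fewer than ``min_prevalence``
   samples are dropped) and removal of female-student samples, so the
   occupation contrast is not confounded by gender;
2. Bayesian-multiplicative (BM) treatment of count zeros: each zero is
   replaced by its posterior Dirichlet expectation and the non-zero
   parts are multiplicatively shrunk so every sample still sums to one,
   preserving their ratios exactly;
3. recursive feature elimination (RFE): at each step ``n_forests``
   independently bootstrapped random forests are grown, per-feature
   importance ("mean decrease accuracy", the drop in out-of-bag accuracy
   when the feature's values are permuted) is averaged across the
   forests, ensemble accuracies are recorded, and the least important
   feature is removed - down to a single feature;
4. the best model is the step with maximal (test accuracy, train
   accuracy), ties resolved towards the fewest features, refitted with
   the very seed that step used so its accuracies reproduce exactly.

Averaging per-forest mean-decrease-accuracy over forests is identical to
averaging over all member trees, which the implementation exploits: all
``n_forests * trees_per_forest`` trees of a step are grown in one pass
and grouped into forests only for the majority votes.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeClassifier

from .tables import CompositionTable, FeatureTable, TableError

N_FORESTS = 100
TREES_PER_FOREST = 500  # randomForest's classification default
_N_PERM_BLOCKS = 3      # distinct feature permutations cycled across trees


# ---------------------------------------------------------------------------
# Bayesian-multiplicative zero replacement


@dataclass(frozen=True)
class BmParams:
    """Prior for the Bayesian-multiplicative treatment.

    SQ (default): uniform base measure 1/m with strength sqrt(n_j);
    Bayes-Laplace: uniform base with strength m (one pseudocount per
    feature); GBM: base proportional to each feature's geometric-mean
    observed proportion, strength sqrt(n_j).  ``strength`` overrides the
    prior's default strength when given.
    """

    prior: str = "SQ"
    strength: float | None = None

    def __post_init__(self) -> None:
        if self.prior not in ("SQ", "GBM", "Bayes-Laplace"):
            raise ValueError(f"unknown BM prior {self.prior!r}")


def bm_replace(table: FeatureTable, params: BmParams = BmParams()) -> CompositionTable:
    """Replace count zeros by posterior Dirichlet expectations; non-zero
    proportions are scaled down so each sample sums to exactly one while
    their mutual ratios are preserved."""
    counts = table.counts.to_numpy(dtype=float)
    m, n_samples = counts.shape
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.counts.columns[totals == 0].tolist()
        raise TableError(f"samples with all-zero counts: {bad}")

    if params.prior in ("SQ", "Bayes-Laplace"):
        base = np.full((m, 1), 1.0 / m)
    else:  # GBM: geometric mean of observed (non-zero) proportions
        props = counts / totals
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(props > 0, np.log(np.where(props > 0, props, 1.0)), np.nan)
            g = np.exp(np.nanmean(logp, axis=1))
        g = np.where(np.isfinite(g), g, np.nanmin(g[np.isfinite(g)] if np.isfinite(g).any() else 1.0))
        base = (g / g.sum()).reshape(-1, 1)

    if params.strength is not None:
        s = np.full(n_samples, float(params.strength))
    elif params.prior == "Bayes-Laplace":
        s = np.full(n_samples, float(m))
    else:
        s = np.sqrt(totals)

    zero = counts == 0
    replaced = base * (s / (totals + s))           # m x n, value used where zero
    repl_mass = (replaced * zero).sum(axis=0)
    scale = 1.0 - repl_mass  # non-zero proportions already sum to 1 per sample
    out = np.where(zero, replaced, (counts / totals) * scale)
    values = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CompositionTable(values, table.feature_kind)


# ---------------------------------------------------------------------------
# forest ensembles


class ForestEnsemble:
    """``n_forests`` random forests of ``trees_per_forest`` trees each.

    Prediction is a nested majority vote: each forest votes the majority
    class of its trees, the ensemble predicts the majority over forests;
    ties break towards the first class in sorted order.
    """

    def __init__(
        self,
        trees: list[DecisionTreeClassifier],
        n_forests: int,
        trees_per_forest: int,
        classes: np.ndarray,
        feature_names: tuple[str, ...],
    ):
        self.trees = trees
        self.n_forests = n_forests
        self.trees_per_forest = trees_per_forest
        self.classes_ = np.asarray(classes)
        self.feature_names = tuple(feature_names)

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.empty((len(self.trees), X.shape[0]), dtype=np.int64)
        for i, tree in enumerate(self.trees):
            t = tree.tree_
            votes[i] = t.value[t.apply(X), 0, :].argmax(axis=1)
        return votes

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        votes = self._tree_votes(X)
        return _nested_majority(votes, self.n_forests, self.trees_per_forest)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise TableError(f"table is missing model features: {missing}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise TableError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return self.classes_[self.predict_encoded(X)]


@dataclass(frozen=True)
class EnsembleResult:
    ranking: pd.DataFrame            # importance + rank per feature
    train_accuracy: float            # nested-majority-vote accuracy
    test_accuracy: float
    forest_mean_train_accuracy: float  # mean of single-forest accuracies
    forest_mean_test_accuracy: float
    ensemble: ForestEnsemble


def _step_core(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    n_forests: int,
    trees_per_forest: int,
    rs: np.random.RandomState,
    compute_importance: bool = True,
) -> tuple[np.ndarray, list[DecisionTreeClassifier], np.ndarray, np.ndarray]:
    """Grow one step's trees; returns (importance, trees, votes_tr, votes_te).

    The RNG is consumed in a fixed order (bootstraps and tree seeds
    first), so refitting with ``compute_importance=False`` reproduces
    the identical trees.
    """
    n, m = Xtr.shape
    ntree = n_forests * trees_per_forest
    Xtr32 = np.ascontiguousarray(Xtr, dtype=np.float32)
    Xte32 = np.ascontiguousarray(Xte, dtype=np.float32)
    boot = rs.randint(0, n, (ntree, n))
    tree_seeds = rs.randint(0, 2**31 - 1, ntree)

    n_blocks = min(_N_PERM_BLOCKS, ntree) if compute_importance else 0
    stacked_blocks = []
    for _ in range(n_blocks):
        perm = np.tile(Xtr32, (m, 1))
        for f in range(m):
            rs.shuffle(perm[f * n : (f + 1) * n, f])
        stacked_blocks.append(np.ascontiguousarray(np.vstack([Xtr32, Xte32, perm])))
    plain = np.ascontiguousarray(np.vstack([Xtr32, Xte32]))

    nte = Xte32.shape[0]
    tree_votes_tr = np.empty((ntree, n), dtype=np.int8)
    tree_votes_te = np.empty((ntree, nte), dtype=np.int8)
    importance = np.zeros(m)
    trees: list[DecisionTreeClassifier] = []
    with sklearn.config_context(skip_parameter_validation=True, assume_finite=True):
        for b in range(ntree):
            idx = boot[b]
            est = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(tree_seeds[b])
            )
            est.fit(np.asfortranarray(Xtr32[idx]), ytr[idx], check_input=False)
            trees.append(est)
            t = est.tree_
            if compute_importance:
                stacked = stacked_blocks[b % n_blocks]
                pred = t.value[t.apply(stacked), 0, :].argmax(axis=1)
                pred_tr = pred[:n]
                pred_te = pred[n : n + nte]
                pred_perm = pred[n + nte :].reshape(m, n)
                oob = np.ones(n, dtype=bool)
                oob[idx] = False
                if oob.any():
                    base_acc = (pred_tr[oob] == ytr[oob]).mean()
                    importance += base_acc - (pred_perm[:, oob] == ytr[oob]).mean(axis=1)
            else:
                pred = t.value[t.apply(plain), 0, :].argmax(axis=1)
                pred_tr, pred_te = pred[:n], pred[n:]
            tree_votes_tr[b] = pred_tr
            tree_votes_te[b] = pred_te
    importance /= ntree
    return importance, trees, tree_votes_tr, tree_votes_te


def _forest_votes(votes: np.ndarray, n_forests: int, trees_per_forest: int) -> np.ndarray:
    """Per-forest vote for class 1 in [0, 1]; a forest whose trees tie
    contributes half a vote to each class (no deterministic tie bias)."""
    per_forest = votes.reshape(n_forests, trees_per_forest, -1).astype(np.int64).sum(axis=1)
    fv = (per_forest * 2 > trees_per_forest).astype(np.float64)
    fv[per_forest * 2 == trees_per_forest] = 0.5
    return fv


def _nested_majority(votes: np.ndarray, n_forests: int, trees_per_forest: int) -> np.ndarray:
    fv = _forest_votes(votes, n_forests, trees_per_forest)
    return (fv.sum(axis=0) * 2 > n_forests).astype(np.int64)


def _vote_accuracies(
    votes: np.ndarray, y: np.ndarray, n_forests: int, trees_per_forest: int
) -> tuple[float, float]:
    """(nested-majority accuracy, mean single-forest accuracy)."""
    fv = _forest_votes(votes, n_forests, trees_per_forest)
    ensemble_pred = (fv.sum(axis=0) * 2 > n_forests).astype(np.int64)
    forest_acc = np.where(fv == y, 1.0, 0.0) + 0.5 * (fv == 0.5)
    return float((ensemble_pred == y).mean()), float(forest_acc.mean())


def _encode_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {list(classes)}")
    return classes, np.searchsorted(classes, y)


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    return X, tuple(feature_names)


def train_forest_ensemble(
    X_train,
    y_train,
    X_test,
    y_test,
    n_forests: int = N_FORESTS,
    trees_per_forest: int = TREES_PER_FOREST,
    seed: int | None = None,
) -> EnsembleResult:
    """Grow ``n_forests`` bootstrapped forests, rank features by averaged
    mean-decrease-accuracy and evaluate majority-vote accuracies.

    ``X_*`` are samples x features (DataFrame columns name the
    features).  Ranks are 1 = most important; importance ties are broken
    towards lexicographically smaller feature ids, so the
    lexicographically last id among a tied minimum ranks worst.
    """
    Xtr, names = _as_matrix(X_train)
    Xte, _ = _as_matrix(X_test, names)
    classes, ytr = _encode_labels(y_train)
    yte = np.searchsorted(classes, np.asarray(y_test))
    if n_forests < 1 or trees_per_forest < 1 or Xtr.shape[1] < 1:
        raise ValueError("n_forests, trees_per_forest and n_features must be >= 1")
    rs = np.random.RandomState(seed)
    importance, trees, votes_tr, votes_te = _step_core(
        Xtr, ytr, Xte, yte, n_forests, trees_per_forest, rs
    )
    order = sorted(range(len(names)), key=lambda i: (-importance[i], names[i]))
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    ranking = pd.DataFrame(
        {"importance": importance, "rank": rank}, index=pd.Index(names, name="feature_id")
    )
    acc_tr, forest_tr = _vote_accuracies(votes_tr, ytr, n_forests, trees_per_forest)
    acc_te, forest_te = _vote_accuracies(votes_te, yte, n_forests, trees_per_forest)
    ensemble = ForestEnsemble(trees, n_forests, trees_per_forest, classes, names)
    return EnsembleResult(ranking, acc_tr, acc_te, forest_tr, forest_te, ensemble)


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass(frozen=True)
class RfeStep:
    features: tuple[str, ...]
    train_accuracy: float
    test_accuracy: float
    eliminated: str
    step_seed: int


@dataclass(frozen=True)
class RfeTrace:
    steps: list[RfeStep]
    master_seed: int | None
    n_forests: int
    trees_per_forest: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": [len(s.features) for s in self.steps],
                "train_accuracy": [s.train_accuracy for s in self.steps],
                "test_accuracy": [s.test_accuracy for s in self.steps],
                "eliminated": [s.eliminated for s in self.steps],
            }
        )


def _step_seed(master_seed: int | None, step: int) -> int:
    ss = np.random.SeedSequence([0 if master_seed is None else master_seed, step])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def rfe(
    X_train,
    y_train,
    X_test,
    y_test,
    n_forests: int = N_FORESTS,
    trees_per_forest: int = TREES_PER_FOREST,
    seed: int | None = None,
) -> RfeTrace:
    """Backward elimination from all features down to one.

    Step k grows ``n_forests`` forests on the surviving m-k+1 features,
    records majority-vote train/test accuracy, and removes the feature
    with the lowest averaged mean-decrease-accuracy (ties: the
    lexicographically last id).  Fully reproducible from ``seed``.
    """
    Xtr, names = _as_matrix(X_train)
    Xte, _ = _as_matrix(X_test, names)
    classes, ytr = _encode_labels(y_train)
    yte = np.searchsorted(classes, np.asarray(y_test))
    m = Xtr.shape[1]
    if m < 1:
        raise ValueError("need at least one feature")

    alive = list(range(m))
    steps: list[RfeStep] = []
    for k in range(m):
        s_seed = _step_seed(seed, k)
        rs = np.random.RandomState(s_seed)
        importance, _, votes_tr, votes_te = _step_core(
            Xtr[:, alive], ytr, Xte[:, alive], yte, n_forests, trees_per_forest, rs
        )
        acc_tr, _ = _vote_accuracies(votes_tr, ytr, n_forests, trees_per_forest)
        acc_te, _ = _vote_accuracies(votes_te, yte, n_forests, trees_per_forest)
        min_imp = importance.min()
        tied = [alive[i] for i in np.flatnonzero(importance <= min_imp + 1e-15)]
        drop = max(tied, key=lambda i: names[i])  # lexicographically last id
        steps.append(
            RfeStep(
                features=tuple(names[i] for i in alive),
                train_accuracy=acc_tr,
                test_accuracy=acc_te,
                eliminated=names[drop],
                step_seed=s_seed,
            )
        )
        alive.remove(drop)
    return RfeTrace(steps, seed, n_forests, trees_per_forest)


@dataclass
class SelectedModel:
    features: tuple[str, ...]
    train_accuracy: float
    test_accuracy: float
    ensemble: ForestEnsemble
    master_seed: int | None
    step_index: int
    provenance: dict = field(default_factory=dict)


def select_best_model(
    trace: RfeTrace,
    X_train,
    y_train,
    X_test,
    y_test,
    provenance: dict | None = None,
) -> SelectedModel:
    """The step with maximal (test accuracy, train accuracy), preferring
    the fewest features; refitted with that step's recorded seed so the
    returned ensemble reproduces the trace accuracies exactly."""
    if not trace.steps:
        raise ValueError("empty trace")
    best = max(
        range(len(trace.steps)),
        key=lambda i: (
            trace.steps[i].test_accuracy,
            trace.steps[i].train_accuracy,
            -len(trace.steps[i].features),
        ),
    )
    step = trace.steps[best]
    Xtr, names = _as_matrix(X_train)
    Xte, _ = _as_matrix(X_test, names)
    classes, ytr = _encode_labels(y_train)
    yte = np.searchsorted(classes, np.asarray(y_test))
    cols = [names.index(f) for f in step.features]
    rs = np.random.RandomState(step.step_seed)
    _, trees, votes_tr, votes_te = _step_core(
        Xtr[:, cols], ytr, Xte[:, cols], yte,
        trace.n_forests, trace.trees_per_forest, rs, compute_importance=False,
    )
    acc_tr, _ = _vote_accuracies(votes_tr, ytr, trace.n_forests, trace.trees_per_forest)
    acc_te, _ = _vote_accuracies(votes_te, yte, trace.n_forests, trace.trees_per_forest)
    ensemble = ForestEnsemble(
        trees, trace.n_forests, trace.trees_per_forest, classes, step.features
    )
    return SelectedModel(
        features=step.features,
        train_accuracy=acc_tr,
        test_accuracy=acc_te,
        ensemble=ensemble,
        master_seed=trace.master_seed,
        step_index=best,
        provenance=provenance or {},
    )


def predict(model: SelectedModel, composition: CompositionTable | pd.DataFrame) -> pd.Series:
    """Majority-vote occupation labels for new samples; the input must
    contain every model feature (extra features are ignored)."""
    if isinstance(composition, CompositionTable):
        frame = composition.values.T  # samples x features
    else:
        frame = composition
    labels = model.ensemble.predict(frame)
    return pd.Series(labels, index=frame.index, name="predicted")


# ---------------------------------------------------------------------------
# splitting, end-to-end fit, serialization


def stratified_split(
    sample_ids: Sequence[str], labels, test_size: int, seed: int | None
) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/test split (test counts per class
    proportional to class sizes, largest-remainder rounding)."""
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    n = len(sample_ids)
    if not 0 < test_size < n:
        raise ValueError("test_size must be in (0, n)")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    quota = counts * test_size / n
    take = np.floor(quota).astype(int)
    rem = np.argsort(-(quota - take))
    for i in range(test_size - take.sum()):
        take[rem[i % len(classes)]] += 1
    test_idx: list[int] = []
    for cls, k in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        test_idx.extend(rng.choice(members, size=int(k), replace=False).tolist())
    test_set = set(test_idx)
    train = [sample_ids[i] for i in range(n) if i not in test_set]
    test = [sample_ids[i] for i in sorted(test_set)]
    return train, test


def fit_occupation_model(
    table: FeatureTable,
    metadata: pd.DataFrame,
    min_prevalence: int = 10,
    bm: BmParams = BmParams(),
    n_forests: int = N_FORESTS,
    trees_per_forest: int = TREES_PER_FOREST,
    test_size: int = 12,
    seed: int | None = None,
) -> tuple[SelectedModel, RfeTrace, dict]:
    """End-to-end model construction for one sample type: drop female
    students, prevalence-filter, BM-transform, stratified split, RFE and
    best-model selection."""
    from .tables import prevalence_filter  # local import avoids cycle at module load

    keep = metadata.index[
        ~((metadata["occupation"] == "student") & (metadata["gender"] == "F"))
    ]
    table = table.select_samples(list(keep))
    meta = metadata.loc[keep]
    table = prevalence_filter(table, min_prevalence)
    comp = bm_replace(table, bm)
    X = comp.values.T  # samples x features
    y = meta["occupation"].to_numpy()

    split_seed = _step_seed(seed, 10_000)
    train_ids, test_ids = stratified_split(list(X.index), y, test_size, split_seed)
    Xtr, Xte = X.loc[train_ids], X.loc[test_ids]
    ytr = meta.loc[train_ids, "occupation"].to_numpy()
    yte = meta.loc[test_ids, "occupation"].to_numpy()

    trace = rfe(Xtr, ytr, Xte, yte, n_forests, trees_per_forest, seed)
    provenance = {
        "min_prevalence": min_prevalence,
        "bm_prior": bm.prior,
        "n_forests": n_forests,
        "trees_per_forest": trees_per_forest,
        "seed": seed,
        "train_samples": train_ids,
        "test_samples": test_ids,
    }
    model = select_best_model(trace, Xtr, ytr, Xte, yte, provenance)
    return model, trace, provenance


MODEL_FORMAT_VERSION = 1


def save_model(model: SelectedModel, path: str | Path) -> None:
    """Versioned archive: a JSON manifest next to an opaque pickled
    forest payload (``<path>.json`` + ``<path>.pkl``)."""
    path = Path(path)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "features": list(model.features),
        "classes": model.ensemble.classes_.tolist(),
        "n_forests": model.ensemble.n_forests,
        "trees_per_forest": model.ensemble.trees_per_forest,
        "train_accuracy": model.train_accuracy,
        "test_accuracy": model.test_accuracy,
        "master_seed": model.master_seed,
        "step_index": model.step_index,
        "provenance": model.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    with open(path.with_suffix(".pkl"), "wb") as fh:
        pickle.dump(model.ensemble.trees, fh)


def load_model(path: str | Path) -> SelectedModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {manifest['format_version']}")
    with open(path.with_suffix(".pkl"), "rb") as fh:
        trees = pickle.load(fh)
    ensemble = ForestEnsemble(
        trees,
        manifest["n_forests"],
        manifest["trees_per_forest"],
        np.asarray(manifest["classes"]),
        tuple(manifest["features"]),
    )
    return SelectedModel(
        features=tuple(manifest["features"]),
        train_accuracy=manifest["train_accuracy"],
        test_accuracy=manifest["test_accuracy"],
        ensemble=ensemble,
        master_seed=manifest["master_seed"],
        step_index=manifest["step_index"],
        provenance=manifest["provenance"],
    )
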