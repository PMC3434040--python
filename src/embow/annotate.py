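"""Multi-label term annotation protocol and its evaluation.

Image groups carry overlapping sets of controlled-vocabulary terms. The
protocol studied here is:

1. keep the ``top_n`` most frequent terms (typically a step sequence
   10, 20, 30, ...), dropping groups that carry none of them;
2. repeatedly split the groups ~1:1 into train/test with per-term
   stratification (30 random partitions by default);
3. fit one binary linear classifier per term (one-vs-rest), linear SVM with
   regularization parameter C = 1 by default, optionally after random
   over-sampling of the positives;
4. score each term by AUC of the real-valued decision scores and by
   F1 / sensitivity / specificity of the thresholded (0) predictions, and
   report unweighted macro averages as mean ± SD over partitions.

Because terms overlap, exact simultaneous 1:1 stratification is infeasible
in general; partitioning is greedy per term in descending frequency order,
assigning each yet-unplaced positive of the current term to whichever side
currently holds fewer of that term's positives, followed by a bounded swap
repair pass that evens out residual per-term imbalances without touching the
overall 1:1 size balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV
from sklearn.svm import LinearSVC

from .codebook import Codebook, build_codebook, sample_descriptors
from .patches import DEFAULT_RADIUS, DEFAULT_STRIDE, make_layout
from .pipeline import MODES, group_features
from .synthetic import LabeledGroupSet

DEFAULT_N_PARTITIONS = 30
DEFAULT_C = 1.0
CV_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
METRICS = ("auc", "f1", "sensitivity", "specificity")


@dataclass
class AnnotationDataset:
    """Group-level features X, binary labels Y, terms ordered by frequency."""

    X: np.ndarray  # (n_groups, n_features)
    Y: np.ndarray  # (n_groups, n_terms) in {0, 1}
    term_names: list[str]  # descending frequency, ties by name
    group_ids: list[str]

    def __post_init__(self):
        if self.Y.shape != (len(self.group_ids), len(self.term_names)):
            raise ValueError("label matrix shape does not match groups/terms")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def term_counts(self) -> np.ndarray:
        return self.Y.sum(axis=0).astype(int)


@dataclass
class EvalResult:
    """Per-(partition, term) metric table with macro aggregation helpers."""

    frame: pd.DataFrame  # columns: partition, term, auc, f1, sensitivity, specificity

    def macro_per_partition(self) -> pd.DataFrame:
        """Unweighted mean over terms, one row per partition."""
        return self.frame.groupby("partition")[list(METRICS)].mean()

    def summary(self) -> dict[str, tuple[float, float]]:
        """metric -> (mean, SD) of the macro averages across partitions."""
        macro = self.macro_per_partition()
        return {m: (float(macro[m].mean()), float(macro[m].std(ddof=1)) if len(macro) > 1 else 0.0)
                for m in METRICS}

    def per_term_summary(self) -> pd.DataFrame:
        g = self.frame.groupby("term")[list(METRICS)]
        out = g.mean().add_suffix("_mean").join(g.std(ddof=1).add_suffix("_sd"))
        return out


def build_dataset(X: np.ndarray, group_ids: Sequence[str],
                  labels: dict[str, set[str]]) -> AnnotationDataset:
    """Assemble the dataset with terms sorted by descending frequency (ties
    broken alphabetically)."""
    freq: dict[str, int] = {}
    for gid in group_ids:
        for t in labels.get(gid, ()):  # noqa: labels may omit empty groups
            freq[t] = freq.get(t, 0) + 1
    terms = sorted(freq, key=lambda t: (-freq[t], t))
    Y = np.zeros((len(group_ids), len(terms)), dtype=np.int64)
    for i, gid in enumerate(group_ids):
        for t in labels.get(gid, ()):
            Y[i, terms.index(t)] = 1
    return AnnotationDataset(X=np.asarray(X), Y=Y, term_names=terms,
                             group_ids=list(group_ids))


def select_terms(dataset: AnnotationDataset, top_n: int) -> AnnotationDataset:
    """Keep the ``top_n`` most frequent terms; drop groups carrying none.

    Raises if ``top_n`` exceeds the available terms or a retained term ends
    up with fewer than 2 positives or 2 negatives (a 1:1 stratified split
    would be impossible).
    """
    if top_n > len(dataset.term_names):
        raise ValueError(
            f"requested {top_n} terms but only {len(dataset.term_names)} available"
        )
    Y = dataset.Y[:, :top_n]
    keep = Y.sum(axis=1) > 0
    Y = Y[keep]
    X = dataset.X[keep]
    gids = [g for g, k in zip(dataset.group_ids, keep) if k]
    for j, t in enumerate(dataset.term_names[:top_n]):
        pos = int(Y[:, j].sum())
        if pos < 2 or len(Y) - pos < 2:
            raise ValueError(
                f"term {t!r} has {pos} positives / {len(Y) - pos} negatives "
                "after selection; need at least 2 of each"
            )
    return AnnotationDataset(X=X, Y=Y, term_names=dataset.term_names[:top_n],
                             group_ids=gids)


def _imbalances(side: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Signed per-term positive imbalance (train minus test)."""
    return (Y[side == 0].sum(axis=0) - Y[side == 1].sum(axis=0)).astype(np.int64)


def _rebalance_sizes(side: np.ndarray, Y: np.ndarray, weights: np.ndarray) -> None:
    """Move single groups until the side sizes differ by at most 1, choosing
    at each step the group whose move least disturbs the per-term balance."""
    while abs(int((side == 0).sum()) - int((side == 1).sum())) > 1:
        heavy = 0 if (side == 0).sum() > (side == 1).sum() else 1
        sign = -2 if heavy == 0 else 2
        imb = _imbalances(side, Y)
        movers = np.flatnonzero(side == heavy)
        cost = np.abs(imb[None, :] + sign * Y[movers]) @ weights
        side[movers[int(np.argmin(cost))]] = 1 - heavy


def _repair_balance(side: np.ndarray, Y: np.ndarray, rng, max_passes: int = 5) -> None:
    """Swap-based repair of residual per-term imbalance, in place.

    While some term's positives differ by more than 1 between the sides, swap
    a positive of that term from the heavy side with a non-positive from the
    light side, choosing the pair that least disturbs the other terms
    (frequent terms weigh more). Swaps keep the overall sizes fixed; each
    swap strictly reduces the target term's imbalance, so passes terminate.
    """
    n_terms = Y.shape[1]
    weights = 2.0 ** np.arange(n_terms, 0, -1)
    _rebalance_sizes(side, Y, weights)
    for _ in range(max_passes):
        clean = True
        for j in range(n_terms):
            while True:
                imb = _imbalances(side, Y)
                if abs(imb[j]) <= 1:
                    break
                heavy = 0 if imb[j] > 0 else 1
                movers = np.flatnonzero((side == heavy) & (Y[:, j] == 1))
                partners = np.flatnonzero((side != heavy) & (Y[:, j] == 0))
                if len(movers) == 0 or len(partners) == 0:
                    break
                sign = 1 if heavy == 0 else -1
                # new imbalance after swapping mover g with partner h:
                # imb + 2*sign*(Y[h] - Y[g]); pick the least-damaging pair
                delta = 2 * sign * (Y[partners][None, :, :] - Y[movers][:, None, :])
                cost = np.abs(imb[None, None, :] + delta) @ weights
                gi, hi = np.unravel_index(int(np.argmin(cost)), cost.shape)
                g, h = movers[gi], partners[hi]
                side[g], side[h] = side[h], side[g]
                clean = False
        if clean:
            return


def make_partitions(dataset: AnnotationDataset,
                    n_partitions: int = DEFAULT_N_PARTITIONS,
                    seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Greedy per-term stratified ~1:1 train/test splits.

    Terms are processed in frequency order; each unassigned positive of the
    current term goes to the side holding fewer of that term's positives
    (random side on ties). Groups positive for no retained term are split
    to balance overall sizes. Every retained term must end with at least one
    positive on each side.
    """
    n = len(dataset.group_ids)
    if n < 2:
        raise ValueError("need at least 2 groups to partition")
    partitions = []
    rng = np.random.default_rng(seed)
    for _ in range(n_partitions):
        side = np.full(n, -1, dtype=np.int64)  # 0 = train, 1 = test
        for j in range(len(dataset.term_names)):
            pos = np.flatnonzero(dataset.Y[:, j] == 1)
            counts = [int((side[pos] == 0).sum()), int((side[pos] == 1).sum())]
            todo = pos[side[pos] == -1]
            rng.shuffle(todo)
            for g in todo:
                if counts[0] < counts[1]:
                    s = 0
                elif counts[1] < counts[0]:
                    s = 1
                else:
                    s = int(rng.integers(2))
                side[g] = s
                counts[s] += 1
        rest = np.flatnonzero(side == -1)
        rng.shuffle(rest)
        for g in rest:
            tr, te = int((side == 0).sum()), int((side == 1).sum())
            side[g] = 0 if tr < te else (1 if te < tr else int(rng.integers(2)))
        # repair on [Y, 1-Y]: balancing the complements too keeps at least
        # one negative of every term on each side whenever two exist
        _repair_balance(side, np.hstack([dataset.Y, 1 - dataset.Y]), rng)
        for j, t in enumerate(dataset.term_names):
            for cls, name in ((1, "positives"), (0, "negatives")):
                cls_sides = side[dataset.Y[:, j] == cls]
                if not ((cls_sides == 0).any() and (cls_sides == 1).any()):
                    raise RuntimeError(
                        f"stratification failed: all {name} of {t!r} on one side"
                    )
        partitions.append((np.flatnonzero(side == 0), np.flatnonzero(side == 1)))
    return partitions


def oversample(train_X: np.ndarray, train_y: np.ndarray,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random over-sampling of the positive class.

    Positives are redrawn with replacement until their count equals the
    negative count; negatives are untouched. A no-op when positives already
    match or exceed the negatives.
    """
    train_y = np.asarray(train_y)
    pos = np.flatnonzero(train_y == 1)
    neg = np.flatnonzero(train_y == 0)
    if len(pos) == 0:
        raise ValueError("cannot oversample a term with zero positives in train")
    if len(pos) >= len(neg):
        return train_X, train_y
    rng = np.random.default_rng(seed)
    drawn = rng.choice(pos, size=len(neg), replace=True)
    idx = np.concatenate([neg, drawn])
    return train_X[idx], train_y[idx]


def _make_estimator(classifier: str, reg: float):
    if classifier == "linear_svm":
        return LinearSVC(C=reg, loss="squared_hinge", dual=False, max_iter=5000)
    if classifier == "logistic":
        return LogisticRegression(C=reg, solver="lbfgs", max_iter=2000)
    if classifier == "ridge":
        # RidgeClassifier penalizes with alpha; keep the grid on 1/alpha so
        # larger values mean weaker regularization, as for C.
        return RidgeClassifier(alpha=1.0 / reg)
    raise ValueError(f"unknown classifier {classifier!r}")


def train_ovr(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    classifier: str = "linear_svm",
    reg: float = DEFAULT_C,
    cv_select: bool = False,
    oversample_positives: bool = False,
    seed: int = 0,
) -> list:
    """One binary linear model per term (columns of ``train_Y``).

    With ``cv_select`` the regularization strength is chosen per term by
    4-fold cross-validation over a decade grid, scored by validation F1.
    """
    models = []
    for j in range(train_Y.shape[1]):
        y = train_Y[:, j]
        if len(np.unique(y)) < 2:
            raise ValueError(f"term column {j} has a single class in training data")
        X, yy = (oversample(train_X, y, seed=seed + j)
                 if oversample_positives else (train_X, y))
        if cv_select:
            grid = {"C": list(CV_GRID)} if classifier != "ridge" else \
                   {"alpha": [1.0 / c for c in CV_GRID]}
            est = _make_estimator(classifier, DEFAULT_C)
            search = GridSearchCV(est, grid, cv=4, scoring="f1", n_jobs=1)
            search.fit(X, yy)
            models.append(search.best_estimator_)
        else:
            est = _make_estimator(classifier, reg)
            est.fit(X, yy)
            models.append(est)
    return models


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    return model.decision_function(X)


def evaluate(models: Sequence, test_X: np.ndarray, test_Y: np.ndarray,
             term_names: Sequence[str], partition: int = 0) -> EvalResult:
    """Per-term AUC (rank-based, ties averaged) and thresholded metrics.

    Predictions are scores > 0. A term absent from the test side is flagged
    undefined and excluded (with a warning) rather than scored.
    """
    import warnings

    rows = []
    for j, (model, t) in enumerate(zip(models, term_names)):
        y = test_Y[:, j]
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(f"term {t!r} has a single class in test; metrics undefined")
            continue
        s = _decision_scores(model, test_X)
        pred = (s > 0).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        rows.append({
            "partition": partition,
            "term": t,
            "auc": float(roc_auc_score(y, s)),
            "f1": f1,
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
        })
    return EvalResult(frame=pd.DataFrame(rows))


@dataclass(frozen=True)
class AnnotationConfig:
    """Protocol parameters for one synthetic annotation experiment."""

    modes: tuple[str, ...] = MODES
    term_counts: tuple[int, ...] = (4,)
    n_partitions: int = DEFAULT_N_PARTITIONS
    classifier: str = "linear_svm"
    reg: float = DEFAULT_C
    cv_select: bool = False
    oversample_positives: bool = False
    codebook_size: int = 50
    codebook_fraction: float = 0.15
    lam: float = 0.01
    radius: int = DEFAULT_RADIUS
    stride: int = DEFAULT_STRIDE
    seed: int = 0
    dataset_name: str = "synthetic"


def run_annotation_experiment(
    group_set: LabeledGroupSet,
    config: AnnotationConfig = AnnotationConfig(),
    codebook: Codebook | None = None,
    return_details: bool = False,
):
    """Full protocol over representation modes x term counts.

    Returns a tidy table with columns
    ``dataset, n_terms, mode, metric, mean, sd`` (the layout the per-mode
    comparison tables use), and optionally the underlying EvalResults.
    """
    if codebook is None:
        h, w = group_set.groups[0][1][0].shape
        layout = make_layout(w, h, radius=config.radius, stride=config.stride)
        sample = sample_descriptors(group_set, layout,
                                    fraction=config.codebook_fraction,
                                    seed=config.seed)
        codebook = build_codebook(sample, c=config.codebook_size, seed=config.seed)

    feats = group_features(group_set, codebook, modes=config.modes,
                           lam=config.lam, radius=config.radius,
                           stride=config.stride)
    rows = []
    details: dict[tuple[str, int], EvalResult] = {}
    for mode in config.modes:
        base = build_dataset(feats[mode], group_set.group_ids, group_set.labels)
        for top_n in config.term_counts:
            ds = select_terms(base, top_n)
            parts = make_partitions(ds, n_partitions=config.n_partitions,
                                    seed=config.seed)
            frames = []
            for p, (tr, te) in enumerate(parts):
                models = train_ovr(ds.X[tr], ds.Y[tr],
                                   classifier=config.classifier, reg=config.reg,
                                   cv_select=config.cv_select,
                                   oversample_positives=config.oversample_positives,
                                   seed=config.seed + p)
                frames.append(evaluate(models, ds.X[te], ds.Y[te],
                                       ds.term_names, partition=p).frame)
            result = EvalResult(frame=pd.concat(frames, ignore_index=True))
            details[(mode, top_n)] = result
            for metric, (mean, sd) in result.summary().items():
                rows.append({"dataset": config.dataset_name, "n_terms": top_n,
                             "mode": mode, "metric": metric,
                             "mean": mean, "sd": sd})
    table = pd.DataFrame(rows)
    if return_details:
        return table, details
    return table


def replace_config(config: AnnotationConfig, **kwargs) -> AnnotationConfig:
    return _dc_replace(config, **kwargs)
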