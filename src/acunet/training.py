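"""Training-harness functions: SGD step, k-fold CV and the ablation study.

These are thin, array-level wrappers over :class:`~acunet.estimator.\
ACUNetSegmenter`; the estimator owns the actual loop.  Cross-validation
reports the arithmetic mean of per-fold metrics, and the ablation harness
trains every requested variant under the identical seed, split and loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .estimator import ACUNetSegmenter, sample_region_dice
from .metrics import ALL_COLUMNS, MetricReport, evaluate_regions
from .volumes import REGION_ORDER

__all__ = ["sgd_step", "FoldSplit", "kfold_split", "train",
           "evaluate_dataset", "cross_validate", "run_ablation"]

log = logging.getLogger("acunet")


def sgd_step(params, grads, learning_rate: float, momentum: float = 0.0,
             buffers=None):
    """One SGD update theta <- theta - eta * grad (with optional momentum).

    ``params``/``grads`` are equally-shaped arrays or lists of arrays.
    Returns ``(new_params, new_buffers)`` without mutating the inputs.
    """
    single = isinstance(params, np.ndarray) or np.isscalar(params)
    ps = [np.asarray(params, dtype=np.float64)] if single else \
        [np.asarray(p, dtype=np.float64) for p in params]
    gs = [np.asarray(grads, dtype=np.float64)] if single else \
        [np.asarray(g, dtype=np.float64) for g in grads]
    if len(ps) != len(gs) or any(p.shape != g.shape for p, g in zip(ps, gs)):
        raise ValueError("params and grads must match in shape")
    if buffers is None:
        bs = [np.zeros_like(p) for p in ps]
    else:
        bs = [np.asarray(buffers, dtype=np.float64).copy()] if single else \
            [np.asarray(b, dtype=np.float64).copy() for b in buffers]
    new_p = []
    for p, g, b in zip(ps, gs, bs):
        b *= momentum
        b += g
        new_p.append(p - learning_rate * b)
    if single:
        return new_p[0], bs[0]
    return new_p, bs


@dataclass(frozen=True)
class FoldSplit:
    """Partition of sample indices into k near-equal folds."""

    k: int
    assignment: np.ndarray      # fold id per sample index

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def kfold_split(n: int, k: int, seed: int = 0) -> FoldSplit:
    """Seeded permutation of ``n`` indices into ``k`` folds (sizes differ <=1)."""
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    assignment = np.empty(n, dtype=np.int64)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, val_idx) in enumerate(kf.split(np.arange(n))):
        assignment[val_idx] = fold
    return FoldSplit(k=k, assignment=assignment)


def train(images, labels, **estimator_params):
    """Fit a segmenter; returns ``(estimator, history DataFrame)``."""
    est = ACUNetSegmenter(**estimator_params)
    est.fit(images, labels)
    return est, est.history_


def evaluate_dataset(est: ACUNetSegmenter, images, labels,
                     spacing=None) -> MetricReport:
    """Mean per-region metric report over a stack of samples.

    Metrics are computed per sample and averaged; undefined surface
    distances (one mask empty) are excluded from the means and counted.
    """
    preds = est.predict(images)
    tables, n_undef = [], 0
    for p, g in zip(preds, np.asarray(labels)):
        rep = evaluate_regions(p, g, spacing)
        tables.append(rep.table.loc[list(REGION_ORDER)])
        n_undef += rep.n_undefined_surface
    mean = pd.concat(tables).groupby(level=0, sort=False).mean()
    mean = mean.loc[list(REGION_ORDER), ALL_COLUMNS]
    mean.loc["Average"] = mean.mean(axis=0, skipna=True)
    return MetricReport(table=mean, n_undefined_surface=n_undef)


def cross_validate(images, labels, k: int, estimator_params: dict | None = None,
                   spacing=None, seed: int = 0):
    """k-fold cross-validation.

    Each fold is held out once while the other k-1 folds train a fresh
    estimator.  Returns ``(per-fold reports, average report)`` where the
    average is the arithmetic mean of the fold tables.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    params = dict(estimator_params or {})
    params.setdefault("seed", seed)
    split = kfold_split(images.shape[0], k, seed=seed)
    reports = []
    for fold in range(k):
        val = split.fold_indices(fold)
        trn = np.flatnonzero(split.assignment != fold)
        log.info("cross_validate fold=%d train=%d val=%d", fold, trn.size,
                 val.size)
        est = ACUNetSegmenter(**params)
        est.fit(images[trn], labels[trn])
        reports.append(evaluate_dataset(est, images[val], labels[val],
                                        spacing))
    avg_table = sum(r.table for r in reports) / k
    avg = MetricReport(table=avg_table,
                       n_undefined_surface=sum(r.n_undefined_surface
                                               for r in reports))
    return reports, avg


def run_ablation(images, labels, variants=("baseline", "channel_only",
                                           "spatial_only", "decoder_only",
                                           "full"),
                 estimator_params: dict | None = None, test_fraction: float = 0.2,
                 seed: int = 0, return_models: bool = False):
    """Train every variant under identical conditions; compare region Dice.

    A single seeded train/test split is shared by all variants, as are the
    weight-init seed, preprocessing and loss weights.  Returns a DataFrame
    with one row per variant and WT/TC/ET Dice columns (plus the fitted
    estimators when ``return_models``).
    """
    if len(variants) < 2:
        raise ValueError("ablation needs at least two variants")
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    params = dict(estimator_params or {})
    params.setdefault("seed", seed)
    rng = np.random.default_rng(seed)
    n = images.shape[0]
    n_test = max(1, int(round(n * test_fraction)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    rows, models = {}, {}
    for variant in variants:
        est = ACUNetSegmenter(**{**params, "variant": variant})
        log.info("ablation variant=%s train=%d test=%d", variant,
                 train_idx.size, test_idx.size)
        est.fit(images[train_idx], labels[train_idx])
        dices = est.region_dice(images[test_idx], labels[test_idx])
        rows[variant] = {f"{r.lower()}_dice": dices[r] for r in REGION_ORDER}
        models[variant] = est
    table = pd.DataFrame(rows).T
    table.index.name = "variant"
    if return_models:
        return table, models
    return table
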