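"""Model-selection machinery: exhaustive grids over classifiers, wavelets,
model orders and packet levels.

Two procedures are provided, mirroring the two-step selection protocol:

* :func:`search_classifier` — joint search over classifier x wavelet x model
  order, using the dual state-space features alone;
* :func:`search_dssm_params` — the same grid restricted to one classifier
  (step 1 of the parameter search);
* :func:`search_le_params` — wavelet x level grid for the locality-energy
  block with the dual-model block frozen (step 2).

Every candidate is evaluated by k-fold cross-validation with its own fold
assignment drawn deterministically from the master seed (seed + a stride
times the candidate index), so candidates are comparable yet independently
resampled.  Ties are broken by higher kappa, then smaller model order, then
candidate-list position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import cross_validate
from .features import dssm_features, le_features
from .preprocess import EpochMatrix

_SEED_STRIDE = 9973  # sub-seed spacing; keeps derived seeds below 2**31


def _sub_seed(seed: int, index: int) -> int:
    return (int(seed) + _SEED_STRIDE * index) % (2 ** 31)


@dataclass(frozen=True)
class GridResult:
    """All evaluated rows plus the argmax row per class-count."""

    table: pd.DataFrame
    best: dict  # n_classes -> row (as a dict)

    def accuracy_matrix(self, n_classes: int, index: str, columns: str
                        ) -> pd.DataFrame:
        """Pivot the accuracies, e.g. orders x wavelets."""
        sub = self.table[(self.table.n_classes == n_classes)
                         & ~self.table.failed]
        return sub.pivot_table(index=index, columns=columns,
                               values="accuracy", sort=False)


_COLUMNS = ["classifier", "wavelet_dssm", "order_dssm", "wavelet_le",
            "level_le", "n_classes", "accuracy", "kappa", "failed", "error"]


def _finalize(rows: list) -> GridResult:
    table = pd.DataFrame(rows, columns=_COLUMNS)
    best = {}
    for n_classes, group in table[~table.failed].groupby("n_classes"):
        # deterministic tie-break: accuracy desc, kappa desc, smaller order,
        # then original candidate order (stable sort keeps it)
        ranked = group.sort_values(
            ["accuracy", "kappa", "order_dssm"],
            ascending=[False, False, True],
            kind="stable",
        )
        best[int(n_classes)] = ranked.iloc[0].to_dict()
    return GridResult(table=table, best=best)


def _label_groups(em: EpochMatrix, labels_by_classes) -> dict:
    if labels_by_classes is not None:
        return {int(k): np.asarray(v, dtype=int) for k, v in
                labels_by_classes.items()}
    if em.labels is None:
        raise ValueError("epoch matrix carries no labels")
    return {int(em.labels.max()) + 1: em.labels}


def _dssm_table(em: EpochMatrix, wavelet: str, order: int) -> np.ndarray:
    """Dual-model feature block for every epoch (no energy columns)."""
    rows = [dssm_features(em.epochs[idx], wavelet, order)
            for idx in range(em.n_epochs)]
    return np.vstack(rows)


class _RawTable:
    """Duck-typed stand-in for FeatureTable when only a matrix is needed."""

    def __init__(self, matrix, labels):
        self.matrix = matrix
        self.labels = labels
        self.n_epochs = matrix.shape[0]


def search_classifier(em: EpochMatrix, classifiers, wavelets, orders,
                      k: int = 10, seed: int = 0,
                      labels_by_classes=None) -> GridResult:
    """Exhaustive classifier x wavelet x order search on dual-model features."""
    if not classifiers or not wavelets or not orders:
        raise ValueError("candidate lists must be non-empty")
    groups = _label_groups(em, labels_by_classes)
    rows = []
    idx = 0
    for wavelet in wavelets:
        for order in orders:
            try:
                matrix = _dssm_table(em, wavelet, order)
                feat_err = None
            except Exception as err:  # noqa: BLE001 - recorded, not fatal
                matrix, feat_err = None, str(err)
            for clf in classifiers:
                for n_classes, labels in groups.items():
                    idx += 1
                    if feat_err is not None:
                        rows.append([clf, wavelet, order, None, None,
                                     n_classes, np.nan, np.nan, True, feat_err])
                        continue
                    try:
                        rep = cross_validate(
                            _RawTable(matrix, labels), clf, k=k,
                            seed=_sub_seed(seed, idx),
                        )
                        rows.append([clf, wavelet, order, None, None, n_classes,
                                     rep.accuracy, rep.kappa, False, None])
                    except Exception as err:  # noqa: BLE001
                        rows.append([clf, wavelet, order, None, None, n_classes,
                                     np.nan, np.nan, True, str(err)])
    return _finalize(rows)


def search_dssm_params(em: EpochMatrix, wavelets, orders, classifier: str,
                       k: int = 10, seed: int = 0,
                       labels_by_classes=None) -> GridResult:
    """Step 1: wavelet x order grid for the dual-model block."""
    return search_classifier(em, [classifier], wavelets, orders, k=k,
                             seed=seed, labels_by_classes=labels_by_classes)


def search_le_params(em: EpochMatrix, wavelets, levels, frozen_dssm,
                     classifier: str, k: int = 10, seed: int = 0,
                     labels_by_classes=None) -> GridResult:
    """Step 2: wavelet x level grid for the energy block, dual models frozen.

    ``frozen_dssm`` is the ``(wavelet_dssm, order_dssm)`` pair selected in
    step 1; its feature block is computed once and reused for every cell.
    """
    if not wavelets or not levels:
        raise ValueError("candidate lists must be non-empty")
    w_dssm, n_dssm = frozen_dssm
    groups = _label_groups(em, labels_by_classes)
    dssm_block = _dssm_table(em, w_dssm, n_dssm)
    rows = []
    idx = 0
    for wavelet in wavelets:
        for level in levels:
            try:
                le_block = np.vstack([
                    le_features(em.epochs[r], wavelet, level)
                    for r in range(em.n_epochs)
                ])
                matrix = np.hstack([le_block, dssm_block])
                feat_err = None
            except Exception as err:  # noqa: BLE001
                matrix, feat_err = None, str(err)
            for n_classes, labels in groups.items():
                idx += 1
                if feat_err is not None:
                    rows.append([classifier, w_dssm, n_dssm, wavelet, level,
                                 n_classes, np.nan, np.nan, True, feat_err])
                    continue
                try:
                    rep = cross_validate(
                        _RawTable(matrix, labels), classifier, k=k,
                        seed=_sub_seed(seed, idx),
                    )
                    rows.append([classifier, w_dssm, n_dssm, wavelet, level,
                                 n_classes, rep.accuracy, rep.kappa, False,
                                 None])
                except Exception as err:  # noqa: BLE001
                    rows.append([classifier, w_dssm, n_dssm, wavelet, level,
                                 n_classes, np.nan, np.nan, True, str(err)])
    return _finalize(rows)
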