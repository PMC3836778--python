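"""Evaluation protocol: stratified k-fold CV, metric suite, ROC, RI coverage,
parameter sweep, terminal-truncation scan, and propensity-vs-measurement
correlation.

Conventions
-----------
* Folds are stratified (the realistic class ratio is ~1:7, so unstratified
  20-folds could contain zero positives) and derived deterministically from
  a master seed.
* Confusion counts are pooled (micro-averaged) over all out-of-fold
  predictions before computing metrics: with only a handful of positives
  per fold, per-fold MCC is too unstable to average.
* MCC is defined as 0 whenever a denominator factor is 0 (the standard
  continuity convention for degenerate confusion tables).

Metric definitions, with TP/TN/FP/FN the pooled confusion counts:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    Q2  = (TP + TN) / (TP + TN + FP + FN)          (overall accuracy)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import model as _model
from .dataset import LabeledDataset
from .exceptions import PresepError
from .pseaac import PseAACParams, PseAACType, encode_batch
from .util import derive_seed

W_GRID_DEFAULT: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 11))
LAM_GRID_DEFAULT: tuple[int, ...] = tuple(range(1, 21))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, labels, calls) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(calls, dtype=int)
        if y.shape != p.shape:
            raise ValueError("labels and calls differ in length")
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
        )


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    q2: float
    mcc: float
    counts: ConfusionCounts
    auc: float | None = None
    per_fold: list[ConfusionCounts] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "q2": self.q2,
            "mcc": self.mcc,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }
        return d


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, Q2 and MCC from a confusion table."""
    if c.total == 0:
        raise PresepError("empty confusion table")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    q2 = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(sensitivity=sens, specificity=spec, q2=q2, mcc=mcc, counts=c)


def roc_auc(labels, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by the rank/trapezoid method plus the ROC curve points.

    Ties in the scores share rank (equivalently, the trapezoid over the tied
    block), so the result equals all-pairs concordance counting with ties
    worth 1/2.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise PresepError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


def ri_coverage_curve(labels, scores) -> pd.DataFrame:
    """Coverage/accuracy per reliability-index threshold.

    For every threshold t = 0..10: the fraction of proteins with RI >= t and
    the prediction accuracy among them (NaN if the stratum is empty). The
    fraction is non-increasing in t; the t = 0 row covers everything.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    ri = np.array([_model.reliability_index(float(o)) for o in s])
    calls = (s >= 0.5).astype(int)
    correct = calls == y
    rows = []
    n = len(y)
    for t in range(11):
        mask = ri >= t
        k = int(mask.sum())
        rows.append(
            {
                "ri_threshold": t,
                "fraction": k / n if n else 0.0,
                "accuracy": float(correct[mask].mean()) if k else float("nan"),
                "n": k,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one parameter setting."""

    metrics: MetricsReport
    oof_scores: np.ndarray  # out-of-fold propensity O per example, input order
    labels: np.ndarray
    fold_assignments: np.ndarray
    folds_used: int


def cross_validate(
    features: np.ndarray,
    labels,
    folds: int = 20,
    seed: int = 0,
    n_trees: int = _model.N_TREES_DEFAULT,
    fold_seed: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled confusion counts.

    ``seed`` drives everything deterministically: the fold assignment uses
    ``fold_seed`` (default ``derive_seed(seed, "folds")``) and fold f's
    forest uses ``derive_seed(seed, "forest", f)``. Passing an explicit
    ``fold_seed`` lets a sweep hold fold assignments fixed across points
    while varying the forests. If a class has fewer members than ``folds``,
    the fold count is reduced to that size with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise PresepError("cross-validation requires both classes present")
    min_class = min(n_pos, n_neg)
    folds_used = folds
    if min_class < folds:
        folds_used = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds "
            f"{folds} -> {folds_used}",
            stacklevel=2,
        )
    if fold_seed is None:
        fold_seed = derive_seed(seed, "folds")
    skf = StratifiedKFold(n_splits=folds_used, shuffle=True, random_state=fold_seed)

    oof = np.full(len(y), np.nan)
    assign = np.full(len(y), -1, dtype=int)
    per_fold: list[ConfusionCounts] = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        m = _model.train(
            X[tr], y[tr], n_trees=n_trees, seed=derive_seed(seed, "forest", f)
        )
        O = _model.vote_fractions(m, X[te])
        oof[te] = O
        assign[te] = f
        per_fold.append(ConfusionCounts.from_predictions(y[te], (O >= 0.5).astype(int)))

    pooled = ConfusionCounts.from_predictions(y, (oof >= 0.5).astype(int))
    report = metrics_from_counts(pooled)
    report.per_fold = per_fold
    report.auc = roc_auc(y, oof)[0]
    return CVResult(
        metrics=report,
        oof_scores=oof,
        labels=y,
        fold_assignments=assign,
        folds_used=folds_used,
    )


def cross_validate_dataset(
    dataset: LabeledDataset,
    params: PseAACParams,
    folds: int = 20,
    seed: int = 0,
    n_trees: int = _model.N_TREES_DEFAULT,
    table=None,
    fold_seed: int | None = None,
) -> CVResult:
    """Encode a labeled dataset under ``params`` and cross-validate it."""
    X, _ = encode_batch([(r.id, r.sequence) for r in dataset.records], params, table)
    return cross_validate(
        X, dataset.labels, folds=folds, seed=seed, n_trees=n_trees, fold_seed=fold_seed
    )


def parameter_sweep(
    dataset: LabeledDataset,
    modes: Sequence[PseAACType] = (PseAACType.TYPE_I, PseAACType.TYPE_II),
    w_grid: Sequence[float] = W_GRID_DEFAULT,
    lam_grid: Sequence[int] = LAM_GRID_DEFAULT,
    folds: int = 20,
    seed: int = 0,
    n_trees: int = _model.N_TREES_DEFAULT,
    table=None,
    base_params: PseAACParams | None = None,
) -> pd.DataFrame:
    """Cross-validate every (mode, w, lambda) grid point.

    Fold assignment is shared across points (one fold seed from the master
    seed); each point trains forests under its own derived seed. Returns a
    long table sorted by MCC descending, ties broken by (mode, w, lambda)
    ascending so the ordering is stable and reproducible.
    """
    if not modes or not w_grid or not lam_grid:
        raise PresepError("sweep grids must be non-empty")
    base = base_params or PseAACParams()
    fold_seed = derive_seed(seed, "folds")
    rows = []
    for mode in modes:
        for w in w_grid:
            for lam in lam_grid:
                params = PseAACParams(
                    mode=mode,
                    w=w,
                    lam=lam,
                    properties=base.properties,
                    nonstandard=base.nonstandard,
                )
                cv = cross_validate_dataset(
                    dataset,
                    params,
                    folds=folds,
                    seed=derive_seed(seed, mode.value, w, lam),
                    n_trees=n_trees,
                    table=table,
                    fold_seed=fold_seed,
                )
                m = cv.metrics
                rows.append(
                    {
                        "mode": mode.value,
                        "w": w,
                        "lam": lam,
                        "mcc": m.mcc,
                        "q2": m.q2,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "auc": m.auc,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["mcc", "mode", "w", "lam"], ascending=[False, True, True, True]
    ).reset_index(drop=True)


def terminal_scan(
    dataset: LabeledDataset,
    params: PseAACParams,
    lengths: Sequence[int],
    folds: int = 20,
    seed: int = 0,
    n_trees: int = _model.N_TREES_DEFAULT,
    table=None,
    terminals: Sequence[str] = ("N", "C"),
) -> pd.DataFrame:
    """Classification performance from terminal sequence windows.

    For each terminal (N or C) and window length k, every sequence is
    truncated to its first/last k residues, re-encoded under ``params``
    (short windows are padded via the effective-lambda rule, so the feature
    dimension is unchanged), and cross-validated. Fold assignment and seeds
    are derived from the master seed, shared across scan points, so N and C
    results at a given k are directly comparable.
    """
    if not lengths:
        raise PresepError("terminal scan needs at least one window length")
    fold_seed = derive_seed(seed, "folds")
    rows = []
    for terminal in terminals:
        for k in lengths:
            p = params.with_truncation(terminal, int(k))
            cv = cross_validate_dataset(
                dataset,
                p,
                folds=folds,
                # keyed on k only: N and C windows at the same k share forest
                # seeds, so their MCCs are directly comparable (and identical
                # when k exceeds every sequence length)
                seed=derive_seed(seed, "window", k),
                n_trees=n_trees,
                table=table,
                fold_seed=fold_seed,
            )
            m = cv.metrics
            rows.append(
                {
                    "terminal": terminal,
                    "k": int(k),
                    "mcc": m.mcc,
                    "q2": m.q2,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "auc": m.auc,
                }
            )
    return pd.DataFrame(rows)


def propensity_correlation(
    pairs: Iterable[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of a measured secretion percentage on the predicted propensity.

    Returns (slope, intercept, R^2) where R^2 is the squared Pearson
    correlation. Needs at least 3 pairs and non-zero variance on both axes.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise PresepError("need at least 3 (propensity, measurement) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PresepError("zero variance in propensity or measurement")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def beta_gal_validation_table() -> pd.DataFrame:
    """The bundled six-beta-galactosidase validation set.

    Columns: protein, predicted secretion propensity (Type I, w = 0.05,
    lambda = 19) and measured extracellular activity percentage.
    """
    with resources.as_file(
        resources.files("presep.data").joinpath("beta_gal_validation.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")
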