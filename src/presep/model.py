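"""Random-forest secretion classifier: propensity, call, reliability index.

The classifier is an ensemble of decision trees; its output for a protein is
the secretion propensity O, defined as the fraction of trees voting for the
secreted class, so O lies in [0, 1]. A protein is called secreted when
O >= 0.5 (ties included, a fixed convention). Each prediction carries a
reliability index

    RI = floor(20 * |O - 0.5|)  in {0, ..., 10}

grading how far the vote is from an even split: 0 is uninformative, 10 a
unanimous forest. No resampling or class weighting is applied by default —
imbalanced training sets (the realistic regime is roughly 1 secreted to 7
non-secreted) are used as-is; ``class_weight`` is exposed for exploration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ModelError, PresepError
from .pseaac import PseAACParams

N_TREES_DEFAULT = 500

_MODEL_FORMAT_VERSION = 1


def reliability_index(O: float) -> int:
    """RI = floor(20*|O - 0.5|), an integer confidence grade in {0..10}.

    The product is rounded at 1e-9 before flooring so vote fractions that
    are exact grid points in decimal (e.g. O = 0.55) are not pushed below
    the floor boundary by binary floating-point representation.
    """
    if not 0.0 <= O <= 1.0:
        raise ModelError(f"propensity O must be in [0, 1], got {O}")
    return int(math.floor(round(20.0 * abs(O - 0.5), 9)))


@dataclass
class PredictionResult:
    seq_id: str
    propensity: float  # O, fraction of trees voting "secreted"
    call: int  # 1 = secreted, 0 = not secreted
    ri: int


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reuse it consistently."""

    forest: RandomForestClassifier
    params: PseAACParams | None
    n_trees: int
    seed: int
    class_counts: tuple[int, int]  # (n_positive, n_negative)
    n_features: int

    def metadata(self) -> dict:
        return {
            "format_version": _MODEL_FORMAT_VERSION,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "class_counts": list(self.class_counts),
            "n_features": self.n_features,
            "pseaac_params": self.params.to_dict() if self.params else None,
        }


def train(
    features: np.ndarray,
    labels,
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
    params: PseAACParams | None = None,
    class_weight=None,
) -> TrainedModel:
    """Fit the forest on a rectangular feature matrix and 0/1 labels.

    Deterministic given (data, settings, seed). Requires at least two
    examples of each class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ModelError(
            f"feature matrix {X.shape} does not match {y.shape[0]} labels"
        )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ModelError(
            f"need >= 2 examples per class, got {n_pos} positive / {n_neg} negative"
        )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        class_weight=class_weight,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        params=params,
        n_trees=n_trees,
        seed=seed,
        class_counts=(n_pos, n_neg),
        n_features=X.shape[1],
    )


def vote_fractions(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Secreted-class vote fraction O per row: mean of per-tree hard votes."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ModelError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match training dimension {model.n_features}"
        )
    # Per-tree argmax votes, not averaged leaf probabilities: O must be a
    # vote share for the RI grid to be meaningful.
    classes = model.forest.classes_
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += classes[np.argmax(tree.predict_proba(X), axis=1)] == 1
    return votes / len(model.forest.estimators_)


def predict(
    model: TrainedModel, features: np.ndarray, ids=None
) -> list[PredictionResult]:
    """One :class:`PredictionResult` per feature row."""
    O = vote_fractions(model, features)
    if ids is None:
        ids = [str(i) for i in range(len(O))]
    if len(ids) != len(O):
        raise ModelError(f"{len(ids)} ids for {len(O)} feature rows")
    return [
        PredictionResult(
            seq_id=i,
            propensity=float(o),
            call=int(o >= 0.5),
            ri=reliability_index(float(o)),
        )
        for i, o in zip(ids, O)
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model plus a JSON metadata sidecar (<path>.meta.json)."""
    path = Path(path)
    joblib.dump(
        {"forest": model.forest, "metadata": model.metadata()},
        path,
        compress=0,
    )
    Path(str(path) + ".meta.json").write_text(
        json.dumps(model.metadata(), indent=2) + "\n"
    )


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
        meta = payload["metadata"]
        pp = meta.get("pseaac_params")
        return TrainedModel(
            forest=payload["forest"],
            params=PseAACParams.from_dict(pp) if pp else None,
            n_trees=meta["n_trees"],
            seed=meta["seed"],
            class_counts=tuple(meta["class_counts"]),
            n_features=meta["n_features"],
        )
    except PresepError:
        raise
    except Exception as e:
        raise ModelError(f"cannot load model from {path}: {e}") from e
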