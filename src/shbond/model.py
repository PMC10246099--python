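"""Undersampled gradient-boosted ensemble for SHB/NHB classification.

Training draws 10 balanced datasets by undersampling the majority NHB class,
selects the interaction depth of each member by 10-fold cross-validation over
a candidate grid, fits boosted decision trees with an exponential
(AdaBoost-type) loss on the full balanced dataset, and averages the 10 member
probabilities at prediction time. The recommended classification threshold on
the averaged probability is 0.870.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import KFold

from .features import (
    FEATURE_NAMES,
    CATEGORICAL_VOCABS,
    HBDataset,
    HBFeatureVector,
    VOCAB_VERSION,
    encode_dataset,
    encode_frame,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1"
DEFAULT_THRESHOLD = 0.870


class MemberTrainingError(RuntimeError):
    pass


class ModelVersionError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoostConfig:
    """Hyperparameters of the boosted ensemble.

    Defaults are the release settings: 5000 trees, shrinkage 0.01,
    exponential loss, interaction depth cross-validated over 1..12 with 10
    folds, 10 members, threshold 0.870.
    """

    n_trees: int = 5000
    shrinkage: float = 0.01
    loss: str = "exponential"
    depth_grid: tuple[int, ...] = tuple(range(1, 13))
    cv_folds: int = 10
    n_members: int = 10
    threshold: float = DEFAULT_THRESHOLD
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrinkage <= 1.0):
            raise ValueError("shrinkage must be in (0, 1]")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if not self.depth_grid:
            raise ValueError("depth_grid must be non-empty")

    @property
    def member_seeds(self) -> list[int]:
        return [self.base_seed + k for k in range(self.n_members)]


def fast_config(base_seed: int = 0, **overrides) -> BoostConfig:
    """Reduced-cost configuration (500 trees, fixed small depth grid)."""
    defaults = dict(n_trees=500, depth_grid=(3,), base_seed=base_seed)
    defaults.update(overrides)
    return BoostConfig(**defaults)


def undersample(train: HBDataset, seed: int) -> HBDataset:
    """Balance a dataset by random NHB undersampling.

    All SHBs are kept; NHBs are drawn without replacement down to the SHB
    count. An already balanced (or SHB-majority) input is returned unchanged.
    """
    shb_idx = [i for i, (_, lab) in enumerate(train.rows) if lab == "SHB"]
    nhb_idx = [i for i, (_, lab) in enumerate(train.rows) if lab == "NHB"]
    if len(shb_idx) > len(nhb_idx):
        logger.warning(
            "SHB count (%d) exceeds NHB count (%d); returning input unchanged",
            len(shb_idx), len(nhb_idx),
        )
        return train
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(nhb_idx), size=len(shb_idx), replace=False))
    keep = sorted(shb_idx + [nhb_idx[i] for i in chosen])
    return HBDataset(
        rows=[train.rows[i] for i in keep],
        provenance=[train.provenance[i] for i in keep],
    )


def _fit_member(X, y, depth: int, config: BoostConfig, seed: int) -> GradientBoostingClassifier:
    clf = GradientBoostingClassifier(
        loss="exponential",
        n_estimators=config.n_trees,
        learning_rate=config.shrinkage,
        max_depth=depth,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def _exponential_loss(clf, X, y) -> float:
    # exponential loss exp(-y_signed * F) on the boosted margin
    raw = clf.decision_function(X)
    y_signed = 2.0 * y - 1.0
    return float(np.mean(np.exp(-y_signed * raw)))


def select_depth(balanced: HBDataset, config: BoostConfig, seed: int) -> int:
    """Pick the interaction depth by K-fold cross-validated exponential loss.

    Each candidate depth is scored by the mean validation loss over the
    folds; the smallest depth attaining the minimum wins, and the fold
    assignment is fixed by ``seed``.
    """
    if len(config.depth_grid) == 1:
        return config.depth_grid[0]
    X, y = encode_dataset(balanced)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"need at least {config.cv_folds} rows per class for CV, have {counts}"
        )
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    mean_loss = {}
    for depth in config.depth_grid:
        losses = []
        for tr, va in folds:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a CV fold lost one class; dataset too small")
            clf = _fit_member(X[tr], y[tr], depth, config, seed)
            losses.append(_exponential_loss(clf, X[va], y[va]))
        mean_loss[depth] = float(np.mean(losses))
    best = min(mean_loss.values())
    return min(d for d, v in mean_loss.items() if v == best)


@dataclass
class EnsembleModel:
    members: list
    depths: list[int]
    config: BoostConfig
    vocab_version: str = VOCAB_VERSION
    format_version: str = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if len(self.members) != len(self.depths):
            raise ValueError("one depth per member required")


def train_ensemble(train: HBDataset, config: Optional[BoostConfig] = None) -> EnsembleModel:
    """Fit the full undersampling ensemble on a labeled dataset.

    For each member seed: undersample to balance, cross-validate the depth on
    the balanced dataset, then refit on the entire balanced dataset with the
    configured tree count and shrinkage.
    """
    config = config or BoostConfig()
    labels = set(train.labels())
    if labels != {"SHB", "NHB"}:
        raise ValueError(f"training data must contain both classes, has {sorted(labels)}")
    members = []
    depths = []
    for k, seed in enumerate(config.member_seeds):
        try:
            balanced = undersample(train, seed)
            depth = select_depth(balanced, config, seed)
            X, y = encode_dataset(balanced)
            members.append(_fit_member(X, y, depth, config, seed))
            depths.append(depth)
        except Exception as exc:
            raise MemberTrainingError(f"member {k} failed: {exc}") from exc
    return EnsembleModel(members=members, depths=depths, config=config)


def _as_frame(x: Union[HBFeatureVector, HBDataset, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(x, HBFeatureVector):
        return pd.DataFrame.from_records([x.as_dict()])
    if isinstance(x, HBDataset):
        return x.to_frame()
    return x


def member_probabilities(model: EnsembleModel, x) -> np.ndarray:
    """(n_samples, n_members) matrix of per-member SHB probabilities.

    Each member maps its boosted margin F(x) through the exponential-loss
    link 1/(1 + exp(-2F)).
    """
    df = _as_frame(x)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature vector arity violation; missing {missing}")
    X = encode_frame(df)
    return np.column_stack([m.predict_proba(X)[:, 1] for m in model.members])


def predict_proba(model: EnsembleModel, x) -> np.ndarray:
    """Averaged SHB probability: the arithmetic mean of the member outputs."""
    return member_probabilities(model, x).mean(axis=1)


def classify(prob, threshold: float = DEFAULT_THRESHOLD):
    """SHB iff the probability is greater than or equal to the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    prob = np.asarray(prob, dtype=float)
    out = np.where(prob >= threshold, "SHB", "NHB")
    return out.item() if out.ndim == 0 else out


def feature_importance(model: EnsembleModel) -> dict[str, float]:
    """Relative-influence importance scores, in percent summing to 100.

    Each member's impurity-reduction scores are normalized to 100 and the
    per-feature scores averaged across members.
    """
    per_member = []
    for m in model.members:
        imp = np.asarray(m.feature_importances_, dtype=float)
        total = imp.sum()
        per_member.append(imp * (100.0 / total) if total > 0 else
                          np.full_like(imp, 100.0 / len(imp)))
    mean = np.mean(per_member, axis=0)
    return dict(zip(FEATURE_NAMES, mean.tolist()))


def save_model(model: EnsembleModel, path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "vocab_version": model.vocab_version,
            "config": model.config,
            "depths": model.depths,
            "members": model.members,
            "vocabularies": CATEGORICAL_VOCABS,
        },
        path,
    )


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"model format {payload.get('format_version')!r} != "
            f"supported {MODEL_FORMAT_VERSION!r}"
        )
    if payload.get("vocab_version") != VOCAB_VERSION:
        raise ModelVersionError(
            f"model vocabularies {payload.get('vocab_version')!r} != "
            f"current {VOCAB_VERSION!r}"
        )
    return EnsembleModel(
        members=payload["members"],
        depths=payload["depths"],
        config=payload["config"],
        vocab_version=payload["vocab_version"],
        format_version=payload["format_version"],
    )
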