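"""Class-imbalance treatment: SMOTE oversampling and the focal loss.

ECG archives are dominated by normal beats; the ectopic classes the
clinician actually cares about can be orders of magnitude rarer.  Two
complementary remedies are implemented:

* **SMOTE** synthesizes new minority beats in the 300-dimensional
  time-domain beat space.  For each synthetic sample a minority beat ``Z``
  and one of its ``k`` nearest same-class neighbours ``Z_r`` are drawn and a
  new beat is placed at ``Z + r (Z_r - Z)`` with ``r ~ U(0, 1)``
  (``interpolate`` mode, the standard construction).  A ``paper_literal``
  mode emitting ``Z + r |Z - Z_r|`` elementwise is kept for comparison; its
  absolute value biases synthetic beats upward and is not the default.

* **Focal loss** re-weights cross-entropy by ``(1 - p_t)^gamma`` so that
  confidently-classified (easy, mostly majority-class) samples contribute
  little gradient: ``FL = -(1 - p_t)^gamma log(p_t)`` where ``p_t`` is the
  probability the model assigns to the true class.  ``gamma = 0`` recovers
  plain cross-entropy; the default ``gamma = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_counts: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    mode: str = "interpolate"  # or "paper_literal"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.mode not in ("interpolate", "paper_literal"):
            raise ValueError(f"unknown SMOTE mode {self.mode!r}")


@dataclass(frozen=True)
class FocalLossConfig:
    gamma: float = 2.0
    class_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def smote(X: np.ndarray, y: np.ndarray, cfg: SmoteConfig
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample minority classes to the configured target counts.

    Returns ``(X_out, y_out, synthetic_flag)``; the originals appear first,
    bit-identical, followed by the synthetic samples.  Classes absent from
    ``target_counts`` (or already at/above target) are passed through.
    Neighbour search is Euclidean in sample space; distance ties are broken
    by index order.  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    rng = np.random.default_rng(cfg.seed)
    new_rows: list[np.ndarray] = []
    new_labels: list = []
    for label in sorted(cfg.target_counts):
        target = int(cfg.target_counts[label])
        idx = np.flatnonzero(y == label)
        have = len(idx)
        if target < have:
            raise ValueError(f"target {target} for class {label!r} below existing {have}")
        n_new = target - have
        if n_new == 0:
            continue
        if have < cfg.k_neighbors + 1:
            raise ValueError(
                f"class {label!r} has {have} samples; SMOTE with k={cfg.k_neighbors} "
                f"needs at least {cfg.k_neighbors + 1}")
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xc)
        # drop self-neighbour in column 0; sklearn's kneighbors is
        # index-order stable on ties
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, have, size=n_new)
        pick = rng.integers(0, cfg.k_neighbors, size=n_new)
        r = rng.random(n_new)
        Z = Xc[base]
        Zr = Xc[neigh[base, pick]]
        if cfg.mode == "interpolate":
            Znew = Z + r[:, None] * (Zr - Z)
        else:  # paper_literal: elementwise absolute difference
            Znew = Z + r[:, None] * np.abs(Z - Zr)
        new_rows.append(Znew)
        new_labels.extend([label] * n_new)
    if new_rows:
        X_out = np.vstack([X] + new_rows)
        y_out = np.concatenate([y, np.array(new_labels, dtype=object)])
    else:
        X_out, y_out = X.copy(), y.copy()
    flag = np.zeros(len(X_out), dtype=bool)
    flag[len(X):] = True
    return X_out, y_out, flag


class SmoteResampler:
    """sklearn/imblearn-style wrapper around :func:`smote`.

    ``target_counts=None`` balances every class up to the majority count.
    """

    def __init__(self, k_neighbors: int = 5, target_counts: Mapping[str, int] | None = None,
                 mode: str = "interpolate", random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target_counts = target_counts
        self.mode = mode
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("k_neighbors", "target_counts", "mode", "random_state")}

    def set_params(self, **params) -> "SmoteResampler":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=object)
        targets = self.target_counts
        if targets is None:
            labels, counts = np.unique(y.astype(str), return_counts=True)
            top = counts.max()
            targets = {lab: int(top) for lab in labels}
        cfg = SmoteConfig(self.k_neighbors, targets, self.random_state, self.mode)
        X_out, y_out, flag = smote(X, y, cfg)
        self.synthetic_flag_ = flag
        return X_out, y_out


def focal_loss(probs: np.ndarray, true_class: np.ndarray,
               cfg: FocalLossConfig | None = None,
               class_order: np.ndarray | None = None) -> float:
    """Mean focal loss of predicted class probabilities.

    ``probs`` is (n, C) rows summing to 1 (a single vector is accepted);
    ``true_class`` holds labels indexing ``class_order`` (defaults to the
    column index).  Per sample: ``-(w_c) (1 - p_t)^gamma ln(p_t)`` with
    ``p_t`` clamped at 1e-12.
    """
    cfg = cfg or FocalLossConfig()
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    t = np.atleast_1d(np.asarray(true_class))
    if len(P) != len(t):
        raise ValueError("probs and true_class lengths differ")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if class_order is not None:
        order = list(class_order)
        cols = np.array([order.index(lab) for lab in t])
    else:
        cols = t.astype(int)
    pt = P[np.arange(len(P)), cols]
    if np.any(pt <= 0):
        import warnings
        warnings.warn("true-class probability of 0 clamped to 1e-12", stacklevel=2)
        pt = np.maximum(pt, 1e-12)
    losses = -((1.0 - pt) ** cfg.gamma) * np.log(pt)
    if cfg.class_weights is not None:
        w = np.array([cfg.class_weights.get(lab, 1.0) for lab in
                      (t if class_order is not None else cols)])
        losses = w * losses
    return float(losses.mean())
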