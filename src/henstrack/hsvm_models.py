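"""The hybrid SVM appearance model: three sub-models and their fusion.

A candidate region's confidence is the weighted mean of three normalized
support-vector scores:

* a binary classifier (target vs. background) — robust to pose change,
* an epsilon-regressor predicting the candidate's overlap ratio with the
  target — sharpens localization and counters drift,
* a one-class estimator trained only on accepted target appearances —
  insensitive to background change.

Raw scores are the kernel decision functions

    conf_b(x) = sum_i a_i y_i k_b(x_i, x)
    conf_r(x) = sum_i (a_i - a_i*) k_r(x_i, x)
    conf_o(x) = sum_i a_i k_o(x_i, x)

min-max normalized into [0, 1] across the candidate batch of one search
step and fused as

    conf(x) = (w_o confn_o + w_r confn_r + w_b confn_b) / (w_o + w_r + w_b)

with default weights (0.3, 0.6, 0.1).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC, SVR, OneClassSVM

from .sampling import SamplePools

__all__ = ["KernelConfig", "FusionWeights", "ConfidenceBundle", "HsvmModel",
           "train", "score", "best_candidate"]


@dataclass(frozen=True)
class KernelConfig:
    """Shared kernel family and per-model hyperparameters.

    The default RBF bandwidth follows the 1 / (n_features * var(X))
    heuristic; C, epsilon and nu are standard library defaults kept
    configurable.
    """

    kernel: str = "rbf"
    gamma: str | float = "scale"
    C_binary: float = 1.0
    C_regression: float = 1.0
    epsilon: float = 0.1
    nu: float = 0.1


@dataclass(frozen=True)
class FusionWeights:
    w_o: float = 0.3
    w_r: float = 0.6
    w_b: float = 0.1

    def __post_init__(self) -> None:
        if min(self.w_o, self.w_r, self.w_b) < 0 or self.w_o + self.w_r + self.w_b <= 0:
            raise ValueError("fusion weights must be non-negative with positive sum")


@dataclass(frozen=True)
class ConfidenceBundle:
    """Raw, normalized and fused confidence scores of one candidate."""

    conf_o: float
    conf_r: float
    conf_b: float
    confn_o: float
    confn_r: float
    confn_b: float
    conf: float


def fuse(confn_o, confn_r, confn_b, weights: FusionWeights = FusionWeights()):
    """Weighted mean of the three normalized channels."""
    total = weights.w_o + weights.w_r + weights.w_b
    return (weights.w_o * np.asarray(confn_o) + weights.w_r * np.asarray(confn_r)
            + weights.w_b * np.asarray(confn_b)) / total


@dataclass
class HsvmModel:
    binary_model: SVC
    regr_model: SVR
    oneclass_model: OneClassSVM
    weights: FusionWeights = field(default_factory=FusionWeights)
    kernel_cfg: KernelConfig = field(default_factory=KernelConfig)

    def save(self, path) -> None:
        """Serialize support vectors, coefficients and configs to one file."""
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "HsvmModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValueError("file does not contain an HsvmModel archive")
        return model


def train(pools: SamplePools, kernel_cfg: KernelConfig = KernelConfig(),
          weights: FusionWeights = FusionWeights()) -> HsvmModel:
    """Fit the three sub-models on the current pools.

    Binary labels are stored as {+1, 0} but trained as {+1, -1}; with
    {+1, 0} the negative terms of the binary decision sum would vanish.
    Deterministic: identical pools give identical decision functions.
    """
    pos, neg = pools.binary_pos, pools.binary_neg
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("binary pools need at least 2 samples per class")
    regr = pools.regr_pos + pools.regr_neg
    if len(regr) < 2:
        raise ValueError("regression pool needs at least 2 samples")
    if len(pools.oneclass) < 1:
        raise ValueError("one-class pool needs at least 1 sample")

    Xb = np.array([s.feature for s in pos + neg])
    yb = np.array([1.0] * len(pos) + [-1.0] * len(neg))
    svc = SVC(kernel=kernel_cfg.kernel, C=kernel_cfg.C_binary,
              gamma=kernel_cfg.gamma)
    svc.fit(Xb, yb)

    Xr = np.array([s.feature for s in regr])
    yr = np.array([s.label for s in regr])
    svr = SVR(kernel=kernel_cfg.kernel, C=kernel_cfg.C_regression,
              epsilon=kernel_cfg.epsilon, gamma=kernel_cfg.gamma)
    svr.fit(Xr, yr)

    Xo = np.array([s.feature for s in pools.oneclass])
    ocs = OneClassSVM(kernel=kernel_cfg.kernel, nu=kernel_cfg.nu,
                      gamma=kernel_cfg.gamma)
    ocs.fit(Xo)

    return HsvmModel(svc, svr, ocs, weights=weights, kernel_cfg=kernel_cfg)


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0.0:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def score(model: HsvmModel, feats: Sequence[np.ndarray] | np.ndarray
          ) -> list[ConfidenceBundle]:
    """Score a candidate batch: raw decision values, per-batch min-max
    normalization, weighted fusion. Order-preserving and deterministic."""
    X = np.asarray(feats, dtype=float)
    if X.ndim == 1:
        X = X[None]
    if X.shape[0] == 0:
        raise ValueError("empty candidate batch")
    raw_b = model.binary_model.decision_function(X)
    raw_r = model.regr_model.predict(X)
    raw_o = model.oneclass_model.decision_function(X)
    n_b, n_r, n_o = _minmax(raw_b), _minmax(raw_r), _minmax(raw_o)
    conf = fuse(n_o, n_r, n_b, model.weights)
    return [
        ConfidenceBundle(float(raw_o[i]), float(raw_r[i]), float(raw_b[i]),
                         float(n_o[i]), float(n_r[i]), float(n_b[i]),
                         float(conf[i]))
        for i in range(X.shape[0])
    ]


def best_candidate(bundles: Sequence[ConfidenceBundle]) -> int:
    """Index of the highest fused confidence; ties go to the earliest index."""
    if len(bundles) == 0:
        raise ValueError("no candidates to rank")
    best, best_conf = 0, bundles[0].conf
    for i, b in enumerate(bundles[1:], start=1):
        if b.conf > best_conf:
            best, best_conf = i, b.conf
    return best
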