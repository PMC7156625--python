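"""Training protocol: augmentation, subject-level splits, MSE/Adam loop with
mean-R² early stopping, and the sklearn-style estimator wrapping it all.

Augmentation follows the published scheme: a uniform integer translation of
up to ±15 voxels along one randomly selected axis, followed by three
consecutive 90° rotations about (independently chosen) principal axes.  Both
are pure voxel permutations/shifts — no interpolation — so a phantom's
analytic morphometry is untouched and the paired target vector never changes.

Targets spanning mm³ (10²–10⁵) and mm⁻¹ (10⁻²) scales would let volumes
dominate a raw MSE, so per-target z-scaling is on by default (the raw-MSE
reading of the protocol remains available via ``target_scaling="off"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _nn
from .network import NetworkSpec, build_model, desk_spec
from .phantom import PhantomSample, SubjectRecord

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "TrainHistory",
    "augment",
    "rotate90",
    "translate",
    "steps_per_epoch",
    "make_splits",
    "CNNMorphometryRegressor",
    "train",
    "predict",
]


# ---------------------------------------------------------------------------
# Augmentation


def translate(volume: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Integer shift along one axis; shifted-out voxels discarded, vacated
    voxels zero-filled."""
    if shift == 0:
        return volume.copy()
    out = np.zeros_like(volume)
    n = volume.shape[axis]
    src = [slice(None)] * volume.ndim
    dst = [slice(None)] * volume.ndim
    src[axis] = slice(max(0, -shift), min(n, n - shift))
    dst[axis] = slice(max(0, shift), min(n, n + shift))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def rotate90(volume: np.ndarray, axis: int, k: int = 1) -> np.ndarray:
    """Rotate 90°·k about a principal axis (0, 1 or 2)."""
    planes = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    return np.rot90(volume, k=k, axes=planes[axis])


def augment(
    volume: np.ndarray,
    rng: np.random.Generator,
    max_translation: int = 15,
    single_axis: bool = False,
    rotations: bool = True,
) -> np.ndarray:
    """One random translation then three consecutive 90° rotations.

    ``single_axis=True`` draws one axis for all three rotations (the
    "single 270° rotation" reading); the default draws an independent axis
    per rotation, which covers the full 24-element cubic rotation group.
    ``rotations=False`` applies the translation only.
    """
    axis = int(rng.integers(0, 3))
    shift = int(rng.integers(-max_translation, max_translation + 1))
    out = translate(volume, axis, shift)
    if not rotations:
        return out
    rot_axis = int(rng.integers(0, 3))
    for _ in range(3):
        out = rotate90(out, rot_axis)
        if not single_axis:
            rot_axis = int(rng.integers(0, 3))
    return out


def steps_per_epoch(n_train: int, batch_size: int) -> int:
    """Optimizer steps per epoch: every sample seen once, last batch short."""
    if n_train < 1:
        raise ValueError("need at least one training sample")
    return math.ceil(n_train / batch_size)


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitPlan:
    """Subject-level train/validate/test assignment."""

    assignment: dict[str, str]

    def subjects(self, split: str) -> list[str]:
        return sorted(s for s, v in self.assignment.items() if v == split)

    def split_of(self, subject_id: str) -> str:
        return self.assignment[subject_id]


def make_splits(
    subjects: Sequence[SubjectRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_extra_splits: int = 0,
    seed: int = 0,
) -> list[SplitPlan]:
    """Subject-level splits with rescan handling and disjoint held-out sets.

    The primary plan forces every rescan subject (more than one scan) into
    the test set.  Across all plans the test sets are pairwise disjoint and
    the validation sets are pairwise disjoint (non-exhaustive cross
    validation).
    """
    rng = np.random.default_rng(seed)
    ids = [s.subject_id for s in subjects]
    rescan = [s.subject_id for s in subjects if len(s.scan_ids) > 1]
    n = len(ids)
    n_plans = 1 + n_extra_splits
    n_test = max(1, round(ratios[2] * n))
    n_val = max(1, round(ratios[1] * n))
    if n_plans * (n_test + n_val) > n or len(rescan) > n_test:
        raise ValueError(
            f"cannot carve {n_plans} disjoint validation+test sets "
            f"({n_plans}x({n_val}+{n_test})) from {n} subjects"
        )
    others = [i for i in ids if i not in set(rescan)]
    rng.shuffle(others)
    pool = rescan + others  # rescan subjects land in plan 0's test set
    plans: list[SplitPlan] = []
    k = 0
    held: list[tuple[list[str], list[str]]] = []
    for _ in range(n_plans):
        test = pool[k : k + n_test]
        k += n_test
        held.append((test, []))
    for j in range(n_plans):
        held[j] = (held[j][0], pool[k : k + n_val])
        k += n_val
    for test, val in held:
        assignment = {i: "train" for i in ids}
        for i in test:
            assignment[i] = "test"
        for i in val:
            assignment[i] = "validate"
        plans.append(SplitPlan(assignment))
    return plans


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 6
    max_epochs: int = 100
    validation_period_epochs: int = 20
    max_translation: int = 15
    seed: int = 0
    target_scaling: str = "per_target_z"  # off | per_target_z
    dropout: float = 0.5
    augment: bool = True
    single_axis_rotations: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if self.target_scaling not in ("off", "per_target_z"):
            raise ValueError(f"unknown target_scaling {self.target_scaling!r}")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_mean_r2: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Epoch whose recorded validation mean R² is maximal."""
        if not self.epochs:
            raise ValueError("empty history")
        return self.epochs[int(np.argmax(self.val_mean_r2))]

    @property
    def best_val_mean_r2(self) -> float:
        return float(np.max(self.val_mean_r2))


def _mean_r2(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean coefficient of determination across targets (constant-reference
    targets excluded)."""
    ss_res = ((pred - ref) ** 2).sum(axis=0)
    ss_tot = ((ref - ref.mean(axis=0)) ** 2).sum(axis=0)
    ok = ss_tot > 0
    if not ok.any():
        return float("nan")
    return float((1.0 - ss_res[ok] / ss_tot[ok]).mean())


class CNNMorphometryRegressor(BaseEstimator, RegressorMixin):
    """3-D CNN regressor from volumes to morphometry vectors.

    Parameters mirror the published protocol (Adam on MSE, batch size 6,
    initial learning rate 1e-5, translation/rotation augmentation, best-epoch
    selection by validation mean R² every ``validation_period_epochs``).
    Desk-scale defaults for ``spec`` use the scaled-down architecture; pass
    ``spec=default_spec()`` for the full 256³ network.

    Attributes set by :meth:`fit`: ``model_``, ``history_``, ``best_epoch_``,
    ``target_mean_``, ``target_scale_``, ``n_targets_``.
    """

    def __init__(
        self,
        spec: NetworkSpec | None = None,
        learning_rate: float = 1e-5,
        batch_size: int = 6,
        max_epochs: int = 100,
        validation_period_epochs: int = 20,
        max_translation: int = 15,
        target_scaling: str = "per_target_z",
        dropout: float = 0.5,
        augment: bool = True,
        single_axis_rotations: bool = False,
        rotation_augment: bool = True,
        fc_init: str = "zero",
        input_scaling: str = "off",
        random_state: int = 0,
    ):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_period_epochs = validation_period_epochs
        self.max_translation = max_translation
        self.target_scaling = target_scaling
        self.dropout = dropout
        self.augment = augment
        self.single_axis_rotations = single_axis_rotations
        self.rotation_augment = rotation_augment
        self.fc_init = fc_init
        self.input_scaling = input_scaling
        self.random_state = random_state

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on volumes ``X (n, E, E, E)`` and targets ``y (n, T)``.

        Without an explicit validation set, the training set doubles as the
        validation set for best-epoch bookkeeping.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 4 or X.shape[0] != y.shape[0]:
            raise ValueError(f"bad shapes X {X.shape}, y {y.shape}")
        spec = self.spec or desk_spec(input_edge=X.shape[1],
                                      output_width=y.shape[1])
        if X.shape[1:] != (spec.input_edge,) * 3:
            raise ValueError(
                f"volumes of shape {X.shape[1:]} do not match the network "
                f"input edge {spec.input_edge}"
            )
        if spec.output_width != y.shape[1]:
            raise ValueError(
                f"spec output width {spec.output_width} != targets {y.shape[1]}"
            )
        # optional input scaling; off by default (the canonical pipeline
        # already fixes the 0-4095 range). "z" standardizes voxel intensities
        # with the training-set mean/sd, "max" divides by the training max.
        if self.input_scaling == "z":
            sd = float(X.std()) or 1.0
            self.input_shift_, self.input_scale_ = float(X.mean()), sd
        elif self.input_scaling == "max":
            self.input_shift_, self.input_scale_ = 0.0, float(X.max()) or 1.0
        elif self.input_scaling == "off":
            self.input_shift_, self.input_scale_ = 0.0, 1.0
        else:
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")
        if (self.input_shift_, self.input_scale_) != (0.0, 1.0):
            X = (X - np.float32(self.input_shift_)) / np.float32(self.input_scale_)

        rng = np.random.default_rng(self.random_state)
        model = build_model(spec, seed=int(rng.integers(2**31)),
                            fc_init=self.fc_init, dropout=self.dropout)

        if self.target_scaling == "per_target_z":
            self.target_mean_ = y.mean(axis=0)
            scale = y.std(axis=0, ddof=0)
            scale[scale == 0] = 1.0
            self.target_scale_ = scale
        else:
            self.target_mean_ = np.zeros(y.shape[1])
            self.target_scale_ = np.ones(y.shape[1])
        ys = (y - self.target_mean_) / self.target_scale_

        opt = _nn.Adam(model.params(), lr=self.learning_rate)
        history = TrainHistory()
        best_weights = model.get_weights()
        best_r2 = -np.inf
        n = X.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if self.augment:
                    xb = np.stack(
                        [augment(X[i], rng, self.max_translation,
                                 self.single_axis_rotations,
                                 rotations=self.rotation_augment) for i in idx]
                    )
                else:
                    xb = X[idx]
                yb = ys[idx]
                out = model.forward(xb[:, None], train=True)
                if not np.isfinite(out).all():
                    raise FloatingPointError(
                        f"non-finite activations at epoch {epoch}"
                    )
                diff = out - yb
                loss = float((diff**2).mean())
                epoch_loss += loss * len(idx)
                model.backward((2.0 / diff.size) * diff.astype(np.float32))
                opt.step(model.grads())
            epoch_loss /= n
            if epoch % self.validation_period_epochs == 0 or epoch == self.max_epochs:
                if X_val is not None:
                    xv = (np.asarray(X_val, np.float32) - np.float32(self.input_shift_)) \
                        / np.float32(self.input_scale_)
                    val_pred = self._forward_batched(model, xv)
                    val_ref = (np.asarray(y_val, float) - self.target_mean_) / self.target_scale_
                else:
                    val_pred = self._forward_batched(model, X)
                    val_ref = ys
                r2 = _mean_r2(val_pred, val_ref)
                history.epochs.append(epoch)
                history.train_loss.append(epoch_loss)
                history.val_mean_r2.append(r2)
                if r2 > best_r2:
                    best_r2 = r2
                    best_weights = model.get_weights()
        model.set_weights(best_weights)
        self.model_ = model
        self.spec_ = spec
        self.history_ = history
        self.best_epoch_ = history.best_epoch
        self.n_targets_ = y.shape[1]
        return self

    def _forward_batched(self, model, X: np.ndarray) -> np.ndarray:
        outs = []
        for start in range(0, X.shape[0], self.batch_size):
            outs.append(model.forward(X[start : start + self.batch_size, None]))
        return np.concatenate(outs, axis=0)

    def predict(self, X) -> np.ndarray:
        """Predict morphometry vectors (target scaling inverted)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        squeeze = X.ndim == 3
        if squeeze:
            X = X[None]
        if X.shape[1:] != (self.spec_.input_edge,) * 3:
            raise ValueError(
                f"volumes of shape {X.shape[1:]} do not match the network "
                f"input edge {self.spec_.input_edge}"
            )
        if (getattr(self, "input_shift_", 0.0), getattr(self, "input_scale_", 1.0)) != (0.0, 1.0):
            X = (X - np.float32(self.input_shift_)) / np.float32(self.input_scale_)
        out = self._forward_batched(self.model_, X).astype(np.float64)
        out = out * self.target_scale_ + self.target_mean_
        return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Functional wrappers over PhantomSample collections


def _stack(samples: Sequence[PhantomSample], target_idx: np.ndarray):
    X = np.stack([s.volume.data for s in samples]).astype(np.float32)
    y = np.stack([s.truth.values[target_idx] for s in samples])
    return X, y


def train(
    samples: Sequence[PhantomSample],
    plan: SplitPlan,
    config: TrainConfig | None = None,
    spec: NetworkSpec | None = None,
    fc_init: str = "zero",
):
    """Train on the plan's train subjects; returns (estimator, history).

    Targets are the truth entries populated in the samples (bound targets).
    """
    config = config or TrainConfig()
    bound = samples[0].truth.mask
    target_idx = np.nonzero(bound)[0]
    tr = [s for s in samples if plan.split_of(s.covariates.subject_id) == "train"]
    va = [s for s in samples if plan.split_of(s.covariates.subject_id) == "validate"]
    X, y = _stack(tr, target_idx)
    est = CNNMorphometryRegressor(
        spec=spec,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        validation_period_epochs=config.validation_period_epochs,
        max_translation=config.max_translation,
        target_scaling=config.target_scaling,
        dropout=config.dropout,
        augment=config.augment,
        single_axis_rotations=config.single_axis_rotations,
        fc_init=fc_init,
        random_state=config.seed,
    )
    if va:
        Xv, yv = _stack(va, target_idx)
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    est.target_idx_ = target_idx
    return est, est.history_


def predict(est: CNNMorphometryRegressor, volume) -> np.ndarray:
    """Predict for one canonical volume (VolumeGrid or ndarray)."""
    data = volume.data if hasattr(volume, "data") else np.asarray(volume)
    return est.predict(data)
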