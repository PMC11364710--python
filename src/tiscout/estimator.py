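"""Scikit-learn style estimator for TI-scout null-point prediction.

``TIScoutNullModel.fit`` takes a list of :class:`TIScoutSeries` and their
annotated null-frame indices, trains the CNN-BiLSTM end to end with the
weighted binary cross-entropy and differential learning rates, and exposes
``predict`` returning one inversion time (ms) per series.  The estimator
composes with sklearn model selection (``get_params``/``set_params``/
``clone`` all work); :mod:`tiscout.train` provides functional wrappers.
"""

from __future__ import annotations

import time

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .infer import predict_ti
from .model import ModelBundle, ModelSpec, build_model
from .preprocess import (
    AugmentPolicy,
    NormalizationStats,
    normalize,
    resize_stack,
    training_sample,
)
from .series import LabelledSeries, TIScoutSeries


def loss_weight(ti, ti_optimal, cap: float = 3.0):
    """Per-window loss weight min(|ln(T_i / T_optimal)|^-1, cap).

    The weight grows without bound as T_i approaches the optimal TI (the
    cap is returned exactly at equality) and decays like 1/|ln ratio| away
    from it, focusing the loss on frames around the null point.
    Vectorised over ``ti``.
    """
    ti = np.asarray(ti, dtype=float)
    ti_optimal = float(ti_optimal)
    if np.any(ti <= 0) or ti_optimal <= 0:
        raise ValueError("inversion times must be positive")
    with np.errstate(divide="ignore"):
        log_ratio = np.log(ti / ti_optimal)
        w = np.where(log_ratio == 0.0, np.inf, 1.0 / np.abs(log_ratio))
    out = np.minimum(w, cap)
    return float(out) if out.ndim == 0 else out


def weighted_bce(probabilities, targets, weights) -> float:
    """Mean over windows of weight * binary cross-entropy; soft targets
    (e.g. 0.5) are supported."""
    p = np.asarray(probabilities, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if not (p.shape == t.shape == w.shape):
        raise ValueError("probabilities, targets and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    bce = -(t * np.log(p) + (1 - t) * np.log(1 - p))
    return float(np.mean(w * bce))


class TIScoutNullModel(BaseEstimator):
    """CNN-BiLSTM null-point predictor for TI scout series.

    Parameters
    ----------
    backbone : {"vgg16", "resnet18", "se_resnet18"}
    preset : {"full", "tiny"}
        ``full`` is the 256 x 256 standard-width architecture; ``tiny`` is a
        width-reduced 64 x 64 variant that trains in minutes on one CPU.
    spec : ModelSpec, optional
        Explicit architecture, overriding backbone/preset.
    epochs, batch_size, lr_backbone, lr_recurrent, weight_decay, weight_cap
        Training hyperparameters; defaults are the production-scale recipe
        (ADAM, 30 epochs, batch 32, 1.5e-2 / 3e-3, decay 1e-4, cap 3).
    lr_decay : float
        Optional per-epoch exponential learning-rate decay factor
        (0 disables; the default recipe keeps the rates constant).
    augment : bool
        Apply the default flip/rotation/intensity augmentation policy.
    uniform_splice : bool
        Disable the triangular oversampling of splices around the null.
    grad_clip : float or None
        Optional global gradient-norm clip (off by default).
    seed : int
        Drives initialisation, splice/drop sampling and augmentation.
    """

    def __init__(self, backbone: str = "se_resnet18", preset: str = "tiny",
                 spec: ModelSpec | None = None,
                 epochs: int = 30, batch_size: int = 32,
                 lr_backbone: float = 1.5e-2, lr_recurrent: float = 3e-3,
                 weight_decay: float = 1e-4, weight_cap: float = 3.0,
                 lr_decay: float = 0.0, augment: bool = True,
                 uniform_splice: bool = False, grad_clip: float | None = None,
                 seed: int = 0, verbose: int = 0):
        self.backbone = backbone
        self.preset = preset
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_backbone = lr_backbone
        self.lr_recurrent = lr_recurrent
        self.weight_decay = weight_decay
        self.weight_cap = weight_cap
        self.lr_decay = lr_decay
        self.augment = augment
        self.uniform_splice = uniform_splice
        self.grad_clip = grad_clip
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------ helpers
    def _resolved_spec(self) -> ModelSpec:
        if self.spec is not None:
            return self.spec
        if self.preset == "tiny":
            return ModelSpec.tiny(self.backbone)
        if self.preset == "full":
            return ModelSpec.full(self.backbone)
        raise ValueError(f"unknown preset {self.preset!r}")

    @staticmethod
    def _as_labelled(X, y) -> list[LabelledSeries]:
        if y is None:
            if not all(isinstance(s, LabelledSeries) for s in X):
                raise ValueError("pass LabelledSeries, or series plus null indices")
            return list(X)
        if len(X) != len(y):
            raise ValueError("one null index per series is required")
        return [LabelledSeries(series=s, null_index=int(k)) for s, k in zip(X, y)]

    # ------------------------------------------------------------------ fitting
    def fit(self, X, y=None):
        """Train on a list of series.

        ``X`` is a list of :class:`TIScoutSeries` with ``y`` the matching
        null-frame indices, or a list of :class:`LabelledSeries` with
        ``y=None``.
        """
        labelled = self._as_labelled(X, y)
        if len(labelled) == 0:
            raise ValueError("training set is empty")
        for item in labelled:
            if len(item.series) < 9:
                raise ValueError(
                    f"series {item.series.series_id!r} has {len(item.series)} frames; "
                    "training requires at least 9"
                )

        spec = self._resolved_spec()
        rng = np.random.default_rng(self.seed)
        network = build_model(spec, seed=int(rng.integers(0, 2**31 - 1)))
        network.train()

        # resize once up front (commutes with splice/drop), then corpus stats
        side = spec.image_size
        resized = [
            LabelledSeries(
                series=TIScoutSeries(
                    frames=resize_stack(item.series.frames, side),
                    ti_values=item.series.ti_values,
                    vendor=item.series.vendor,
                    series_id=item.series.series_id,
                ),
                null_index=item.null_index,
            )
            for item in labelled
        ]
        stats = NormalizationStats.from_series([item.series for item in resized])
        resized = [
            LabelledSeries(
                series=TIScoutSeries(
                    frames=normalize(item.series.frames, stats),
                    ti_values=item.series.ti_values,
                    vendor=item.series.vendor,
                    series_id=item.series.series_id,
                ),
                null_index=item.null_index,
            )
            for item in resized
        ]

        optimizer = nn.Adam(
            [
                {"params": network.backbone_parameters(), "lr": self.lr_backbone},
                {"params": network.recurrent_parameters(), "lr": self.lr_recurrent},
            ],
            weight_decay=self.weight_decay,
        )
        policy = AugmentPolicy.training_default() if self.augment else None

        n = len(resized)
        history = []
        for epoch in range(self.epochs):
            if self.lr_decay:
                decay = (1.0 - self.lr_decay) ** epoch
                optimizer.groups[0]["lr"] = self.lr_backbone * decay
                optimizer.groups[1]["lr"] = self.lr_recurrent * decay
            t0 = time.perf_counter()
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, n, self.batch_size):
                batch_idx = perm[lo:lo + self.batch_size]
                stacks, targets, weights = [], [], []
                for i in batch_idx:
                    item = resized[i]
                    windows = training_sample(item, rng, policy=policy,
                                              uniform_splice=self.uniform_splice)
                    stacks.append(np.stack([w.channels for w in windows]))
                    targets.append([w.target for w in windows])
                    weights.append(loss_weight(
                        np.array([w.centre_ti for w in windows]),
                        item.null_ti, cap=self.weight_cap,
                    ))
                xb = np.stack(stacks, axis=1)                 # (5, B, 3, S, S)
                tb = np.asarray(targets, dtype=np.float64).T  # (5, B)
                wb = np.stack(weights, axis=1)                # (5, B)

                logits = network.forward_sequence(xb).astype(np.float64)
                p = nn.sigmoid(logits)
                eps = 1e-12
                pc = np.clip(p, eps, 1 - eps)
                loss = float(np.mean(wb * -(tb * np.log(pc) + (1 - tb) * np.log(1 - pc))))
                dlogits = (wb * (p - tb) / p.size).astype(np.float32)

                optimizer.zero_grad()
                network.backward_sequence(dlogits)
                if self.grad_clip:
                    self._clip_gradients(network, self.grad_clip)
                optimizer.step()
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  loss {history[-1]:.4f}  "
                      f"({time.perf_counter() - t0:.1f}s)")

        network.eval()
        self.spec_ = spec
        self.network_ = network
        self.norm_stats_ = stats
        self.history_ = history
        self.bundle_ = ModelBundle(
            spec=spec, network=network, norm_stats=stats, seed=self.seed,
            metadata={"epochs": self.epochs, "n_series": n,
                      "final_loss": history[-1] if history else None},
        )
        return self

    @staticmethod
    def _clip_gradients(network, max_norm: float) -> None:
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in network.parameters()))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in network.parameters():
                p.grad *= scale

    # ---------------------------------------------------------------- inference
    def predict(self, X) -> np.ndarray:
        """Predicted optimal TI (ms) for each series in ``X``."""
        return np.array([p.predicted_ti for p in self.predict_full(X)])

    def predict_frame_index(self, X) -> np.ndarray:
        return np.array([p.predicted_frame_index for p in self.predict_full(X)])

    def predict_full(self, X) -> list:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "bundle_")
        series_list = [x.series if isinstance(x, LabelledSeries) else x for x in X]
        return [predict_ti(self.bundle_, s) for s in series_list]

    def score(self, X, y) -> float:
        """Negative mean absolute TI error (ms); higher is better, so MAE
        stays the quantity sklearn model selection minimises."""
        series_list = [x.series if isinstance(x, LabelledSeries) else x for x in X]
        truth = np.array([
            float(s.ti_values[int(k)]) for s, k in zip(series_list, y)
        ])
        pred = self.predict(series_list)
        return -float(np.mean(np.abs(pred - truth)))
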