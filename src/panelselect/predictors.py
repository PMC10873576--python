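"""Predictive models mapping observed channels to the remaining channels.

The reference backend is a per-pixel multi-output linear (ridge) model fit by
empirical risk minimization on all pooled training pixels: each predicted
channel is an affine function of the observed channel intensities at the
same pixel. This ignores spatial context by design — it is exact on
latent-factor data whose channels are affine combinations of a few anchors,
deterministic, and fast enough to drive the selection loop on one CPU. The
marker-selection procedure itself is agnostic to the predictor family, so
richer spatial backends (e.g. a convolutional encoder–decoder trained on
random patches with sliding-window stitched inference) plug in behind the
same ``fit`` / ``predict`` / ``validation_risks`` surface; ``backend="conv"``
is reserved for such an extension and is not implemented here.

Validation risk per predicted marker is the mean absolute per-pixel error on
the validation split — the same L1 dissimilarity ``ξ`` the marker graph uses
for its edge loadings (shared implementation, see :func:`validation_risks`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import dissimilarity
from .images import MultichannelDataset, MultichannelImage


@dataclass(frozen=True)
class PredictorSpec:
    """Configuration for a predictor backend.

    Parameters
    ----------
    backend
        ``"linear"`` (reference, implemented) or ``"conv"`` (extension point).
    lam
        Ridge regularization strength for the linear backend; the small
        default keeps the normal equations well-posed on collinear channels
        without visibly biasing coefficients.
    patch_size, learning_rate, max_epochs, patience
        Training configuration reserved for patch-based spatial backends
        (patch size default 192, learning rate default 1e-4).
    seed
        Seed for any stochastic element of fitting (unused by the
        closed-form linear backend, recorded for reproducibility).
    """

    backend: str = "linear"
    lam: float = 1e-6
    patch_size: int = 192
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("linear", "conv"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class FittedPredictor:
    """A fitted linear map from observed to predicted channels."""

    input_markers: list[str]
    output_markers: list[str]
    coef: np.ndarray  # (n_outputs, n_inputs)
    intercept: np.ndarray  # (n_outputs,)
    spec: PredictorSpec = field(default_factory=PredictorSpec)
    validation_risk: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.input_markers) & set(self.output_markers):
            raise ValueError("input and output marker lists must be disjoint")
        self.coef = np.asarray(self.coef, dtype=np.float64)
        self.intercept = np.asarray(self.intercept, dtype=np.float64)
        if self.coef.shape != (len(self.output_markers), len(self.input_markers)):
            raise ValueError("coef shape must be (n_outputs, n_inputs)")

    # -- persistence: portable arrays + JSON header -----------------------
    def save(self, path: str | Path) -> Path:
        """Save as ``<path>.npz`` (arrays) + ``<path>.json`` (marker header)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), coef=self.coef, intercept=self.intercept)
        header = {
            "input_markers": self.input_markers,
            "output_markers": self.output_markers,
            "backend": self.spec.backend,
            "lam": self.spec.lam,
            "validation_risk": self.validation_risk,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedPredictor":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        return cls(
            header["input_markers"],
            header["output_markers"],
            arrays["coef"],
            arrays["intercept"],
            PredictorSpec(backend=header["backend"], lam=header["lam"]),
            {k: float(v) for k, v in header["validation_risk"].items()},
        )


def _pooled_pixels(
    images: Sequence[MultichannelImage], names: Sequence[str]
) -> np.ndarray:
    """All pixels of the named channels stacked as (n_pixels, n_channels)."""
    cols = []
    for img in images:
        sub = img.select_channels(names)
        cols.append(sub.pixels.reshape(len(names), -1).T)
    return np.concatenate(cols, axis=0)


def fit(
    spec: PredictorSpec,
    dataset: MultichannelDataset,
    observed: Sequence[str],
) -> FittedPredictor:
    """Fit a predictor of the non-observed channels by ERM (mean squared error).

    The linear backend solves the ridge normal equations
    ``(XᵀX + λ n I) β = XᵀY`` on centered pooled training pixels in closed
    form (λ scaled by the pixel count so its meaning is size-invariant);
    with ``λ = 0`` a least-squares solve handles rank-deficient designs.
    Validation risks (per-marker mean absolute error on the validation
    split) are computed and stored on the returned model.
    """
    if spec.backend == "conv":
        raise NotImplementedError(
            "the conv backend is an extension point; use backend='linear'"
        )
    all_names = dataset.channel_names
    observed = list(observed)
    if not observed:
        raise ValueError("observed set must be nonempty")
    missing = set(observed) - set(all_names)
    if missing:
        raise ValueError(f"observed markers not in dataset: {sorted(missing)}")
    outputs = [m for m in all_names if m not in set(observed)]
    if not outputs:
        raise ValueError("observed set must be a strict subset of the markers")

    X = _pooled_pixels(dataset.train_images, observed)
    Y = _pooled_pixels(dataset.train_images, outputs)
    n = X.shape[0]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if spec.lam > 0:
        gram = Xc.T @ Xc + spec.lam * n * np.eye(Xc.shape[1])
        coef = np.linalg.solve(gram, Xc.T @ Yc).T
    else:
        coef = np.linalg.lstsq(Xc, Yc, rcond=None)[0].T
    intercept = y_mean - coef @ x_mean

    model = FittedPredictor(observed, outputs, coef, intercept, spec)
    if dataset.val_images:
        model.validation_risk = validation_risks(model, dataset.val_images)
    return model


def predict(
    model: FittedPredictor, img: MultichannelImage
) -> MultichannelImage:
    """Predict the model's output channels for one image.

    ``img`` must contain every input channel (extra channels are ignored and
    order is corrected by name). Returns an image whose channels are the
    model's outputs, in the model's output order.
    """
    missing = set(model.input_markers) - set(img.channel_names)
    if missing:
        raise ValueError(f"image lacks input channels: {sorted(missing)}")
    sub = img.select_channels(model.input_markers)
    h, w = sub.shape
    X = sub.pixels.reshape(len(model.input_markers), -1).T
    Y = X @ model.coef.T + model.intercept
    pixels = Y.T.reshape(len(model.output_markers), h, w)
    return MultichannelImage(pixels, tuple(model.output_markers), img.normalized)


def validation_risks(
    model: FittedPredictor, val: Sequence[MultichannelImage]
) -> dict[str, float]:
    """Per-marker mean absolute per-pixel error over the validation images.

    This is the exact ``ξ`` used for marker-graph edge loadings (it calls
    the graph module's dissimilarity), so updated loadings and reported
    risks can never drift apart.
    """
    if not val:
        raise ValueError("validation set is empty")
    preds = [predict(model, img) for img in val]
    risks: dict[str, float] = {}
    for m in model.output_markers:
        truth = [img.channel(m) for img in val]
        guess = [p.channel(m) for p in preds]
        risks[m] = dissimilarity(guess, truth)
    return risks


def inherit_weights(model: FittedPredictor, newly_observed: str) -> FittedPredictor:
    """Carry a model's weights into the next round's architecture.

    Spatial backends reuse trained weights when a marker moves from the
    output side to the input side (fresh random init for the new input
    channel, the moved marker's output weights dropped). The linear backend
    refits exactly in closed form each round, so inheritance is a no-op:
    the model is returned unchanged with a warning.
    """
    if newly_observed not in model.output_markers:
        raise ValueError(f"{newly_observed!r} is not an output of this model")
    warnings.warn(
        "inherit_weights is a no-op for the linear backend (it refits exactly)",
        UserWarning,
        stacklevel=2,
    )
    return model


def make_factory(spec: PredictorSpec):
    """A predictor factory for the selection loop: ``(dataset, observed, seed) -> model``."""

    def factory(
        dataset: MultichannelDataset, observed: Sequence[str], seed: int
    ) -> FittedPredictor:
        round_spec = PredictorSpec(
            backend=spec.backend,
            lam=spec.lam,
            patch_size=spec.patch_size,
            learning_rate=spec.learning_rate,
            max_epochs=spec.max_epochs,
            patience=spec.patience,
            seed=seed,
        )
        return fit(round_spec, dataset, observed)

    return factory
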