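"""Neural-network land-use suitability probabilities.

A single-hidden-layer network (logistic hidden units, cross-entropy
loss) is trained on sampled (driver-vector, observed-class) pairs and
then evaluated at every cell, giving a per-cell, per-class suitability
probability field.  Raw network outputs are renormalized per cell so
the six probabilities sum to exactly 1, the constraint the CA engine
relies on.  Drivers are min–max rescaled to [0, 1] before training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .exceptions import ArgumentError, TrainingError
from .grids import CLASSES, N_CLASSES, DriverStack, LandUseMap


@dataclass
class TrainingSet:
    """Sampled (driver vector, class label) pairs for suitability training."""

    X: np.ndarray  # (n, n_drivers), normalized drivers
    y: np.ndarray  # (n,), class codes 1..6
    driver_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ArgumentError("X and y must have the same number of samples")
        if self.X.shape[1] != len(self.driver_names):
            raise ArgumentError("X columns must match driver names")


@dataclass
class AnnModel:
    """Trained suitability network plus its driver manifest."""

    mlp: MLPClassifier
    driver_names: list[str]
    hidden_size: int
    training_meta: dict = field(default_factory=dict)

    @property
    def hidden_weights(self) -> np.ndarray:
        return self.mlp.coefs_[0]

    @property
    def output_weights(self) -> np.ndarray:
        return self.mlp.coefs_[1]


@dataclass
class SuitabilityCube:
    """Per-cell, per-class suitability probabilities, shape (6, rows, cols).

    Probabilities at each active cell sum to 1; nodata cells are all-NaN.
    """

    probs: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape[0] != N_CLASSES:
            raise ArgumentError("suitability cube needs 6 class planes")
        sums = self.probs[:, self.active].sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ArgumentError("active-cell probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]


def sample_training(
    lum: LandUseMap,
    drivers: DriverStack,
    n: int,
    strategy: str = "uniform",
    seed: int = 0,
) -> TrainingSet:
    """Sample ``n`` training cells without replacement.

    ``uniform`` draws (near-)equal counts per present class, falling back
    to proportional sampling with a warning if some class has no cells;
    ``random`` draws uniformly from all active cells.
    """
    if lum.shape != drivers.shape:
        raise ArgumentError("map and drivers must share a shape")
    active_idx = np.flatnonzero(lum.active & ~drivers.nodata_mask)
    if n > active_idx.size:
        raise ArgumentError(f"n={n} exceeds the {active_idx.size} active cells")
    rng = np.random.default_rng(seed)
    labels_all = lum.classes.ravel()[active_idx]

    if strategy == "random":
        pick = rng.choice(active_idx, size=n, replace=False)
    elif strategy == "uniform":
        present = [c for c in CLASSES if (labels_all == c).any()]
        if len(present) < N_CLASSES:
            warnings.warn(
                "some classes have no cells; falling back to proportional sampling",
                stacklevel=2,
            )
            pick = rng.choice(active_idx, size=n, replace=False)
        else:
            quota = n // len(present)
            chosen: list[np.ndarray] = []
            spare_pool: list[np.ndarray] = []
            for c in present:
                cells = active_idx[labels_all == c]
                take = min(quota, cells.size)
                sel = rng.choice(cells, size=take, replace=False)
                chosen.append(sel)
                rest = np.setdiff1d(cells, sel, assume_unique=True)
                spare_pool.append(rest)
            picked = np.concatenate(chosen)
            shortfall = n - picked.size
            if shortfall > 0:
                pool = np.concatenate(spare_pool)
                picked = np.concatenate(
                    [picked, rng.choice(pool, size=shortfall, replace=False)]
                )
            pick = picked
    else:
        raise ArgumentError(f"unknown sampling strategy {strategy!r}")

    mask = np.zeros(lum.classes.size, dtype=bool)
    mask[pick] = True
    mask2d = mask.reshape(lum.shape)
    X_all = drivers.design_matrix(mask2d)
    y = lum.classes[mask2d]
    # design_matrix/boolean indexing give row-major order for both X and y
    return TrainingSet(X_all, y.astype(np.int16), drivers.names)


def train_ann(
    ts: TrainingSet,
    hidden_size: int = 12,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
) -> AnnModel:
    """Fit the single-hidden-layer suitability network.

    Logistic hidden activations, softmax output, cross-entropy loss;
    fully deterministic for a given seed.
    """
    if epochs < 1:
        raise ArgumentError("epochs must be ≥ 1")
    mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_size,),
        activation="logistic",
        solver="adam",
        learning_rate_init=lr,
        max_iter=epochs,
        random_state=seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(ts.X, ts.y)
    if not np.isfinite(mlp.loss_):
        raise TrainingError(
            f"training diverged: loss={mlp.loss_!r}, lr={lr}, epochs={epochs}"
        )
    meta = {"n_samples": int(ts.X.shape[0]), "epochs": epochs, "lr": lr, "seed": seed}
    return AnnModel(mlp, list(ts.driver_names), hidden_size, meta)


def predict_suitability(model: AnnModel, drivers: DriverStack) -> SuitabilityCube:
    """Evaluate the network at every active cell and renormalize per cell."""
    if list(model.driver_names) != list(drivers.names):
        raise ArgumentError(
            f"driver layers {drivers.names} do not match the training manifest "
            f"{model.driver_names}"
        )
    active = ~drivers.nodata_mask
    X = drivers.design_matrix(active)
    raw = model.mlp.predict_proba(X)  # (n, n_trained_classes)
    rows, cols = drivers.shape
    cube = np.full((N_CLASSES, rows, cols), np.nan)
    full = np.zeros((X.shape[0], N_CLASSES))
    for j, c in enumerate(model.mlp.classes_):
        full[:, int(c) - 1] = raw[:, j]
    full /= full.sum(axis=1, keepdims=True)
    cube[:, active] = full.T
    return SuitabilityCube(cube, active)


def roc_auc_per_class(
    cube: SuitabilityCube, observed: LandUseMap
) -> dict[int, float | None]:
    """One-vs-rest ROC AUC of each class plane against the observed map.

    Classes absent from the observed map (or universal, leaving no
    negatives) are reported as ``None``.
    """
    if cube.shape != observed.shape:
        raise ArgumentError("cube and observed map must share a shape")
    act = observed.active & cube.active
    labels = observed.classes[act]
    out: dict[int, float | None] = {}
    for c in CLASSES:
        pos = labels == c
        if pos.sum() in (0, labels.size):
            out[c] = None
            continue
        scores = cube.probs[c - 1][act]
        out[c] = float(roc_auc_score(pos, scores))
    return out


def mean_auc(aucs: dict[int, float | None]) -> float:
    vals = [v for v in aucs.values() if v is not None]
    if not vals:
        raise ArgumentError("no class had a defined AUC")
    return float(np.mean(vals))
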