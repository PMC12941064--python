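"""Neural surrogate for diffuse reflectance: preprocessing, training, evaluation.

The surrogate regresses a single diffuse reflectance value from the flattened
per-layer physical parameters (mu_a, mu_s, g, n, d) at one wavelength
(input dimension 5 x layer count; wavelength itself is not an input — all
wavelength dependence enters through the physical parameters).

Protocol highlights, mirrored from standard practice for simulator
surrogates:

* spectrum-level 70/10/20 train/validation/test splits (all wavelengths of
  one parameter set stay in the same split, preventing leakage),
* decadic log transform of mu_a, mu_s and d followed by z-scoring, with
  statistics frozen on the training split only; reflectance targets are left
  untouched (naturally bounded in [0, 1]),
* MSE loss, AdamW with lr 1e-4 and weight decay 1e-3, halve-on-plateau
  scheduling to a floor of 1e-8, 32-bit precision, no dropout or batch norm,
* the final-epoch checkpoint is returned (not the best-validation one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import MLP, AdamW, PlateauScheduler, parameter_count

__all__ = [
    "SurrogateSpec",
    "TrainingConfig",
    "NormalizationStats",
    "SurrogateModel",
    "FidelityReport",
    "split_dataset",
    "kfold_splits",
    "fit_normalization",
    "preprocess",
    "inverse_preprocess",
    "train_surrogate",
    "predict_reflectance",
    "evaluate_fidelity",
    "default_log_flags",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture of the surrogate MLP.

    Defaults reproduce the reference architecture: five hidden layers of 512
    units, leaky-ReLU slope 0.2, logistic scalar output, Kaiming-normal
    weights and zero biases (~1.05 M trainable parameters at 15 inputs).
    """

    input_dim: int
    hidden_units: int = 512
    hidden_layers: int = 5
    leaky_slope: float = 0.2

    @property
    def n_parameters(self) -> int:
        """Closed-form trainable parameter count."""
        return parameter_count(self.input_dim, self.hidden_units, self.hidden_layers)

    def build(self, rng: np.random.Generator) -> MLP:
        return MLP(self.input_dim, self.hidden_units, self.hidden_layers,
                   self.leaky_slope, rng=rng)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol of the surrogate.

    ``patience`` and ``max_epochs`` default to the dataset-size rule: patience
    20 epochs for >= 1e5 training rows, 50 otherwise; max_epochs =
    25 x patience with a floor of 500.  The seed is mandatory.
    """

    seed: int
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    batch_size: int = 4096
    patience: int | None = None
    max_epochs: int | None = None
    min_lr: float = 1e-8
    lr_factor: float = 0.5

    def resolved(self, n_train_rows: int) -> tuple[int, int]:
        patience = self.patience
        if patience is None:
            patience = 20 if n_train_rows >= 100_000 else 50
        max_epochs = self.max_epochs
        if max_epochs is None:
            max_epochs = max(25 * patience, 500)
        return patience, max_epochs


def default_log_flags(input_dim: int) -> np.ndarray:
    """log10 flags for flattened (mu_a, mu_s, g, n, d) blocks: mu_a, mu_s, d."""
    if input_dim % 5 != 0:
        raise ValueError("input_dim must be a multiple of 5 (per-layer blocks)")
    flags = np.zeros(input_dim, dtype=bool)
    for layer in range(input_dim // 5):
        flags[layer * 5 + 0] = True  # mu_a
        flags[layer * 5 + 1] = True  # mu_s
        flags[layer * 5 + 4] = True  # d
    return flags


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature decadic-log flags and z-score statistics (train split only)."""

    log10_transform: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "log10_transform", np.asarray(self.log10_transform, bool))
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "std", np.asarray(self.std, float))
        if np.any(self.std <= 0):
            bad = np.flatnonzero(self.std <= 0)
            raise ValueError(f"zero-variance feature(s) at index {bad.tolist()}")


def fit_normalization(train_params: np.ndarray,
                      log10_transform: np.ndarray | None = None,
                      *, allow_constant: bool = False) -> NormalizationStats:
    """Fit log10 + z-score statistics on the training split.

    Raises (naming the feature) for zero-variance features; reflectance
    targets are never transformed.  With ``allow_constant`` a constant
    feature (e.g. the fixed semi-infinite bottom-layer thickness) is mapped
    to zero instead of raising, by assigning it unit scale.
    """
    x = np.asarray(train_params, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("train_params must be a nonempty 2-D array")
    flags = default_log_flags(x.shape[1]) if log10_transform is None \
        else np.asarray(log10_transform, bool)
    t = x.copy()
    if np.any(t[:, flags] <= 0):
        raise ValueError("nonpositive value under a log10-transformed feature")
    t[:, flags] = np.log10(t[:, flags])
    mean = t.mean(axis=0)
    std = t.std(axis=0)
    if np.any(std <= 0):
        bad = np.flatnonzero(std <= 0)
        if not allow_constant:
            raise ValueError(
                f"feature(s) {bad.tolist()} have zero variance on the training split")
        std[bad] = 1.0
    return NormalizationStats(log10_transform=flags, mean=mean, std=std)


def preprocess(params: np.ndarray, norm: NormalizationStats) -> np.ndarray:
    """(log10 where flagged - mean) / std, elementwise; pure and invertible."""
    x = np.atleast_2d(np.asarray(params, dtype=float))
    if x.shape[1] != norm.mean.size:
        raise ValueError(f"expected {norm.mean.size} features, got {x.shape[1]}")
    t = x.copy()
    flags = norm.log10_transform
    if np.any(t[:, flags] <= 0):
        raise ValueError("nonpositive value under a log10-transformed feature")
    t[:, flags] = np.log10(t[:, flags])
    return (t - norm.mean) / norm.std


def inverse_preprocess(features: np.ndarray, norm: NormalizationStats) -> np.ndarray:
    """Exact inverse of :func:`preprocess` given the same statistics."""
    z = np.atleast_2d(np.asarray(features, dtype=float))
    t = z * norm.std + norm.mean
    x = t.copy()
    flags = norm.log10_transform
    x[:, flags] = 10.0 ** t[:, flags]
    return x


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_dataset(spectrum_ids: np.ndarray,
                  fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
                  seed: int = 0):
    """Spectrum-level train/validation/test partition of long-form rows.

    ``spectrum_ids`` groups the rows (wavelengths) of one parameter set; all
    rows of a spectrum land in the same split.  Returns three row-index
    arrays forming a disjoint cover.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ids = np.asarray(spectrum_ids)
    unique = np.unique(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n = unique.size
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0 or n_train == 0:
        raise ValueError(f"degenerate split for {n} spectra with fractions {fractions}")
    groups = (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])
    out = []
    for g in groups:
        mask = np.isin(ids, g)
        out.append(np.flatnonzero(mask))
    return tuple(out)


def kfold_splits(train_spectrum_ids: np.ndarray, n_folds: int, seed: int):
    """Fold partition of the training pool only (validation/test stay global).

    Yields per-fold row-index arrays over the training pool; the k-fold
    protocol keeps one global validation and test set fixed across folds and
    rotates only which part of the training pool is used.
    """
    ids = np.asarray(train_spectrum_ids)
    unique = np.unique(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    folds = np.array_split(perm, n_folds)
    for held_out in folds:
        mask = ~np.isin(ids, held_out)
        yield np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# model, training, evaluation
# ---------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    """Trained surrogate: architecture, weights, frozen normalization, metadata."""

    spec: SurrogateSpec
    norm: NormalizationStats
    state: dict
    training_meta: dict = field(default_factory=dict)

    def predict(self, params: np.ndarray) -> np.ndarray:
        return predict_reflectance(self, params)

    def save(self, path) -> None:
        """Write a portable HDF5 checkpoint (loadable without training data)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["input_dim"] = self.spec.input_dim
            f.attrs["hidden_units"] = self.spec.hidden_units
            f.attrs["hidden_layers"] = self.spec.hidden_layers
            f.attrs["leaky_slope"] = self.spec.leaky_slope
            g = f.create_group("weights")
            for k, v in self.state.items():
                g.create_dataset(k, data=v)
            n = f.create_group("normalization")
            n.create_dataset("log10_transform", data=self.norm.log10_transform)
            n.create_dataset("mean", data=self.norm.mean)
            n.create_dataset("std", data=self.norm.std)
            m = f.create_group("training_meta")
            for k, v in self.training_meta.items():
                m.attrs[k] = v

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        import h5py

        with h5py.File(path, "r") as f:
            spec = SurrogateSpec(
                input_dim=int(f.attrs["input_dim"]),
                hidden_units=int(f.attrs["hidden_units"]),
                hidden_layers=int(f.attrs["hidden_layers"]),
                leaky_slope=float(f.attrs["leaky_slope"]),
            )
            state = {k: np.asarray(v) for k, v in f["weights"].items()}
            norm = NormalizationStats(
                log10_transform=np.asarray(f["normalization/log10_transform"]),
                mean=np.asarray(f["normalization/mean"]),
                std=np.asarray(f["normalization/std"]),
            )
            meta = dict(f["training_meta"].attrs)
        return cls(spec=spec, norm=norm, state=state, training_meta=meta)


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite validation loss)."""


def train_surrogate(
    train_params: np.ndarray,
    train_targets: np.ndarray,
    val_params: np.ndarray,
    val_targets: np.ndarray,
    spec: SurrogateSpec,
    config: TrainingConfig,
    norm: NormalizationStats | None = None,
) -> SurrogateModel:
    """Train the surrogate with the plateau-scheduled AdamW protocol.

    Normalization statistics are fitted on the training split only (or passed
    in pre-fitted).  Returns the final-epoch checkpoint with training
    metadata (seed, epochs run, final validation loss).
    """
    train_params = np.asarray(train_params, float)
    train_targets = np.asarray(train_targets, float)
    if norm is None:
        norm = fit_normalization(train_params, allow_constant=True)
    x_train = preprocess(train_params, norm).astype(np.float32)
    y_train = train_targets.astype(np.float32)
    x_val = preprocess(np.asarray(val_params, float), norm).astype(np.float32)
    y_val = np.asarray(val_targets, np.float32)

    rng = np.random.default_rng(config.seed)
    net = spec.build(rng)
    opt = AdamW(net.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    patience, max_epochs = config.resolved(x_train.shape[0])
    sched = PlateauScheduler(opt, patience=patience, factor=config.lr_factor,
                             min_lr=config.min_lr)

    n = x_train.shape[0]
    batch = min(config.batch_size, n)
    val_loss = np.inf
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            net.forward(x_train[idx], cache=True)
            _, grads = net.backward(x_train[idx], y_train[idx])
            opt.step(grads)
        val_pred = net.forward(x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        if not np.isfinite(val_loss):
            raise TrainingError(
                f"validation loss diverged at epoch {epoch} (lr={opt.lr:.3g})"
            )
        sched.step(val_loss)

    return SurrogateModel(
        spec=spec,
        norm=norm,
        state=net.get_state(),
        training_meta={
            "seed": int(config.seed),
            "epochs_run": int(max_epochs),
            "final_val_loss": val_loss,
            "final_lr": opt.lr,
        },
    )


def _rebuild(model: SurrogateModel) -> MLP:
    net = model.spec.build(np.random.default_rng(0))
    net.set_state(model.state)
    return net


def predict_reflectance(model: SurrogateModel, params: np.ndarray,
                        batch_size: int = 65536) -> np.ndarray:
    """Predict reflectance for physical parameter vectors; output in (0, 1)."""
    x = preprocess(params, model.norm).astype(np.float32)
    net = _rebuild(model)
    out = np.empty(x.shape[0], dtype=np.float64)
    for start in range(0, x.shape[0], batch_size):
        out[start:start + batch_size] = net.forward(x[start:start + batch_size])
    return out


@dataclass(frozen=True)
class FidelityReport:
    """Goodness of fit of surrogate predictions against reference reflectances."""

    mae: float
    mape_percent: float
    ape_percent: np.ndarray
    n_mape_excluded: int

    def summary(self) -> str:
        q = np.percentile(self.ape_percent, [50, 95]) if self.ape_percent.size else (np.nan,) * 2
        return (
            f"MAE = {self.mae:.3e}\n"
            f"MAPE = {self.mape_percent:.4f} % ({self.n_mape_excluded} zero targets excluded)\n"
            f"APE median / 95th pct = {q[0]:.4f} % / {q[1]:.4f} %"
        )


def evaluate_fidelity(model: SurrogateModel, test_params: np.ndarray,
                      test_targets: np.ndarray,
                      reference_targets: np.ndarray | None = None) -> FidelityReport:
    """MAE / MAPE / per-sample APE of the surrogate on a test set.

    With ``reference_targets`` (e.g. matched simulations at ten times more
    photons) errors are computed against the low-noise reference instead of
    the training-fidelity targets.
    """
    targets = np.asarray(test_targets if reference_targets is None else reference_targets,
                         dtype=float)
    if targets.size == 0:
        raise ValueError("empty test set")
    pred = predict_reflectance(model, test_params)
    abs_err = np.abs(pred - targets)
    mae = float(np.mean(abs_err))
    pos = targets > 0
    ape = abs_err[pos] / targets[pos] * 100.0
    mape = float(np.mean(ape)) if ape.size else float("nan")
    return FidelityReport(
        mae=mae,
        mape_percent=mape,
        ape_percent=ape,
        n_mape_excluded=int(np.count_nonzero(~pos)),
    )
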