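"""Neural data-scaling experiment and power-law fitting.

Test error of the surrogate as a function of training-data volume is modeled
as ``error(N) = a * N**b + c`` — a power-law decay with scale ``a``,
exponent ``b`` and irreducible error ``c`` (the floor that more data cannot
beat, set by the Monte Carlo noise of the training targets).

The experiment uses nested subsampling: the subset at a smaller fraction is
contained in every larger one under the same seed, and samples are only ever
added to the training split while the global validation and test splits stay
fixed.  The fit is least squares of ``log10(a N^b + c)`` against
``log10(observed MAE)`` with SciPy's trust-region-reflective solver and
parameter bounds [0, -5, 0] to [inf, 5, 1e-2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .surrogate import (
    SurrogateSpec,
    TrainingConfig,
    evaluate_fidelity,
    kfold_splits,
    train_surrogate,
)

__all__ = [
    "ScalingLawFit",
    "subsample_training",
    "run_scaling_experiment",
    "fit_power_law",
    "DEFAULT_FRACTIONS",
]

#: Subsampling fractions of the full training pool used by the reference
#: protocol; scaled-down runs restrict to the fractions that still yield a
#: usable number of spectra.
DEFAULT_FRACTIONS = (0.001, 0.0025, 0.005, 0.01, 0.025, 0.10, 0.25, 0.50, 1.00)

POWER_LAW_BOUNDS = (np.array([0.0, -5.0, 0.0]), np.array([np.inf, 5.0, 1e-2]))


def subsample_training(train_spectrum_ids: np.ndarray, fraction: float, seed: int):
    """Row indices of a nested, spectrum-level training subset.

    The subset at fraction f1 < f2 is a strict subset of the one at f2 under
    the same seed (one global permutation, prefix selection).  Subset sizes
    are floored to whole spectra with a minimum of one.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ids = np.asarray(train_spectrum_ids)
    unique = np.unique(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    k = max(1, int(np.floor(fraction * unique.size)))
    chosen = perm[:k]
    return np.flatnonzero(np.isin(ids, chosen))


@dataclass(frozen=True)
class ScalingLawFit:
    """Fitted power law error(N) = a N^b + c with fit standard deviations."""

    a: float
    b: float
    c: float
    std_a: float
    std_b: float
    std_c: float
    sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    errors: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(n, float) ** self.b + self.c

    def summary(self) -> str:
        return (
            "Power-law fit  error(N) = a * N^b + c\n"
            f"  a = {self.a:.4g} +/- {self.std_a:.2g}\n"
            f"  b = {self.b:.4f} +/- {self.std_b:.2g}\n"
            f"  c = {self.c:.4g} +/- {self.std_c:.2g}\n"
            f"  fitted on {self.sizes.size} (N, MAE) points, "
            f"N in [{self.sizes.min():.0f}, {self.sizes.max():.0f}]"
            if self.sizes.size else
            f"Power-law fit a={self.a:.4g} b={self.b:.4f} c={self.c:.4g}"
        )


def fit_power_law(sizes, errors) -> ScalingLawFit:
    """Fit the power law on log-scaled data with trust-region reflective.

    Residuals are ``log10(a N^b + c) - log10(MAE)``, which equalizes relative
    error across decades; parameter standard deviations come from the
    Gauss-Newton covariance at the solution.
    """
    sizes = np.asarray(sizes, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if sizes.shape != errors.shape or sizes.size < 4 or np.unique(sizes).size < 4:
        raise ValueError("need >= 4 distinct sizes with matching errors")
    if np.any(errors <= 0) or np.any(sizes <= 0):
        raise ValueError("sizes and errors must be positive")

    log_err = np.log10(errors)

    def residuals(p):
        a, b, c = p
        model = a * sizes**b + c
        return np.log10(np.maximum(model, 1e-300)) - log_err

    # initial guess: pure power law through the extreme points, no floor
    b0 = (log_err[np.argmax(sizes)] - log_err[np.argmin(sizes)]) / (
        np.log10(sizes.max()) - np.log10(sizes.min())
    )
    b0 = float(np.clip(b0, -4.9, 4.9))
    a0 = float(errors[np.argmin(sizes)] / sizes.min() ** b0)
    c0 = min(float(errors.min()) * 0.1, 9e-3)
    sol = least_squares(residuals, x0=[a0, b0, c0], bounds=POWER_LAW_BOUNDS,
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(
            f"power-law fit did not converge: {sol.message}; residuals {sol.fun}"
        )
    # covariance from the Jacobian at the solution
    dof = max(sizes.size - 3, 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * 2 * sol.cost / dof
        stds = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        stds = np.full(3, np.nan)
    a, b, c = sol.x
    return ScalingLawFit(a=float(a), b=float(b), c=float(c),
                         std_a=float(stds[0]), std_b=float(stds[1]), std_c=float(stds[2]),
                         sizes=sizes.copy(), errors=errors.copy())


def run_scaling_experiment(
    params: np.ndarray,
    targets: np.ndarray,
    spectrum_ids: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    fractions,
    spec: SurrogateSpec,
    config: TrainingConfig,
    n_folds: int = 1,
    subsample_seed: int = 0,
    steps_budget: int | None = None,
):
    """Retrain the surrogate on nested training subsets and record test MAE.

    Returns ``(sizes, errors, records)`` where sizes/errors are flat arrays
    over (fraction, fold) runs — Ndata counts training rows (spectra x
    wavelengths) — and ``records`` is a list of dicts for reporting.  The
    global validation and test splits are identical for every run.
    """
    params = np.asarray(params, float)
    targets = np.asarray(targets, float)
    ids = np.asarray(spectrum_ids)
    sizes, errors, records = [], [], []
    for fraction in sorted(fractions):
        sub_rel = subsample_training(ids[train_idx], fraction, subsample_seed)
        pool_idx = train_idx[sub_rel]
        if n_folds > 1:
            fold_row_sets = list(kfold_splits(ids[pool_idx], n_folds, config.seed))
        else:
            fold_row_sets = [np.arange(pool_idx.size)]
        for fold, rel in enumerate(fold_row_sets):
            rows = pool_idx[rel]
            max_epochs = config.max_epochs
            if steps_budget is not None and max_epochs is not None:
                # constant optimizer-step budget across sizes: small subsets
                # need many epochs to converge, large ones few
                batches = max(1, rows.size // config.batch_size)
                max_epochs = min(max_epochs, max(600, steps_budget // batches))
            cfg = TrainingConfig(
                seed=config.seed + 1000 * fold,
                learning_rate=config.learning_rate,
                weight_decay=config.weight_decay,
                batch_size=config.batch_size,
                patience=config.patience,
                max_epochs=max_epochs,
                min_lr=config.min_lr,
            )
            try:
                model = train_surrogate(
                    params[rows], targets[rows],
                    params[val_idx], targets[val_idx],
                    spec, cfg,
                )
            except Exception as exc:  # pragma: no cover - recorded, not fatal
                records.append({"fraction": fraction, "fold": fold,
                                "n_rows": int(rows.size), "error": str(exc)})
                continue
            report = evaluate_fidelity(model, params[test_idx], targets[test_idx])
            sizes.append(rows.size)
            errors.append(report.mae)
            records.append({"fraction": fraction, "fold": fold,
                            "n_rows": int(rows.size), "test_mae": report.mae})
    return np.asarray(sizes, float), np.asarray(errors, float), records
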