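"""Inference-timing harness: surrogate versus Monte Carlo wall time.

Measures the end-to-end time to generate batches of spectra — the surrogate
timing includes physiological-parameter preprocessing and the network
forward pass, making the comparison fair; the Monte Carlo timing runs the
same batch at one or more photon budgets.  Speedup ratios are descriptive
and machine-relative, never asserted against external hardware numbers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .optics import ChromophoreTable, ParameterSpace, sample_physiological_parameters
from .surrogate import SurrogateModel, predict_reflectance
from .application import _feature_matrix
from .transport import simulate_spectrum

__all__ = ["TimingReport", "benchmark_inference"]


@dataclass
class TimingReport:
    """Wall-time samples (seconds per batch) for each condition."""

    surrogate_times: np.ndarray
    mc_times: dict[int, np.ndarray] = field(default_factory=dict)
    batch_spectra: int = 0
    n_wavelengths: int = 0
    preprocessing_calls: int = 0

    def median_surrogate(self) -> float:
        return float(np.median(self.surrogate_times))

    def median_mc(self, photons: int) -> float:
        return float(np.median(self.mc_times[photons]))

    def speedup(self, photons: int) -> float:
        return self.median_mc(photons) / self.median_surrogate()

    def summary(self) -> str:
        lines = [
            f"batch: {self.batch_spectra} spectra x {self.n_wavelengths} wavelengths, "
            f"{self.surrogate_times.size} repeats",
            f"surrogate median: {self.median_surrogate() * 1e3:.2f} ms "
            f"(IQR {np.percentile(self.surrogate_times, 25) * 1e3:.2f}-"
            f"{np.percentile(self.surrogate_times, 75) * 1e3:.2f} ms)",
        ]
        for p, t in self.mc_times.items():
            lines.append(
                f"MC {p} photons median: {np.median(t):.3f} s  "
                f"(speedup {self.speedup(p):.0f}x)"
            )
        return "\n".join(lines)


def benchmark_inference(
    model: SurrogateModel,
    space: ParameterSpace,
    table: ChromophoreTable,
    *,
    batch_spectra: int = 1000,
    repeats: int = 30,
    mc_photon_budgets: tuple[int, ...] = (),
    mc_batch_spectra: int | None = None,
    seed: int = 0,
) -> TimingReport:
    """Time surrogate and Monte Carlo generation of parameter-set batches.

    Each repeat draws an independent batch of physiological parameter sets;
    surrogate timing covers physiology-to-physics conversion, preprocessing
    and the forward pass.  MC timing (optional; expensive) may use a smaller
    ``mc_batch_spectra`` which is then scaled to the full batch size.
    """
    wavelengths = np.asarray(space.wavelengths_nm, float)
    sur_times = np.empty(repeats)
    pre_calls = 0
    for r in range(repeats):
        columns = sample_physiological_parameters(space, batch_spectra, seed + r)
        t0 = time.perf_counter()
        feats = _feature_matrix(columns, wavelengths, table, space.semi_infinite_bottom)
        predict_reflectance(model, feats)
        sur_times[r] = time.perf_counter() - t0
        pre_calls += 1

    mc_times: dict[int, np.ndarray] = {}
    mc_n = mc_batch_spectra if mc_batch_spectra is not None else batch_spectra
    for photons in mc_photon_budgets:
        times = np.empty(repeats)
        for r in range(repeats):
            columns = sample_physiological_parameters(space, mc_n, 10_000 + seed + r)
            t0 = time.perf_counter()
            for i, col in enumerate(columns):
                simulate_spectrum(col, wavelengths, table, photons, seed + 31 * i)
            times[r] = (time.perf_counter() - t0) * (batch_spectra / mc_n)
        mc_times[photons] = times

    return TimingReport(
        surrogate_times=sur_times,
        mc_times=mc_times,
        batch_spectra=batch_spectra,
        n_wavelengths=wavelengths.size,
        preprocessing_calls=pre_calls,
    )
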