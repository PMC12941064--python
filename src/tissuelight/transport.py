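"""Multilayer Monte Carlo diffuse-reflectance simulation.

Physics: pencil-beam normal incidence on a stack of infinitely wide
homogeneous layers; weighted (implicit-capture) photon random walk with step
``s = -ln(xi) / mu_t``, per-interaction absorption deposit ``W mu_a / mu_t``,
Henyey-Greenstein deflection, unpolarized-Fresnel boundary events, and
Russian roulette below a weight threshold.  The specular fraction
``((n0 - n1) / (n0 + n1))^2`` is removed at entry and reported separately;
``r_hat`` is the summed weight escaping the top surface divided by the number
of launched photons.

Reproducibility: photons are processed in fixed chunks of 2**16, each chunk
driven by an independent SeedSequence-spawned substream, so results are
deterministic for a given (column, n_photons, seed) and independent of how
chunks are scheduled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .optics import ChromophoreTable, PhysiologicalLayerParams, TissueColumn, physical_properties

__all__ = [
    "SimulationResult",
    "fresnel_reflectance",
    "sample_hg_cosine",
    "simulate_reflectance",
    "simulate_spectrum",
    "DEFAULT_ROULETTE_THRESHOLD",
    "DEFAULT_ROULETTE_M",
]

DEFAULT_ROULETTE_THRESHOLD = 1e-4
DEFAULT_ROULETTE_M = 10
_CHUNK = 1 << 16  # fixed chunk size; part of the deterministic stream layout


@dataclass(frozen=True)
class SimulationResult:
    """Diffuse-reflectance estimate with full photon weight bookkeeping."""

    r_hat: float
    r_specular: float
    n_total: int
    transmitted_weight: float
    absorbed_weight: float
    seed: int

    @property
    def n_returned_effective(self) -> float:
        """Effective returned-photon count r_hat * n_total."""
        return self.r_hat * self.n_total

    @property
    def energy_closure(self) -> float:
        """r_specular + r_hat + transmitted + absorbed (1 up to roulette noise)."""
        return self.r_specular + self.r_hat + self.transmitted_weight + self.absorbed_weight


def fresnel_reflectance(n1, n2, cos_theta_i):
    """Unpolarized Fresnel reflectance (vectorized NumPy reference).

    Total internal reflection beyond the critical angle returns exactly 1.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ci = np.clip(np.asarray(cos_theta_i, dtype=float), 0.0, 1.0)
    sin_i = np.sqrt(np.clip(1.0 - ci**2, 0.0, 1.0))
    sin_t = n1 * sin_i / n2
    tir = sin_t >= 1.0
    sin_t = np.where(tir, 0.0, sin_t)
    ct = np.sqrt(np.clip(1.0 - sin_t**2, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
        rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
        r = 0.5 * (rs**2 + rp**2)
    r = np.where(tir | (ci < 1e-12), 1.0, r)
    r = np.where(n1 == n2, 0.0, r)
    return r if r.ndim else float(r)


def sample_hg_cosine(g, u):
    """Henyey-Greenstein deflection cosine via the analytic inverse CDF.

    For g = 0 the distribution is uniform on [-1, 1].  Vectorized.
    """
    g = np.asarray(g, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(np.abs(g) >= 1):
        raise ValueError("|g| must be < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        tmp = (1.0 - g**2) / (1.0 - g + 2.0 * g * u)
        c = np.where(g == 0.0, 2.0 * u - 1.0, (1.0 + g**2 - tmp**2) / np.where(g == 0.0, 1.0, 2.0 * g))
    c = np.clip(c, -1.0, 1.0)
    return c if c.ndim else float(c)


def _column_arrays(column: TissueColumn):
    mu_a, mu_s, g, n, d = column.as_arrays()
    if not np.all(np.isfinite(mu_a)) or not np.all(np.isfinite(mu_s)):
        raise ValueError("non-finite optical properties")
    boundaries = np.concatenate([[0.0], np.cumsum(d)])
    return (
        np.ascontiguousarray(mu_a),
        np.ascontiguousarray(mu_s),
        np.ascontiguousarray(g),
        np.ascontiguousarray(n),
        np.ascontiguousarray(boundaries),
    )


def simulate_reflectance(
    column: TissueColumn,
    n_photons: int,
    seed: int,
    roulette_threshold: float = DEFAULT_ROULETTE_THRESHOLD,
    roulette_m: int = DEFAULT_ROULETTE_M,
) -> SimulationResult:
    """Estimate total diffuse reflectance of a layered tissue column.

    Launches ``n_photons`` pencil-beam photons at normal incidence and returns
    the diffuse reflectance MLE together with specular / transmitted /
    absorbed weight fractions.  Fully reproducible under a fixed seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mu_a, mu_s, g, n, boundaries = _column_arrays(column)
    r_spec = fresnel_reflectance(column.ambient_n, float(n[0]), 1.0)

    n_chunks = (n_photons + _CHUNK - 1) // _CHUNK
    chunk_seeds = np.random.SeedSequence(seed).generate_state(n_chunks, dtype=np.uint32)
    refl = trans = absorbed = 0.0
    remaining = n_photons
    for c in range(n_chunks):
        batch = min(_CHUNK, remaining)
        remaining -= batch
        r, t, a = _kernels.transport_chunk(
            batch, mu_a, mu_s, g, n, boundaries,
            float(column.ambient_n), float(column.ambient_n_below),
            float(roulette_threshold), int(roulette_m), int(chunk_seeds[c]),
        )
        refl += r
        trans += t
        absorbed += a

    return SimulationResult(
        r_hat=refl / n_photons,
        r_specular=float(r_spec),
        n_total=n_photons,
        transmitted_weight=trans / n_photons,
        absorbed_weight=absorbed / n_photons,
        seed=int(seed),
    )


def simulate_spectrum(
    phys: Sequence[PhysiologicalLayerParams],
    wavelengths_nm: Sequence[float],
    table: ChromophoreTable,
    n_photons: int,
    seed: int,
    *,
    semi_infinite_bottom: bool = True,
    roulette_threshold: float = DEFAULT_ROULETTE_THRESHOLD,
    roulette_m: int = DEFAULT_ROULETTE_M,
):
    """Simulate the diffuse-reflectance spectrum of one physiological column.

    One independent :func:`simulate_reflectance` per wavelength, with
    independent substreams spawned from ``seed``.  Returns
    ``(values, results)`` where ``values`` is the spectrum array and
    ``results`` the per-wavelength :class:`SimulationResult` list.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    sub = np.random.SeedSequence(seed).generate_state(wavelengths_nm.size, dtype=np.uint32)
    results = []
    values = np.empty(wavelengths_nm.size)
    for i, lam in enumerate(wavelengths_nm):
        column = physical_properties(phys, float(lam), table,
                                     semi_infinite_bottom=semi_infinite_bottom)
        res = simulate_reflectance(column, n_photons, int(sub[i]),
                                   roulette_threshold, roulette_m)
        results.append(res)
        values[i] = res.r_hat
    return values, results
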