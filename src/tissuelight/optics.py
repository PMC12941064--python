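"""Physiological tissue parameterization and optical-property synthesis.

This module maps physiology (blood volume fraction, hemoglobin oxygenation,
Mie-type scattering parameters) to the per-layer, per-wavelength physical
optical properties (mu_a, mu_s, g, n, d) consumed by the Monte Carlo
transport engine and the neural surrogate, and provides Latin-hypercube
sampling of physiological parameter spaces.

Absorption follows the standard tissue-optics convention with hemoglobin as
the sole chromophore::

    mu_a(lambda) = vhb * ln(10) * (c_hb / M_hb)
                   * [stO2 * eps_HbO2(lambda) + (1 - stO2) * eps_Hb(lambda)]

with whole-blood hemoglobin concentration ``c_hb`` = 150 g/L and molar mass
``M_hb`` = 64,500 g/mol.  Reduced scattering follows a Mie-type power law
``mu_s'(lambda) = a_mie * (lambda / 500 nm) ** (-b_mie)`` and
``mu_s = mu_s' / (1 - g)``.

The bundled extinction table (``data/hemoglobin_extinction_synthetic.csv``)
is a synthetic stand-in: a smooth spectral model anchored at widely known
textbook extinction values (Q-bands, 660/760/800/940 nm anchors, the ~800 nm
isosbestic region).  It reproduces the qualitative shape and magnitude of
oxy-/deoxy-hemoglobin spectra and is the single table used consistently
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "PhysiologicalLayerParams",
    "LayerOpticalProperties",
    "TissueColumn",
    "ParameterBound",
    "ParameterSpace",
    "load_default_chromophore_table",
    "hemoglobin_absorption",
    "mie_scattering",
    "physical_properties",
    "sample_physiological_parameters",
    "HB_CONCENTRATION_G_PER_L",
    "HB_MOLAR_MASS_G_PER_MOL",
    "MIE_REFERENCE_NM",
    "SEMI_INFINITE_CM",
]

#: Whole-blood hemoglobin concentration (g/L), the de-facto standard value.
HB_CONCENTRATION_G_PER_L = 150.0
#: Hemoglobin molar mass (g/mol).
HB_MOLAR_MASS_G_PER_MOL = 64_500.0
#: Reference wavelength of the reduced-scattering power law (nm).
MIE_REFERENCE_NM = 500.0
#: Bottom-layer thickness approximating a semi-infinite medium (cm).
SEMI_INFINITE_CM = 20.0


class ConfigurationError(ValueError):
    """Raised for invalid parameter-space or tissue-model configuration."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Molar extinction of oxy-/deoxy-hemoglobin on a strictly increasing grid.

    Units: wavelength nm; extinction L mol^-1 cm^-1.  Interpolation is linear
    and restricted to the tabulated range (no extrapolation).
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        if w.ndim != 1 or w.size < 2 or not np.all(np.diff(w) > 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb"):
            e = np.asarray(getattr(self, name), dtype=float)
            if e.shape != w.shape or not np.all(e > 0):
                raise ConfigurationError(f"{name} must be positive and match the grid")
            object.__setattr__(self, name, e)
        object.__setattr__(self, "wavelength_nm", w)

    @property
    def lambda_min(self) -> float:
        return float(self.wavelength_nm[0])

    @property
    def lambda_max(self) -> float:
        return float(self.wavelength_nm[-1])

    def _check_range(self, lambda_nm: np.ndarray) -> None:
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam < self.lambda_min) or np.any(lam > self.lambda_max):
            raise ValueError(
                f"wavelength outside tabulated range "
                f"[{self.lambda_min}, {self.lambda_max}] nm; no extrapolation"
            )

    def extinction(self, lambda_nm):
        """Linearly interpolated (eps_hbo2, eps_hb) at ``lambda_nm``."""
        self._check_range(lambda_nm)
        lam = np.asarray(lambda_nm, dtype=float)
        return (
            np.interp(lam, self.wavelength_nm, self.eps_hbo2),
            np.interp(lam, self.wavelength_nm, self.eps_hb),
        )

    @classmethod
    def from_csv(cls, path) -> "ChromophoreTable":
        """Read a ``wavelength_nm,eps_hbo2,eps_hb`` CSV."""
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "eps_hbo2", "eps_hb"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"chromophore CSV missing columns: {sorted(missing)}")
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(float),
            eps_hbo2=df["eps_hbo2"].to_numpy(float),
            eps_hb=df["eps_hb"].to_numpy(float),
        )


def load_default_chromophore_table() -> ChromophoreTable:
    """Load the bundled synthetic hemoglobin extinction table (450-1000 nm)."""
    ref = resources.files("tissuelight.data") / "hemoglobin_extinction_synthetic.csv"
    with resources.as_file(ref) as path:
        return ChromophoreTable.from_csv(path)


@dataclass(frozen=True)
class PhysiologicalLayerParams:
    """Physiology of one tissue layer.

    vhb     blood volume fraction in [0, 1]
    sto2    hemoglobin oxygen saturation in [0, 1]
    a_mie   reduced scattering amplitude at 500 nm (cm^-1)
    b_mie   scattering power (dimensionless)
    g       scattering anisotropy, |g| < 1
    n       refractive index (>= 1)
    d       layer thickness (cm, > 0)
    """

    vhb: float
    sto2: float
    a_mie: float
    b_mie: float
    g: float
    n: float
    d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vhb <= 1.0:
            raise ConfigurationError(f"vhb={self.vhb} outside [0, 1]")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ConfigurationError(f"sto2={self.sto2} outside [0, 1]")
        if self.a_mie < 0:
            raise ConfigurationError("a_mie must be >= 0")
        if not abs(self.g) < 1.0:
            raise ConfigurationError("anisotropy g must satisfy |g| < 1")
        if self.n < 1.0:
            raise ConfigurationError("refractive index must be >= 1")
        if not self.d > 0:
            raise ConfigurationError("layer thickness must be > 0")


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Physical optical properties of one layer at one wavelength."""

    mu_a: float  # absorption coefficient, cm^-1
    mu_s: float  # scattering coefficient, cm^-1
    g: float
    n: float
    d: float  # thickness, cm

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s", "g", "n", "d"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite optical property {name}")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be nonnegative")
        if self.d <= 0:
            raise ValueError("layer thickness must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_a, self.mu_s, self.g, self.n, self.d])


@dataclass(frozen=True)
class TissueColumn:
    """Ordered top-to-bottom stack of layers under an ambient medium."""

    layers: tuple[LayerOpticalProperties, ...]
    ambient_n: float = 1.0
    ambient_n_below: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ConfigurationError("a tissue column needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def as_arrays(self):
        """(mu_a, mu_s, g, n, d) arrays of shape (n_layers,)."""
        arr = np.stack([l.as_array() for l in self.layers])
        return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4]

    def feature_vector(self) -> np.ndarray:
        """Flattened per-layer (mu_a, mu_s, g, n, d), the surrogate input."""
        return np.concatenate([l.as_array() for l in self.layers])


# ---------------------------------------------------------------------------
# physiology -> physics
# ---------------------------------------------------------------------------

def hemoglobin_absorption(lambda_nm, vhb, sto2, table: ChromophoreTable):
    """Absorption coefficient mu_a (cm^-1) of hemoglobin-perfused tissue.

    Implements the convex combination of the two hemoglobin species scaled by
    blood volume fraction; vectorized over ``lambda_nm``.
    """
    vhb = np.asarray(vhb, dtype=float)
    sto2 = np.asarray(sto2, dtype=float)
    if np.any(vhb < 0) or np.any(vhb > 1) or np.any(sto2 < 0) or np.any(sto2 > 1):
        raise ValueError("vhb and sto2 must lie in [0, 1]")
    eps_hbo2, eps_hb = table.extinction(lambda_nm)
    molar_blood = HB_CONCENTRATION_G_PER_L / HB_MOLAR_MASS_G_PER_MOL  # mol/L
    mu_a = vhb * math.log(10.0) * molar_blood * (sto2 * eps_hbo2 + (1.0 - sto2) * eps_hb)
    return mu_a if np.ndim(mu_a) else float(mu_a)


def mie_scattering(lambda_nm, a_mie, b_mie, g, lambda_ref_nm: float = MIE_REFERENCE_NM):
    """Scattering coefficient mu_s (cm^-1) from the reduced-scattering power law.

    mu_s'(lambda) = a_mie * (lambda / lambda_ref)^(-b_mie); mu_s = mu_s' / (1 - g).
    """
    a_mie = np.asarray(a_mie, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(a_mie < 0):
        raise ValueError("a_mie must be >= 0")
    if np.any(np.abs(g) >= 1):
        raise ZeroDivisionError("anisotropy |g| must be < 1 (g = 1 divides by zero)")
    lam = np.asarray(lambda_nm, dtype=float)
    mu_s_prime = a_mie * (lam / lambda_ref_nm) ** (-np.asarray(b_mie, dtype=float))
    mu_s = mu_s_prime / (1.0 - g)
    return mu_s if np.ndim(mu_s) else float(mu_s)


def physical_properties(
    phys: Sequence[PhysiologicalLayerParams],
    lambda_nm: float,
    table: ChromophoreTable,
    *,
    semi_infinite_bottom: bool = True,
    ambient_n: float = 1.0,
) -> TissueColumn:
    """Convert a per-layer physiology to a :class:`TissueColumn` at one wavelength.

    With ``semi_infinite_bottom`` the bottom-layer thickness is forced to
    20 cm, approximating a semi-infinite medium.
    """
    if len(phys) == 0:
        raise ConfigurationError("need at least one layer")
    layers = []
    for i, p in enumerate(phys):
        d = p.d
        if semi_infinite_bottom and i == len(phys) - 1:
            d = SEMI_INFINITE_CM
        layers.append(
            LayerOpticalProperties(
                mu_a=hemoglobin_absorption(lambda_nm, p.vhb, p.sto2, table),
                mu_s=mie_scattering(lambda_nm, p.a_mie, p.b_mie, p.g),
                g=p.g,
                n=p.n,
                d=d,
            )
        )
    return TissueColumn(layers=tuple(layers), ambient_n=ambient_n)


# ---------------------------------------------------------------------------
# Latin hypercube sampling of parameter spaces
# ---------------------------------------------------------------------------

_FIELDS = ("vhb", "sto2", "a_mie", "b_mie", "g", "n", "d")


@dataclass(frozen=True)
class ParameterBound:
    """(min, max) bound of one physiological parameter with a sampling scale."""

    low: float
    high: float
    scale: Literal["linear", "log10"] = "linear"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(f"invalid bound: low={self.low} >= high={self.high}")
        if self.scale == "log10" and self.low <= 0:
            raise ConfigurationError("log10 scale requires low > 0")
        if self.scale not in ("linear", "log10"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")

    def transform(self, unit: np.ndarray) -> np.ndarray:
        """Map unit-interval samples onto the bound on its declared scale."""
        if self.scale == "log10":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return 10.0 ** (lo + unit * (hi - lo))
        return self.low + unit * (self.high - self.low)


def _default_layer_bounds() -> dict:
    # Stand-in ranges spanning published tissue-optics values; every bound is
    # a plain config field and may be overridden.
    return {
        "vhb": ParameterBound(0.001, 0.30, "log10"),
        "sto2": ParameterBound(0.0, 1.0),
        "a_mie": ParameterBound(5.0, 50.0),
        "b_mie": ParameterBound(0.3, 3.0),
        "g": ParameterBound(0.80, 0.95),
        "n": ParameterBound(1.33, 1.54),
        "d": ParameterBound(0.002, 0.1, "log10"),
    }


@dataclass(frozen=True)
class ParameterSpace:
    """Per-layer sampling bounds for every physiological parameter.

    ``layer_bounds`` maps each of (vhb, sto2, a_mie, b_mie, g, n, d) to a
    :class:`ParameterBound` per layer.  With ``constant_sto2`` one shared
    oxygenation (a common arterial saO2) is drawn per column and applied to
    all layers, matching the three-layer epithelial model.
    """

    layer_bounds: tuple[dict, ...] = field(default_factory=lambda: tuple(
        _default_layer_bounds() for _ in range(3)
    ))
    wavelengths_nm: tuple[float, ...] = tuple(np.linspace(500.0, 1000.0, 15))
    constant_sto2: bool = True
    semi_infinite_bottom: bool = True

    def __post_init__(self) -> None:
        if len(self.layer_bounds) < 1:
            raise ConfigurationError("need at least one layer")
        for lb in self.layer_bounds:
            missing = set(_FIELDS) - set(lb)
            if missing:
                raise ConfigurationError(f"layer bounds missing fields: {sorted(missing)}")
        object.__setattr__(self, "layer_bounds", tuple(dict(lb) for lb in self.layer_bounds))
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))

    @property
    def n_layers(self) -> int:
        return len(self.layer_bounds)

    def dimensions(self) -> list[tuple[int, str]]:
        """Sampled scalar dimensions as (layer index, field) pairs.

        With ``constant_sto2`` a single shared dimension (-1, "sto2") replaces
        the per-layer oxygenations.
        """
        dims: list[tuple[int, str]] = []
        if self.constant_sto2:
            dims.append((-1, "sto2"))
        for i in range(self.n_layers):
            for f in _FIELDS:
                if f == "sto2" and self.constant_sto2:
                    continue
                dims.append((i, f))
        return dims

    def bound_for(self, layer: int, fieldname: str) -> ParameterBound:
        if layer == -1:  # shared saO2: use the first layer's sto2 bound
            return self.layer_bounds[0]["sto2"]
        return self.layer_bounds[layer][fieldname]


def latin_hypercube_unit(n: int, dims: int, rng: np.random.Generator) -> np.ndarray:
    """n-by-dims Latin hypercube on [0, 1): one sample per equal stratum."""
    u = (rng.random((n, dims)) + np.arange(n)[:, None]) / n
    for j in range(dims):
        u[:, j] = u[rng.permutation(n), j]
    return u


def sample_physiological_parameters(
    space: ParameterSpace, n: int, seed: int
) -> list[tuple[PhysiologicalLayerParams, ...]]:
    """Latin-hypercube sample ``n`` tissue columns from ``space``.

    Every scalar dimension is stratified into ``n`` equal-probability strata on
    its declared (linear or log10) scale, with exactly one sample per stratum.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dims = space.dimensions()
    unit = latin_hypercube_unit(n, len(dims), rng)
    values = np.empty_like(unit)
    for j, (layer, fieldname) in enumerate(dims):
        values[:, j] = space.bound_for(layer, fieldname).transform(unit[:, j])

    columns = []
    for i in range(n):
        row = dict(zip(dims, values[i]))
        shared_sto2 = row.get((-1, "sto2"))
        layers = []
        for li in range(space.n_layers):
            kwargs = {f: row[(li, f)] for f in _FIELDS if (li, f) in row}
            if space.constant_sto2:
                kwargs["sto2"] = shared_sto2
            layers.append(PhysiologicalLayerParams(**kwargs))
        columns.append(tuple(layers))
    return columns


def single_layer_space(
    *,
    vhb: ParameterBound = ParameterBound(0.001, 0.30, "log10"),
    sto2: ParameterBound = ParameterBound(0.0, 1.0),
    a_mie: ParameterBound = ParameterBound(5.0, 50.0),
    b_mie: ParameterBound = ParameterBound(0.3, 3.0),
    g: ParameterBound = ParameterBound(0.80, 0.95),
    n: ParameterBound = ParameterBound(1.33, 1.54),
    d: ParameterBound = ParameterBound(0.002, 0.1, "log10"),
    wavelengths_nm: Sequence[float] = tuple(np.linspace(500.0, 1000.0, 15)),
) -> ParameterSpace:
    """Convenience constructor for a semi-infinite single-layer space."""
    bounds = {"vhb": vhb, "sto2": sto2, "a_mie": a_mie, "b_mie": b_mie,
              "g": g, "n": n, "d": d}
    return ParameterSpace(
        layer_bounds=(bounds,),
        wavelengths_nm=tuple(wavelengths_nm),
        constant_sto2=True,
        semi_infinite_bottom=True,
    )
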