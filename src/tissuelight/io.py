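"""HDF5 dataset containers shared by the simulator and the surrogate.

One schema serves both Monte Carlo outputs and surrogate predictions so the
downstream realism / scaling stages are source-agnostic:

::

    /params        (n_rows, 5 * n_layers)  float64   physical parameters
    /reflectance   (n_rows,)               float64   diffuse reflectance
    /wavelengths   (n_rows,)               float64   wavelength per row (nm)
    /spectrum_ids  (n_rows,)               int64     groups rows of one spectrum
    attrs: model_name, photons, seed, created_utc, checksum

The checksum attribute guards against partially written or corrupted files.
"""

from __future__ import annotations

import datetime
import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetContainer", "write_container", "read_container", "FormatError",
    "write_spectra_set", "read_spectra_set", "write_library", "read_library",
    "write_cube", "read_cube",
]


class FormatError(RuntimeError):
    """Raised for schema mismatches or corrupted containers."""


@dataclass
class DatasetContainer:
    """Long-form parameter/reflectance records with provenance."""

    params: np.ndarray
    reflectance: np.ndarray
    wavelengths: np.ndarray
    spectrum_ids: np.ndarray
    model_name: str = "mc"
    photons: int = 0
    seed: int = 0
    extra_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=np.int64)
        n = self.params.shape[0]
        for name in ("reflectance", "wavelengths", "spectrum_ids"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"/{name} row count inconsistent with /params")

    @property
    def n_rows(self) -> int:
        return self.params.shape[0]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.params, self.reflectance, self.wavelengths, self.spectrum_ids):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


_DATASETS = ("params", "reflectance", "wavelengths", "spectrum_ids")


def write_container(path, data: DatasetContainer) -> None:
    """Write the container with a content checksum; lossless at 64-bit."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("params", data=data.params)
        f.create_dataset("reflectance", data=data.reflectance)
        f.create_dataset("wavelengths", data=data.wavelengths)
        f.create_dataset("spectrum_ids", data=data.spectrum_ids)
        f.attrs["model_name"] = data.model_name
        f.attrs["photons"] = int(data.photons)
        f.attrs["seed"] = int(data.seed)
        f.attrs["created_utc"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        f.attrs["checksum"] = data.checksum()
        for k, v in data.extra_attrs.items():
            f.attrs[k] = v


def read_container(path) -> DatasetContainer:
    """Read and validate a container; checksum failures raise FormatError."""
    import h5py

    with h5py.File(path, "r") as f:
        for name in _DATASETS:
            if name not in f:
                raise FormatError(f"container missing dataset /{name}")
        data = DatasetContainer(
            params=np.asarray(f["params"]),
            reflectance=np.asarray(f["reflectance"]),
            wavelengths=np.asarray(f["wavelengths"]),
            spectrum_ids=np.asarray(f["spectrum_ids"]),
            model_name=str(f.attrs.get("model_name", "")),
            photons=int(f.attrs.get("photons", 0)),
            seed=int(f.attrs.get("seed", 0)),
        )
        stored = str(f.attrs.get("checksum", ""))
    if stored and stored != data.checksum():
        raise FormatError("container checksum mismatch: file is partial or corrupted")
    return data


# ---------------------------------------------------------------------------
# spectra sets, libraries and labeled cubes
# ---------------------------------------------------------------------------

def write_spectra_set(path, spectra_set) -> None:
    """Store a realism SpectraSet (spectra matrix, grid, annotation tables)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=spectra_set.spectra)
        f.create_dataset("wavelengths", data=spectra_set.wavelengths_nm)
        for name in ("subject_id", "class_label", "image_id"):
            v = getattr(spectra_set, name)
            if v is not None:
                f.create_dataset(name, data=np.asarray(v, dtype="S64"))


def read_spectra_set(path):
    import h5py
    from .realism import SpectraSet

    with h5py.File(path, "r") as f:
        if "spectra" not in f or "wavelengths" not in f:
            raise FormatError("spectra-set file missing /spectra or /wavelengths")
        kw = {}
        for name in ("subject_id", "class_label", "image_id"):
            if name in f:
                kw[name] = np.asarray(f[name]).astype(str)
        return SpectraSet(np.asarray(f["spectra"]), np.asarray(f["wavelengths"]), **kw)


def write_library(path, library) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=library.spectra)
        f.create_dataset("sto2", data=library.sto2)
        f.create_dataset("band_centers", data=library.band_centers)
        f.attrs["provenance"] = library.provenance


def read_library(path):
    import h5py
    from .application import SpectrumLibrary

    with h5py.File(path, "r") as f:
        for name in ("spectra", "sto2", "band_centers"):
            if name not in f:
                raise FormatError(f"library file missing /{name}")
        return SpectrumLibrary(np.asarray(f["spectra"]), np.asarray(f["sto2"]),
                               np.asarray(f["band_centers"]),
                               provenance=str(f.attrs.get("provenance", "")))


def write_cube(path, cube) -> None:
    """Store a LabeledHSICube as an HDF5 group (arrays + attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=cube.image)
        f.create_dataset("label_map", data=cube.label_map)
        f.create_dataset("band_centers", data=cube.band_centers)
        f.create_dataset("class_names", data=np.asarray(cube.class_names, dtype="S64"))
        if cube.true_sto2_map is not None:
            f.create_dataset("true_sto2_map", data=cube.true_sto2_map)
        f.attrs["subject_id"] = cube.subject_id
        f.attrs["timepoint"] = cube.timepoint
        f.attrs["phase"] = cube.phase


def read_cube(path):
    import h5py
    from .application import LabeledHSICube

    with h5py.File(path, "r") as f:
        for name in ("image", "label_map", "band_centers", "class_names"):
            if name not in f:
                raise FormatError(f"cube file missing /{name}")
        return LabeledHSICube(
            image=np.asarray(f["image"]),
            label_map=np.asarray(f["label_map"]),
            class_names=tuple(np.asarray(f["class_names"]).astype(str)),
            band_centers=np.asarray(f["band_centers"]),
            subject_id=str(f.attrs["subject_id"]),
            timepoint=float(f.attrs["timepoint"]),
            phase=str(f.attrs["phase"]),
            true_sto2_map=np.asarray(f["true_sto2_map"]) if "true_sto2_map" in f else None,
        )
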