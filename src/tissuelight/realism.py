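"""Realism assessment of simulated spectra against a reference spectra set.

The central metric is spectral recall: the fraction of reference ("real")
spectra that have at least one candidate (simulated or surrogate-generated)
spectrum within a distance threshold ``d_max`` under the per-wavelength
mean absolute error.  Recall treats realism as coverage of the reference
manifold rather than density matching, which suits incomplete in vivo
reference datasets.

Hierarchical aggregation removes subject-specific bias: the binary recall
decision is computed per reference spectrum, averaged per subject and class,
then averaged across subjects (unweighted) to give per-class scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectraSet",
    "RecallConfig",
    "spectral_mae",
    "nearest_distances",
    "spectral_recall",
    "hierarchical_recall",
    "select_threshold",
    "pca_realism",
    "subsample_equal",
]

DEFAULT_D_MAX = 0.02


@dataclass(frozen=True)
class RecallConfig:
    """Distance threshold of the recall metric (spectral MAE, strict <)."""

    d_max: float = DEFAULT_D_MAX

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be > 0")


@dataclass(frozen=True)
class SpectraSet:
    """Annotated collection of spectra on one shared wavelength grid.

    ``subject_id`` / ``class_label`` / ``image_id`` are optional per-spectrum
    annotations required by the hierarchical and PCA protocols.
    """

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    subject_id: np.ndarray | None = None
    class_label: np.ndarray | None = None
    image_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if s.ndim != 2 or s.shape[1] != w.size:
            raise ValueError("spectra must be (count, n_lambda) on the given grid")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "spectra", s)
        object.__setattr__(self, "wavelengths_nm", w)
        for name in ("subject_id", "class_label", "image_id"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != s.shape[0]:
                    raise ValueError(f"{name} must have one entry per spectrum")
                object.__setattr__(self, name, v)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def select(self, mask) -> "SpectraSet":
        def sub(v):
            return None if v is None else v[mask]

        return SpectraSet(self.spectra[mask], self.wavelengths_nm,
                          sub(self.subject_id), sub(self.class_label), sub(self.image_id))


def _check_grids(a: SpectraSet, b: SpectraSet) -> None:
    if a.wavelengths_nm.shape != b.wavelengths_nm.shape or \
            not np.allclose(a.wavelengths_nm, b.wavelengths_nm):
        raise ValueError("spectra sets are on different wavelength grids")


def spectral_mae(a: np.ndarray, b: np.ndarray) -> float:
    """Per-wavelength mean absolute distance between two spectra."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("spectra grids differ")
    return float(np.mean(np.abs(a - b)))


def nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min_j MAE(a_i, b_j) for every row of ``a``; exact (brute-force) result.

    Row-vectorized with the same ``mean`` reduction a scalar double loop
    performs, so the result is bit-identical to the brute-force definition.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("spectra grids differ")
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        out[i] = np.abs(a[i] - b).mean(axis=1).min()
    return out


def spectral_recall(a: SpectraSet, b: SpectraSet,
                    cfg: RecallConfig = RecallConfig()) -> float:
    """Fraction of reference spectra with a candidate strictly within d_max."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("recall needs nonempty spectra sets")
    _check_grids(a, b)
    dmin = nearest_distances(a.spectra, b.spectra)
    return float(np.mean(dmin < cfg.d_max))


def hierarchical_recall(a: SpectraSet, b: SpectraSet,
                        cfg: RecallConfig = RecallConfig()) -> dict[object, float]:
    """Per-class recall aggregated spectrum -> subject -> class.

    Per reference spectrum the binary hit decision is computed, averaged per
    (subject, class), and the per-subject scores are averaged unweighted per
    class.  Subjects without spectra of a class are skipped for that class.
    """
    if a.subject_id is None or a.class_label is None:
        raise ValueError("hierarchical recall needs subject_id and class_label annotations")
    _check_grids(a, b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("recall needs nonempty spectra sets")
    hits = nearest_distances(a.spectra, b.spectra) < cfg.d_max
    scores: dict[object, list[float]] = {}
    for subject in np.unique(a.subject_id):
        s_mask = a.subject_id == subject
        for cls in np.unique(a.class_label[s_mask]):
            m = s_mask & (a.class_label == cls)
            scores.setdefault(cls, []).append(float(np.mean(hits[m])))
    return {cls: float(np.mean(v)) for cls, v in scores.items()}


def select_threshold(a: SpectraSet, candidate_sets: list[SpectraSet],
                     grid: np.ndarray | None = None) -> float:
    """Threshold at the steepest recall increase, minimized across candidates.

    For each candidate set the grid point with the maximal forward difference
    of the recall curve is that candidate's optimal threshold; the returned
    threshold is the lowest across candidates.  A flat recall curve yields
    the smallest grid point.
    """
    if grid is None:
        grid = np.logspace(-3, -1, 50)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    best = []
    for b in candidate_sets:
        _check_grids(a, b)
        dmin = nearest_distances(a.spectra, b.spectra)
        curve = np.array([np.mean(dmin < t) for t in grid])
        inc = np.diff(curve)
        if np.all(inc <= 0):  # flat curve: signal with the smallest grid point
            best.append(grid[0])
        else:
            best.append(grid[1:][np.argmax(inc)])
    return float(min(best))


def subsample_equal(sets: list[SpectraSet], n: int, seed: int) -> list[SpectraSet]:
    """Seeded uniform subsampling of each set to ``n`` spectra (without
    replacement); removes dataset size as a confounding factor."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sets:
        if len(s) < n:
            raise ValueError(f"set of {len(s)} spectra cannot be subsampled to {n}")
        out.append(s.select(np.sort(rng.choice(len(s), size=n, replace=False))))
    return out


@dataclass(frozen=True)
class PCARealismResult:
    """Frozen 2-D reference embedding with projected candidate sets."""

    components: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    reference_embedding: np.ndarray
    reference_class: np.ndarray
    class_means: dict
    candidate_embeddings: list[np.ndarray]
    coverage: list[float] = field(default_factory=list)

    def project(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, float) - self.mean) @ self.components.T


def pca_realism(reference: SpectraSet, candidates: list[SpectraSet],
                n_components: int = 2) -> PCARealismResult:
    """PCA manifold comparison of candidate sets against a reference.

    The PCA is fitted to image-level, label-averaged reference spectra (one
    mean spectrum per (image, class) pair); candidates are projected with the
    frozen loadings.  Coverage is summarized per candidate as the fraction of
    its points inside the convex hull of the reference embedding.
    """
    from sklearn.decomposition import PCA

    if reference.image_id is None or reference.class_label is None:
        raise ValueError("reference needs image_id and class_label annotations")
    keys = list(zip(reference.image_id.tolist(), reference.class_label.tolist()))
    uniq = sorted(set(keys))
    averaged = np.stack([
        reference.spectra[[k == u for k in keys]].mean(axis=0) for u in uniq
    ])
    if averaged.shape[0] < n_components:
        raise ValueError(
            f"only {averaged.shape[0]} image-level averaged spectra for "
            f"{n_components} components"
        )
    pca = PCA(n_components=n_components)
    ref_emb = pca.fit_transform(averaged)
    ref_cls = np.array([u[1] for u in uniq])
    class_means = {c: ref_emb[ref_cls == c].mean(axis=0) for c in np.unique(ref_cls)}

    cand_embs, coverage = [], []
    hull = None
    if n_components == 2 and averaged.shape[0] >= 3:
        from scipy.spatial import Delaunay

        try:
            hull = Delaunay(ref_emb)
        except Exception:
            hull = None  # degenerate (collinear) reference cloud
    for c in candidates:
        _check_grids(reference, c)
        emb = pca.transform(c.spectra)
        cand_embs.append(emb)
        if hull is not None:
            coverage.append(float(np.mean(hull.find_simplex(emb) >= 0)))
        else:
            coverage.append(float("nan"))
    return PCARealismResult(
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        reference_embedding=ref_emb,
        reference_class=ref_cls,
        class_means=class_means,
        candidate_embeddings=cand_embs,
        coverage=coverage,
    )
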