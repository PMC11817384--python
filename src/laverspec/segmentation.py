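"""Pore exclusion inside the ROI via ISODATA clustering.

Dried-laver sheets carry small pores through which the bright white
scanning background shows, so pore pixels are near-flat, high-reflectance
spectra while tissue pixels are darker and structured.  Pixel spectra are
clustered with full ISODATA (iterative nearest-centroid assignment with
cluster splitting and merging, capped at 100 classes, 5% assignment-change
convergence, 10 iterations), clusters resembling the white reference are
flagged as pore, and the per-sheet feature vector is the mean spectrum
over the remaining tissue pixels.

Initial centroids are the mean spectra of brightness-quantile bins, which
makes the clustering deterministic and invariant to pixel ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cube_io import SpectralCube

__all__ = [
    "IsodataParams",
    "PoreMask",
    "EmptyTissueError",
    "isodata_cluster",
    "classify_pore_clusters",
    "mean_spectrum",
    "extract_sample_spectrum",
]


class EmptyTissueError(ValueError):
    """Every pixel was masked as pore; no tissue spectrum exists."""


@dataclass(frozen=True)
class IsodataParams:
    """ISODATA controls.

    ``change_threshold`` is the convergence criterion: stop when fewer
    than this fraction of pixels change cluster between iterations.
    ``split_std`` (reflectance units) triggers splitting of clusters with
    a high-variance band; ``merge_distance`` (RMS per-band reflectance)
    merges close centroids.
    """

    max_classes: int = 100
    change_threshold: float = 0.05
    max_iterations: int = 10
    min_cluster_size: int = 20
    initial_classes: int = 5
    split_std: float = 0.05
    merge_distance: float = 0.02

    def __post_init__(self) -> None:
        if self.max_classes < 2:
            raise ValueError("max_classes must be >= 2")
        if not 0 < self.change_threshold < 1:
            raise ValueError("change_threshold must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 2 <= self.initial_classes <= self.max_classes:
            raise ValueError("initial_classes must lie in [2, max_classes]")


@dataclass
class PoreMask:
    """Boolean pore image over the ROI; True marks pore pixels."""

    mask: np.ndarray
    suspicious: bool = False  # every cluster looked like pore

    @property
    def pore_fraction(self) -> float:
        return float(self.mask.mean())


def _as_pixels(roi: SpectralCube | np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    data = roi.data if isinstance(roi, SpectralCube) else np.asarray(roi)
    if data.ndim != 3:
        raise ValueError("ROI must be a lines x samples x bands array")
    lines, samples, bands = data.shape
    return data.reshape(-1, bands).astype(np.float64), (lines, samples)


def _initial_centroids(pixels: np.ndarray, k: int) -> np.ndarray:
    """Mean spectra of k brightness-quantile bins (deterministic)."""
    brightness = pixels.mean(axis=1)
    order = np.argsort(brightness, kind="stable")
    bins = np.array_split(order, k)
    cents = [pixels[b].mean(axis=0) for b in bins if b.size > 0]
    return np.unique(np.array(cents), axis=0)


def isodata_cluster(
    roi: SpectralCube | np.ndarray,
    params: IsodataParams = IsodataParams(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pixel spectra; returns (label image, cluster mean spectra).

    Each iteration assigns pixels to the nearest centroid (Euclidean over
    bands), drops clusters below ``min_cluster_size``, merges centroids
    closer than ``merge_distance`` and splits clusters whose widest band
    standard deviation exceeds ``split_std`` while under ``max_classes``.
    Iteration stops once fewer than ``change_threshold`` of pixels change
    assignment, or after ``max_iterations``.  A constant ROI yields a
    single cluster.  ``rng`` is accepted for interface symmetry; the
    algorithm is deterministic.
    """
    pixels, shape = _as_pixels(roi)
    n_pixels, n_bands = pixels.shape
    if n_pixels < max(2, params.min_cluster_size):
        raise ValueError("ROI too small to cluster")

    if np.allclose(pixels, pixels[0]):
        labels = np.zeros(n_pixels, dtype=int)
        return labels.reshape(shape), pixels[:1].copy()

    centroids = _initial_centroids(pixels, params.initial_classes)
    prev_labels = np.full(n_pixels, -1)
    labels = prev_labels
    for _ in range(params.max_iterations):
        d = cdist(pixels, centroids)
        labels = np.argmin(d, axis=1)
        changed = np.mean(labels != prev_labels)
        prev_labels = labels

        # drop undersized clusters, reassign their pixels
        counts = np.bincount(labels, minlength=len(centroids))
        keep = counts >= params.min_cluster_size
        if keep.sum() == 0:
            keep[np.argmax(counts)] = True
        if not keep.all():
            centroids = centroids[keep]
            d = cdist(pixels, centroids)
            labels = np.argmin(d, axis=1)
            prev_labels = labels

        # update means
        centroids = np.array(
            [pixels[labels == c].mean(axis=0) for c in range(len(centroids))]
        )

        if changed < params.change_threshold:
            break

        # merge closest pair while under the per-band RMS threshold
        while len(centroids) > 1:
            dc = cdist(centroids, centroids) / np.sqrt(n_bands)
            np.fill_diagonal(dc, np.inf)
            i, j = np.unravel_index(np.argmin(dc), dc.shape)
            if dc[i, j] >= params.merge_distance:
                break
            ni = np.sum(labels == i)
            nj = np.sum(labels == j)
            merged = (ni * centroids[i] + nj * centroids[j]) / max(ni + nj, 1)
            centroids = np.delete(centroids, j, axis=0)
            centroids[i if i < j else i - 1] = merged
            labels = np.where(labels == j, i, labels)
            labels[labels > j] -= 1

        # split clusters with a high-variance band
        new_centroids = []
        for c in range(len(centroids)):
            members = pixels[labels == c]
            stds = members.std(axis=0)
            wide = int(np.argmax(stds))
            if (
                stds[wide] > params.split_std
                and len(centroids) + len(new_centroids) < params.max_classes
                and members.shape[0] >= 2 * params.min_cluster_size
            ):
                delta = np.zeros(n_bands)
                delta[wide] = stds[wide]
                new_centroids.append(centroids[c] + delta)
                centroids[c] = centroids[c] - delta
        if new_centroids:
            centroids = np.vstack([centroids, np.array(new_centroids)])

    # final assignment against the final centroid set
    d = cdist(pixels, centroids)
    labels = np.argmin(d, axis=1)
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[v] for v in labels])
    centroids = np.array([pixels[labels == c].mean(axis=0) for c in range(len(present))])
    return labels.reshape(shape), centroids


def classify_pore_clusters(
    labels: np.ndarray,
    centroids: np.ndarray,
    white_spectrum: np.ndarray | None = None,
    cosine_threshold: float = 0.995,
    brightness_threshold: float = 0.6,
) -> PoreMask:
    """Flag clusters resembling the white reference as pore.

    A cluster is pore when its mean spectrum is both bright (mean
    reflectance above ``brightness_threshold``) and spectrally flat in
    the sense of cosine similarity to the white spectrum (default: unit
    flat spectrum) above ``cosine_threshold``.  Should every cluster
    qualify, the mask is returned with ``suspicious=True`` — the ROI may
    have missed the sheet entirely.
    """
    centroids = np.atleast_2d(centroids)
    if white_spectrum is None:
        white = np.ones(centroids.shape[1])
    else:
        white = np.asarray(white_spectrum, dtype=float)
    wnorm = white / np.linalg.norm(white)
    cnorm = np.linalg.norm(centroids, axis=1)
    cos = centroids @ wnorm / np.where(cnorm > 0, cnorm, 1.0)
    is_pore = (cos >= cosine_threshold) & (centroids.mean(axis=1) >= brightness_threshold)
    mask = is_pore[labels]
    suspicious = bool(is_pore.all())
    if suspicious:
        warnings.warn("all clusters classified as pore; ROI may contain no tissue")
    return PoreMask(mask=mask, suspicious=suspicious)


def mean_spectrum(roi: SpectralCube | np.ndarray, mask: PoreMask | np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean spectrum over non-pore pixels.

    With no mask (or an all-false mask) this is the plain spatial mean.
    Raises :class:`EmptyTissueError` if the mask covers every pixel.
    """
    data = roi.data if isinstance(roi, SpectralCube) else np.asarray(roi)
    if mask is None:
        return data.mean(axis=(0, 1))
    m = mask.mask if isinstance(mask, PoreMask) else np.asarray(mask, dtype=bool)
    if m.shape != data.shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match ROI {data.shape[:2]}")
    tissue = ~m
    if not tissue.any():
        raise EmptyTissueError("mask covers every pixel; no tissue left")
    return data[tissue].mean(axis=0)


def extract_sample_spectrum(
    roi: SpectralCube,
    params: IsodataParams = IsodataParams(),
    white_spectrum: np.ndarray | None = None,
) -> tuple[np.ndarray, PoreMask]:
    """Cluster, mask pores, and return the pore-free mean spectrum + mask."""
    labels, centroids = isodata_cluster(roi, params)
    mask = classify_pore_clusters(labels, centroids, white_spectrum)
    if mask.suspicious:
        # fall back to the unmasked mean rather than failing the sheet
        return mean_spectrum(roi, None), mask
    return mean_spectrum(roi, mask), mask
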