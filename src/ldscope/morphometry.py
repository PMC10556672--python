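"""Brightfield cell morphometry: pixel classification, particle analysis,
shape filtering and prolate-spheroid volumetry.

The 2D pipeline mirrors a trainable-segmentation workflow: per-pixel
features (raw intensity, Sobel edge magnitude, moving-maximum texture and
a Gabor filter bank) feed a bootstrap-aggregated decision-tree classifier
that outputs a per-pixel probability of belonging to a cell; the
thresholded probability map is analysed into particles with the standard
shape descriptors (circularity, fitted-ellipse axes, Feret diameter,
aspect ratio, roundness, solidity); ecotype-specific filters remove
debris, bubbles and merged blobs; and each retained cell's volume is
estimated as V = pi/6 * W^2 * L with W the fitted-ellipse minor axis and
L the Feret diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import gabor_kernel
from skimage.measure import label as sk_label
from skimage.measure import perimeter as sk_perimeter
from skimage.measure import regionprops
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger(__name__)

PARTICLE_COLUMNS = [
    "label", "area_um2", "perimeter_um", "circularity", "ellipse_major_um",
    "ellipse_minor_um", "feret_um", "AR", "roundness", "solidity",
    "width_um", "length_um", "volume_um3", "centroid_x_um", "centroid_y_um",
]


# ---------------------------------------------------------------------------
# prolate-spheroid volume model
# ---------------------------------------------------------------------------

def estimate_cell_volume(width: float, length: float) -> float:
    """Prolate-spheroid cell volume V = pi/6 * W^2 * L (um^3).

    Width enters squared, so the two dimensions are not interchangeable.
    """
    width = np.asarray(width, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(width <= 0) or np.any(length <= 0):
        raise ValueError("width and length must be positive")
    out = math.pi / 6.0 * width ** 2 * length
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# per-pixel features
# ---------------------------------------------------------------------------

def compute_features(image: np.ndarray,
                     max_filter_radii: tuple[int, ...] = (2, 12, 25),
                     gabor_frequencies: tuple[float, ...] = (0.1,),
                     gabor_orientations: int = 4) -> np.ndarray:
    """Per-pixel feature stack for the pixel classifier.

    Planes: raw intensity, Sobel gradient magnitude (edges), moving
    maxima (texture/context) and the Gabor energy of an oriented filter
    bank; one (H, W, F) float array.  The maximum filter runs at several
    radii because the largest scale is what separates thin elongated
    cells (whose neighbourhood reaches bright background) from wide dark
    debris; radii are in pixels and config-exposed since the appropriate
    scales depend on the pixel size.  Gabor frequencies are in
    cycles/pixel, orientations evenly spaced over pi.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    planes = [img]
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    edge = np.hypot(gx, gy)
    if not edge.any():
        log.info("constant image: edge features are identically zero")
    planes.append(edge)
    for r in max_filter_radii:
        planes.append(ndimage.maximum_filter(img, size=2 * r + 1,
                                             mode="reflect"))
    for f in gabor_frequencies:
        energies = []
        for k in range(gabor_orientations):
            theta = k * math.pi / gabor_orientations
            kern = gabor_kernel(f, theta=theta)
            # Gabor energy (magnitude of the complex response): phase
            # invariant, so the plane does not oscillate across a cell
            re = fftconvolve(img, np.real(kern), mode="same")
            im = fftconvolve(img, np.imag(kern), mode="same")
            energies.append(np.hypot(re, im))
        # pool across orientations so the feature does not depend on the
        # angle a cell happens to lie at
        energies = np.stack(energies)
        planes.append(energies.max(axis=0))
        planes.append(energies.mean(axis=0))
    return np.stack(planes, axis=-1)


# ---------------------------------------------------------------------------
# pixel classifier
# ---------------------------------------------------------------------------

class PixelClassifier(BaseEstimator, ClassifierMixin):
    """Two-class per-pixel classifier ("cell" vs background/debris/bubbles).

    A bootstrap-aggregated decision-tree ensemble (random forest) over the
    feature stack of :func:`compute_features`.  Training pixels come from
    sparse annotations; :meth:`fit_image` accepts a label mask (0 =
    unlabeled, 1 = cell, 2 = background) and subsamples at most
    ``max_train_pixels`` per run for speed, deterministically from
    ``random_state``.

    Parameters follow sklearn conventions; fitted attributes carry a
    trailing underscore.
    """

    def __init__(self, n_estimators: int = 30, max_depth: int | None = None,
                 min_samples_leaf: int = 2, max_train_pixels: int = 60000,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_train_pixels = max_train_pixels
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PixelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("both classes must be represented in the "
                             "training labels")
        rng = np.random.default_rng(self.random_state)
        if X.shape[0] > self.max_train_pixels:
            idx = rng.choice(X.shape[0], self.max_train_pixels, replace=False)
            X, y = X[idx], y[idx]
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state, n_jobs=1)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def fit_image(self, features: np.ndarray, label_mask: np.ndarray
                  ) -> "PixelClassifier":
        """Fit from a feature stack and a sparse annotation mask."""
        sel = label_mask > 0
        X = features[sel]
        y = np.where(label_mask[sel] == 1, 1, 0)
        return self.fit(X, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict_proba_image(self, features: np.ndarray) -> np.ndarray:
        """Probability map of the "cell" class over a feature stack."""
        check_is_fitted(self, "forest_")
        h, w, f = features.shape
        proba = self.forest_.predict_proba(features.reshape(-1, f))
        cell_col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, cell_col].reshape(h, w)


def train_classifier(features: np.ndarray, label_mask: np.ndarray,
                     seed: int = 0, **params) -> PixelClassifier:
    """Thin functional wrapper over :class:`PixelClassifier`."""
    return PixelClassifier(random_state=seed, **params).fit_image(
        features, label_mask)


# ---------------------------------------------------------------------------
# particle analysis
# ---------------------------------------------------------------------------

def feret_diameter(coords: np.ndarray) -> float:
    """Maximum pairwise distance between pixel centers of a particle.

    Computed over the convex hull vertices, which is exactly the
    brute-force maximum over all boundary-point pairs (the maximum of a
    convex function over a convex set is attained at a vertex).
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (collinear) particles: brute force over all pixels
    return float(pdist(pts).max())


@dataclass
class EcotypeFilterConfig:
    """Shape-filter bounds applied after particle analysis.

    Defaults follow the original screening protocol: area 25-200 um^2,
    circularity 0-0.4 for both ecotypes; AR >= 3, roundness <= 0.3,
    solidity >= 0.55 for Pt1 and AR >= 3.5, roundness <= 0.3,
    solidity >= 0.5 for Pt4.
    """

    area_range_um2: tuple[float, float] = (25.0, 200.0)
    circularity_range: tuple[float, float] = (0.0, 0.4)
    min_AR: float = 3.0
    max_roundness: float = 0.3
    min_solidity: float = 0.55

    def __post_init__(self) -> None:
        if not self.area_range_um2[0] < self.area_range_um2[1]:
            raise ValueError("area range lower bound must be below upper")

    @classmethod
    def for_ecotype(cls, ecotype: str) -> "EcotypeFilterConfig":
        if ecotype == "Pt1":
            return cls(min_AR=3.0, max_roundness=0.3, min_solidity=0.55)
        if ecotype == "Pt4":
            return cls(min_AR=3.5, max_roundness=0.3, min_solidity=0.5)
        raise ValueError(f"unknown ecotype {ecotype!r}")


class ParticleAnalyzer(BaseEstimator):
    """Probability map -> particle measurement table.

    ``transform`` thresholds the map at ``threshold`` (default 0.5),
    labels 8-connected components and measures, per particle: area,
    perimeter, circularity = 4 pi A / P^2, moment-fitted ellipse axes,
    Feret diameter, AR = major/minor, roundness = 4 A / (pi major^2) and
    solidity = A / convex area, all converted to um with
    ``pixel_size_um`` before any filtering.
    """

    def __init__(self, threshold: float = 0.5, pixel_size_um: float = 0.1,
                 min_area_px: int = 5):
        self.threshold = threshold
        self.pixel_size_um = pixel_size_um
        self.min_area_px = min_area_px

    def transform(self, prob_map: np.ndarray) -> pd.DataFrame:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        px = self.pixel_size_um
        mask = np.asarray(prob_map) >= self.threshold
        labels = sk_label(mask, connectivity=2)
        rows = []
        for rp in regionprops(labels):
            if rp.area < self.min_area_px:
                continue
            area = rp.area * px * px
            perim = sk_perimeter(rp.image, neighborhood=4) * px
            circ = 4.0 * math.pi * area / perim ** 2 if perim > 0 else np.nan
            major = rp.axis_major_length * px
            minor = rp.axis_minor_length * px
            feret = feret_diameter(rp.coords) * px
            ar = major / minor if minor > 0 else np.inf
            roundness = 4.0 * area / (math.pi * major ** 2) if major > 0 else np.nan
            width, length = minor, feret
            vol = (estimate_cell_volume(width, length)
                   if width > 0 and length > 0 else np.nan)
            cy, cx = rp.centroid
            rows.append([rp.label, area, perim, circ, major, minor, feret,
                         ar, roundness, rp.solidity, width, length, vol,
                         (cx + 0.5) * px, (cy + 0.5) * px])
        return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)

    def fit(self, X=None, y=None):  # stateless; present for pipeline duck-typing
        return self


def segment_particles(prob_map: np.ndarray, threshold: float = 0.5,
                      pixel_size_um: float = 0.1) -> pd.DataFrame:
    """Functional wrapper over :class:`ParticleAnalyzer`."""
    return ParticleAnalyzer(threshold=threshold,
                            pixel_size_um=pixel_size_um).transform(prob_map)


def filter_cells(particles: pd.DataFrame,
                 config: EcotypeFilterConfig) -> pd.DataFrame:
    """Apply the area/circularity/AR/roundness/solidity screen.

    All five predicates must hold (bounds inclusive); the input frame is
    untouched and row order is preserved.  Idempotent by construction.
    """
    p = particles
    keep = (
        (p["area_um2"] >= config.area_range_um2[0])
        & (p["area_um2"] <= config.area_range_um2[1])
        & (p["circularity"] >= config.circularity_range[0])
        & (p["circularity"] <= config.circularity_range[1])
        & (p["AR"] >= config.min_AR)
        & (p["roundness"] <= config.max_roundness)
        & (p["solidity"] >= config.min_solidity)
    )
    return p.loc[keep].copy()


# ---------------------------------------------------------------------------
# convenience: full 2D pipeline on one image
# ---------------------------------------------------------------------------

def measure_mosaic(image: np.ndarray, classifier: PixelClassifier,
                   ecotype: str = "Pt1", pixel_size_um: float = 0.1,
                   threshold: float = 0.5,
                   feature_kwargs: dict | None = None) -> pd.DataFrame:
    """Features -> probability map -> particles -> ecotype filter."""
    feats = compute_features(image, **(feature_kwargs or {}))
    prob = classifier.predict_proba_image(feats)
    particles = segment_particles(prob, threshold=threshold,
                                  pixel_size_um=pixel_size_um)
    return filter_cells(particles, EcotypeFilterConfig.for_ecotype(ecotype))
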