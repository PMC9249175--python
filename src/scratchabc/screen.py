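"""Screen-level analytics over per-condition posterior distributions.

Each experimental condition (gene knockdown) is summarised by the weighted
posterior mean of the model parameters, reported in the identifiable 5-D
space (m, p - d, gamma_m, gamma_p, gamma_b).  Across a screen these points
are clustered with K-means (on z-scored coordinates, with the number of
clusters chosen by the elbow of the within-cluster sum of squares), and
compared with two simple experiment-level read-outs:

* the cell-count fold change C = c24 / c0, with the model-based estimates
  C = exp(24 (p - d)) (density-independent) and its density-corrected
  refinement, and
* the wound-area fold change W = w24 / w0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .ibm import CellPopulation
from .summaries import DENSITY_BINS, density_profile

__all__ = [
    "KnockdownSummary",
    "ClusterResult",
    "posterior_mean",
    "kmeans_cluster",
    "wcss_scan",
    "elbow_select_k",
    "fold_change_naive",
    "fold_change_density_corrected",
    "wound_area_from_profile",
]

#: a density-profile bin is called wound if it holds less than this fraction
#: of the median occupied-bin count
WOUND_BIN_THRESHOLD = 0.5


@dataclass
class KnockdownSummary:
    """Posterior point estimate and raw read-outs for one condition."""

    label: str
    posterior_mean: np.ndarray  # (m, p - d, gamma_m, gamma_p, gamma_b)
    c0: int
    c24: int
    w0: float
    w24: float
    fov_area: float

    @property
    def fold_cell(self) -> float:
        if self.c0 <= 0:
            raise ValueError("cell fold change undefined for c0 = 0")
        return self.c24 / self.c0

    @property
    def fold_wound(self) -> float:
        if self.w0 <= 0:
            raise ValueError("wound fold change undefined for w0 = 0")
        return self.w24 / self.w0


@dataclass
class ClusterResult:
    """K-means clustering output; labels are 1-based cluster ids."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    wcss: Optional[np.ndarray] = None  # WCSS over the scan range k = 1..k_max


def posterior_mean(pop) -> np.ndarray:
    """Weighted posterior mean in the 5-D space (m, p-d, gamma_m, gamma_p, gamma_b).

    ``pop`` is a particle population with ``thetas`` (N, 6) ordered as
    (m, p, d, gamma_m, gamma_p, gamma_b) and normalised ``weights``.
    """
    th = np.asarray(pop.thetas, dtype=float)
    w = np.asarray(pop.weights, dtype=float)
    mean6 = w @ th / w.sum()
    return np.array([mean6[0], mean6[1] - mean6[2], mean6[3], mean6[4], mean6[5]])


def _standardise(points: np.ndarray) -> np.ndarray:
    sd = points.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (points - points.mean(axis=0)) / sd


def kmeans_cluster(points, k: int, rng=None, standardise: bool = True,
                   n_restarts: int = 10) -> ClusterResult:
    """K-means (Lloyd, multiple restarts, best WCSS kept) on the screen points.

    Coordinates are z-scored by default because the parameters differ by
    orders of magnitude in scale.  Deterministic given the seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not 1 <= k <= len(points):
        raise ValueError(f"k={k} must be between 1 and the number of points "
                         f"({len(points)})")
    x = _standardise(points) if standardise else points
    seed = int(np.random.default_rng(rng).integers(2 ** 31 - 1))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(x)
    return ClusterResult(k=k, assignments=km.labels_ + 1,
                         centroids=km.cluster_centers_)


def wcss_scan(points, k_max: int, rng=None,
              standardise: bool = True) -> np.ndarray:
    """Best within-cluster sum of squares for k = 1 .. k_max."""
    points = np.asarray(points, dtype=float)
    if k_max > len(points):
        raise ValueError("k_max exceeds the number of points")
    x = _standardise(points) if standardise else points
    gen = np.random.default_rng(rng)
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        seed = int(gen.integers(2 ** 31 - 1))
        km = KMeans(n_clusters=k, n_init=10, random_state=seed,
                    algorithm="lloyd").fit(x)
        out[k - 1] = km.inertia_
    return out


def elbow_select_k(wcss_by_k: Sequence[float]) -> int:
    """Elbow of a WCSS-versus-k curve: the interior k with maximal curvature.

    ``wcss_by_k[i]`` is the WCSS at k = i + 1.  The elbow is the k
    maximising the discrete second difference W(k-1) - 2 W(k) + W(k+1);
    ties break toward smaller k.
    """
    w = np.asarray(wcss_by_k, dtype=float)
    if w.size < 3:
        raise ValueError("need WCSS values for at least three k to find an elbow")
    curv = w[:-2] - 2.0 * w[1:-1] + w[2:]
    return int(np.argmax(curv)) + 2  # interior k values start at k = 2


def fold_change_naive(p_minus_d: float, duration: float = 24.0) -> float:
    """Expected cell-count fold change ignoring density effects: e^(t (p-d))."""
    return math.exp(duration * p_minus_d)


def fold_change_density_corrected(p_minus_d: float, gamma_p: float,
                                  sigma: float, c0: float, c24: float,
                                  w0: float, w24: float, fov_area: float,
                                  duration: float = 24.0,
                                  prefactor: Optional[float] = None) -> float:
    """Cell-count fold change corrected for density-dependent proliferation.

    The per-cell crowding sum is approximated by the kernel integral
    ``rho * integral w dA = rho * 2 pi sigma^2`` at the average of the
    initial and final free-area densities ``rho_t = c_t / (F - w_t)``:

        C = exp(t (p - d - gamma_p * pre * (rho_0 + rho_24))),

    with ``pre = pi sigma^2`` by default (``prefactor`` overrides it, for
    comparison with other printed forms of the correction).  Areas are in
    mm^2 and converted internally; sigma is in um.
    """
    if fov_area <= w0 or fov_area <= w24:
        raise ValueError("field-of-view area must exceed both wound areas")
    if c0 < 0 or c24 < 0:
        raise ValueError("cell counts must be non-negative")
    pre = math.pi * sigma ** 2 if prefactor is None else prefactor
    rho0 = c0 / ((fov_area - w0) * 1e6)
    rho24 = c24 / ((fov_area - w24) * 1e6)
    return math.exp(duration * (p_minus_d - gamma_p * pre * (rho0 + rho24)))


def wound_area_from_profile(pop: CellPopulation,
                            n_bins: int = DENSITY_BINS,
                            threshold: float = WOUND_BIN_THRESHOLD) -> float:
    """Wound area (mm^2) segmented from the 1-D density profile.

    Bins holding fewer cells than ``threshold`` times the median occupied
    bin are marked as wound; the largest contiguous run of wound bins
    (respecting the periodic wrap) defines the wound band.  A population
    with no occupied bins returns the full field-of-view area.
    """
    profile = density_profile(pop, n_bins)
    area_fov = pop.domain.area / 1e6
    occupied = profile > 0
    if not occupied.any():
        return area_fov
    cutoff = threshold * np.median(profile[occupied])
    wound = profile < cutoff
    if wound.all():
        return area_fov
    if not wound.any():
        return 0.0
    # rotate so a non-wound bin is first, then take the longest run
    start = int(np.argmin(wound))
    rolled = np.roll(wound, -start)
    best = run = 0
    for flag in rolled:
        run = run + 1 if flag else 0
        best = max(best, run)
    dy = pop.domain.width_y / n_bins
    return best * dy * pop.domain.width_x / 1e6
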