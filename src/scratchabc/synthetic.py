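"""Synthetic scratch-assay datasets with known ground truth.

Emulates what the imaging pipeline of a wound-healing screen delivers: for
each well, a table of cell centres at t = 0 h (a near-confluent monolayer
with a cell-free wound band of varying position and width) and at t = 24 h
(here produced by forward simulation of the individual-based model), plus
per-well metadata (counts, wound areas, field-of-view area, pixel scale,
estimated cell diameter).

Two reference parameter regimes are built in:

* regime I  - fast movers whose motility is *enhanced* by crowding:
  m = 1.5 /h, p - d = 0.01 /h, gamma_m = -1 /h, gamma_p = 0.01 /h,
  gamma_b = 20 um;
* regime II - slow movers with contact-inhibited motility and faster net
  proliferation: m = 0.5 /h, p - d = 0.025 /h, gamma_m = 1.5 /h,
  gamma_p = 0.01 /h, gamma_b = 20 um.

Only the net proliferation rate p - d is identifiable from two snapshots,
so the split is fixed by convention: d = 0.005 /h and p = d + (p - d).

The module also provides the cell-diameter estimator used to set the
interaction scale sigma = phi / 2 from data: phi is the diameter of the
circle whose area equals the median per-cell Voronoi area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial import Voronoi

from .ibm import CellPopulation, Domain, ModelParams, simulate
from .screen import wound_area_from_profile

__all__ = [
    "REGIMES",
    "DEFAULT_PHI",
    "DEFAULT_MONOLAYER_DENSITY",
    "DEATH_RATE_SPLIT",
    "ScratchObservation",
    "WoundGeometry",
    "regime_params",
    "generate_initial_condition",
    "generate_regime_dataset",
    "estimate_cell_diameter",
    "voronoi_areas",
]

#: ground-truth 5-D parameter values (m, p - d, gamma_m, gamma_p, gamma_b)
REGIMES: Dict[str, Dict[str, float]] = {
    "I": {"m": 1.5, "p_minus_d": 0.01, "gamma_m": -1.0,
          "gamma_p": 0.01, "gamma_b": 20.0},
    "II": {"m": 0.5, "p_minus_d": 0.025, "gamma_m": 1.5,
           "gamma_p": 0.01, "gamma_b": 20.0},
}

#: default synthetic cell diameter (um), ~ one density-profile bin
DEFAULT_PHI = 24.0

#: monolayer density outside the wound band (cells / um^2); gives initial
#: populations of roughly 250-350 cells on the default cropped field of view
DEFAULT_MONOLAYER_DENSITY = 6.0e-4

#: fixed death rate used to split p - d into (p, d)
DEATH_RATE_SPLIT = 0.005

# wound-band geometry ranges (um), spanning wound fractions comparable to
# the 1.8-3.1 mm^2 range seen in control wells rescaled to the cropped view
_WOUND_WIDTH_RANGE = (430.0, 740.0)
_WOUND_CENTER_FRACTION = (0.35, 0.65)


@dataclass
class ScratchObservation:
    """One paired scratch-assay observation with its metadata.

    Areas (w0, w24, fov_area) are in mm^2; positions in um.
    """

    initial: CellPopulation
    final: CellPopulation
    w0: float
    w24: float
    um_per_px: float = 2.97
    phi: float = DEFAULT_PHI
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial.domain != self.final.domain:
            raise ValueError("initial and final snapshots must share a domain")
        f = self.fov_area
        for name, w in (("w0", self.w0), ("w24", self.w24)):
            if not 0 <= w <= f + 1e-9:
                raise ValueError(f"wound area {name}={w} outside [0, {f}] mm^2")

    @property
    def c0(self) -> int:
        return self.initial.size

    @property
    def c24(self) -> int:
        return self.final.size

    @property
    def fov_area(self) -> float:
        """Field-of-view area in mm^2."""
        return self.initial.domain.area / 1e6


@dataclass(frozen=True)
class WoundGeometry:
    """A horizontal cell-free band in an otherwise uniform monolayer."""

    center_y: float
    width: float
    monolayer_density: float = DEFAULT_MONOLAYER_DENSITY

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wound width must be positive")
        if self.monolayer_density <= 0:
            raise ValueError("monolayer density must be positive")


def regime_params(regime: str, phi: float = DEFAULT_PHI,
                  d: float = DEATH_RATE_SPLIT) -> ModelParams:
    """ModelParams for a named regime, splitting p - d with death rate d."""
    try:
        g = REGIMES[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}; choose from "
                         f"{sorted(REGIMES)}") from None
    return ModelParams(m=g["m"], p=d + g["p_minus_d"], d=d,
                       gamma_m=g["gamma_m"], gamma_p=g["gamma_p"],
                       gamma_b=g["gamma_b"], phi=phi)


def generate_initial_condition(geom: WoundGeometry, domain: Domain,
                               rng: np.random.Generator) -> CellPopulation:
    """Uniformly random monolayer with the wound band left empty.

    The band [center_y - width/2, center_y + width/2] is taken modulo the
    periodic y axis.  The number of cells is Poisson with mean
    density * (area outside the band).
    """
    if geom.width >= domain.width_y:
        raise ValueError("wound band covers the whole domain")
    free_height = domain.width_y - geom.width
    n = rng.poisson(geom.monolayer_density * domain.width_x * free_height)
    x = rng.uniform(0.0, domain.width_x, n)
    # sample y on the complement of the band, anchored at its upper edge
    band_top = (geom.center_y + geom.width / 2.0) % domain.width_y
    y = (band_top + rng.uniform(0.0, free_height, n)) % domain.width_y
    return CellPopulation(np.column_stack([x, y]), time=0.0, domain=domain)


def generate_regime_dataset(regime: str, n_obs: int,
                            domain: Optional[Domain] = None,
                            phi: float = DEFAULT_PHI,
                            rng=None,
                            monolayer_density: float = DEFAULT_MONOLAYER_DENSITY,
                            t_end: float = 24.0) -> List[ScratchObservation]:
    """Forward-simulated dataset of n_obs observations under one regime.

    Every observation gets its own randomly drawn wound geometry, so initial
    wound size and position vary across the dataset as they do between
    wells.  Ground-truth parameters are recorded in each observation's
    ``meta``.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    rng = np.random.default_rng(rng)
    domain = domain or Domain()
    params = regime_params(regime, phi=phi)
    truth = dict(REGIMES[regime])
    observations = []
    for k in range(n_obs):
        geom = WoundGeometry(
            center_y=rng.uniform(*_WOUND_CENTER_FRACTION) * domain.width_y,
            width=rng.uniform(*_WOUND_WIDTH_RANGE),
            monolayer_density=monolayer_density,
        )
        initial = generate_initial_condition(geom, domain, rng)
        final = simulate(initial, params, t_end, rng=rng)
        observations.append(ScratchObservation(
            initial=initial,
            final=final,
            w0=wound_area_from_profile(initial),
            w24=wound_area_from_profile(final),
            phi=phi,
            label=f"regime_{regime}_{k:03d}",
            meta={"regime": regime, "ground_truth": truth,
                  "wound_center_y": geom.center_y, "wound_width": geom.width},
        ))
    return observations


def estimate_cell_diameter(areas) -> float:
    """Equivalent-circle diameter of the median per-cell area.

    phi = 2 sqrt(median(A) / pi); robust to a minority of distorted
    tessellation polygons.  Input areas in um^2, result in um.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one cell area")
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        raise ValueError("cell areas must be positive and finite")
    return float(2.0 * np.sqrt(np.median(areas) / np.pi))


def voronoi_areas(pop: CellPopulation) -> np.ndarray:
    """Per-cell Voronoi polygon areas on the periodic domain (um^2).

    Computed by tiling the 3 x 3 periodic images and keeping the polygons of
    the central copy, so every region is finite; areas sum to the domain
    area (up to tessellation round-off).
    """
    n = pop.size
    if n < 4:
        raise ValueError("Voronoi tessellation needs at least 4 cells")
    widths = pop.domain.widths
    offsets = np.array([(ix, iy) for iy in (-1, 0, 1) for ix in (-1, 0, 1)])
    tiled = (pop.positions[None, :, :] + (offsets * widths)[:, None, :])
    tiled = tiled.reshape(-1, 2)
    central_start = 4 * n  # offset (0, 0) is the 5th of the 9 tiles
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[central_start + i]]
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas
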