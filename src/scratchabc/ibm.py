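"""Lattice-free individual-based model of density-dependent cell behaviour.

Each cell is an agent at a continuous position on a periodic rectangular
domain (the cropped field of view of a scratch assay, 180 x 512 pixels at
2.97 um/pixel by default).  Cells move, proliferate and die according to a
continuous-time Markov jump process:

* the movement rate of cell n is ``M_n = max(0, m - gamma_m * C_n)`` where
  ``C_n = sum_{j != n} exp(-r_nj^2 / 2 sigma^2)`` is a Gaussian-kernel
  crowding sum (truncated to zero at ``r >= 3 sigma``),
* the proliferation rate is ``P_n = max(0, p - gamma_p * C_n)``,
* the death rate is a constant ``d``.

Movement and daughter-placement directions are drawn from a von Mises
distribution whose mean is the direction of the bias vector (the negative
gradient of the crowding potential ``B(x) = sum_j gamma_b w(|x - x_j|)``)
and whose concentration is the bias magnitude, so isolated cells move
isotropically while crowded cells are pushed down the local density
gradient.  A move or proliferation displaces by one cell diameter ``phi``.

The process is simulated exactly with the Gillespie algorithm.  Two engines
are provided: a numba-compiled engine with a uniform-grid spatial hash and
event-local rate updates (the default, fast enough for inference), and a
plain-Python reference engine that recomputes every rate from scratch after
each event (used as an independent oracle in the tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

__all__ = [
    "UM_PER_PX",
    "FOV_PX",
    "ModelParams",
    "Domain",
    "CellPopulation",
    "SimEvent",
    "crowding_kernel",
    "min_image_displacement",
    "local_crowding_sum",
    "movement_rate",
    "proliferation_rate",
    "bias_vector",
    "sample_direction",
    "apply_event",
    "simulate",
]

#: microns per pixel of the imaging data the default geometry matches
UM_PER_PX = 2.97
#: cropped field of view in pixels (x axis, y axis); y is the wound axis
FOV_PX = (180, 512)

# cutoff radius of the interaction kernel, in units of sigma
_CUTOFF_SIGMA = 3.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """The six free parameters of the model plus the cell diameter.

    Rates are per hour, lengths in microns.  ``sigma``, the interaction
    length scale, is tied to the cell diameter as ``sigma = phi / 2``.
    """

    m: float
    p: float
    d: float
    gamma_m: float
    gamma_p: float
    gamma_b: float
    phi: float = 24.0

    def __post_init__(self) -> None:
        if self.m < 0 or self.p < 0 or self.d < 0:
            raise ValueError("intrinsic rates m, p, d must be non-negative")
        if self.gamma_p < 0:
            raise ValueError("gamma_p must be non-negative")
        if self.gamma_b < 0:
            raise ValueError("gamma_b must be non-negative")
        if self.phi <= 0:
            raise ValueError("cell diameter phi must be positive")

    @property
    def sigma(self) -> float:
        """Interaction length scale, phi / 2."""
        return self.phi / 2.0

    def as_array(self) -> np.ndarray:
        """The sampled parameter vector (m, p, d, gamma_m, gamma_p, gamma_b)."""
        return np.array(
            [self.m, self.p, self.d, self.gamma_m, self.gamma_p, self.gamma_b]
        )


@dataclass(frozen=True)
class Domain:
    """Periodic rectangular domain, widths in microns."""

    width_x: float = FOV_PX[0] * UM_PER_PX
    width_y: float = FOV_PX[1] * UM_PER_PX

    def __post_init__(self) -> None:
        if self.width_x <= 0 or self.width_y <= 0:
            raise ValueError("domain widths must be positive")

    @classmethod
    def from_pixels(cls, nx: int = FOV_PX[0], ny: int = FOV_PX[1],
                    um_per_px: float = UM_PER_PX) -> "Domain":
        return cls(width_x=nx * um_per_px, width_y=ny * um_per_px)

    @property
    def widths(self) -> np.ndarray:
        return np.array([self.width_x, self.width_y])

    @property
    def area(self) -> float:
        return self.width_x * self.width_y

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Map positions into [0, width) per axis."""
        wrapped = np.mod(positions, self.widths)
        # guard against a==width after rounding of the modulo
        return np.where(wrapped >= self.widths, 0.0, wrapped)


@dataclass
class CellPopulation:
    """Cell centre positions (N, 2) in microns at a simulation time in hours."""

    positions: np.ndarray
    time: float = 0.0
    domain: Domain = field(default_factory=Domain)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        self.positions = self.domain.wrap(pos)

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True)
class SimEvent:
    """A single Gillespie event: 'move', 'proliferate' or 'die'."""

    kind: str
    cell_index: int
    time: float
    direction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("move", "proliferate", "die"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind != "die" and self.direction is None:
            raise ValueError(f"{self.kind} event requires a direction")


# ---------------------------------------------------------------------------
# elementary operations (reference, NumPy)
# ---------------------------------------------------------------------------


def crowding_kernel(r, sigma: float):
    """Gaussian interaction kernel w(r) = exp(-r^2 / 2 sigma^2).

    Truncated to exactly zero for r >= 3 sigma; values lie in [0, 1].
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(r, dtype=float)
    w = np.where(r < _CUTOFF_SIGMA * sigma, np.exp(-(r ** 2) / (2.0 * sigma ** 2)), 0.0)
    return w if w.ndim else float(w)


def min_image_displacement(a, b, domain: Domain) -> np.ndarray:
    """Shortest periodic displacement b - a; components in [-width/2, width/2]."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    w = domain.widths
    return d - w * np.round(d / w)


def _pairwise_min_image(pop: CellPopulation, i: int) -> np.ndarray:
    """Min-image displacements from cell i to every other cell, (N-1, 2)."""
    if not 0 <= i < pop.size:
        raise IndexError(f"cell index {i} out of range for population of {pop.size}")
    others = np.delete(pop.positions, i, axis=0)
    return min_image_displacement(pop.positions[i], others, pop.domain)


def local_crowding_sum(i: int, pop: CellPopulation, sigma: float) -> float:
    """Crowding sum of cell i: sum over j != i of w(|x_i - x_j|)."""
    if pop.size <= 1:
        if not 0 <= i < max(pop.size, 1):
            raise IndexError(f"cell index {i} out of range")
        return 0.0
    disp = _pairwise_min_image(pop, i)
    r = np.hypot(disp[:, 0], disp[:, 1])
    return float(np.sum(crowding_kernel(r, sigma)))


def movement_rate(i: int, pop: CellPopulation, params: ModelParams) -> float:
    """Density-modulated movement rate M_i = max(0, m - gamma_m * C_i)."""
    c = local_crowding_sum(i, pop, params.sigma)
    return max(0.0, params.m - params.gamma_m * c)


def proliferation_rate(i: int, pop: CellPopulation, params: ModelParams) -> float:
    """Density-modulated proliferation rate P_i = max(0, p - gamma_p * C_i)."""
    c = local_crowding_sum(i, pop, params.sigma)
    return max(0.0, params.p - params.gamma_p * c)


def bias_vector(i: int, pop: CellPopulation, params: ModelParams) -> np.ndarray:
    """Negative gradient of the crowding potential at cell i's position.

    B(x) = sum_j gamma_b w(|x - x_j|); the self term has zero gradient at the
    cell's own centre, so the sum runs over j != i.  Points away from local
    crowding (down the density gradient).
    """
    if pop.size <= 1:
        if not 0 <= i < max(pop.size, 1):
            raise IndexError(f"cell index {i} out of range")
        return np.zeros(2)
    sigma = params.sigma
    disp = _pairwise_min_image(pop, i)  # x_j - x_i
    r = np.hypot(disp[:, 0], disp[:, 1])
    w = crowding_kernel(r, sigma)
    # -grad of gamma_b * exp(-r^2/2s^2) wrt x_i is gamma_b * w * (x_i - x_j)/s^2
    coef = params.gamma_b * w / sigma ** 2
    return -(coef[:, None] * disp).sum(axis=0)


def sample_direction(bias: np.ndarray, rng: np.random.Generator) -> float:
    """Draw a movement angle in [0, 2 pi).

    von Mises with mean arg(bias) and concentration |bias|; uniform when the
    bias vanishes.
    """
    bx, by = float(bias[0]), float(bias[1])
    kappa = math.hypot(bx, by)
    if not math.isfinite(kappa):
        raise ValueError("bias vector must be finite")
    if kappa == 0.0:
        return float(rng.uniform(0.0, 2.0 * math.pi))
    ang = float(rng.vonmises(math.atan2(by, bx), kappa))
    return ang % (2.0 * math.pi)


def apply_event(pop: CellPopulation, event: SimEvent,
                params: ModelParams) -> CellPopulation:
    """Return the population after one event (functional update)."""
    n = pop.size
    if not 0 <= event.cell_index < n:
        raise IndexError(f"event cell index {event.cell_index} is stale (N={n})")
    pos = pop.positions
    if event.kind == "move":
        step = params.phi * np.array(
            [math.cos(event.direction), math.sin(event.direction)]
        )
        new = pos.copy()
        new[event.cell_index] = pos[event.cell_index] + step
    elif event.kind == "proliferate":
        step = params.phi * np.array(
            [math.cos(event.direction), math.sin(event.direction)]
        )
        daughter = pos[event.cell_index] + step
        new = np.vstack([pos, daughter])
    else:  # die
        new = np.delete(pos, event.cell_index, axis=0)
    return CellPopulation(new, time=event.time, domain=pop.domain)


# ---------------------------------------------------------------------------
# fast Gillespie engine (numba)
# ---------------------------------------------------------------------------
#
# State layout: dense arrays of the first ``n`` live cells.  A uniform grid
# with cell size >= 3 sigma stores, per grid cell, a compact fixed-capacity
# array of the particle indices it contains, plus a precomputed list of the
# (up to 9) periodic neighbour grid cells, so every interaction query is a
# handful of contiguous reads.  Per-cell movement/proliferation rates are
# kept in arrays with 64-cell block partial sums for proportional event
# selection; block sums are refreshed periodically to shed float drift from
# the incremental +/- updates.

_BLK = 32


@njit(cache=True, inline="always", fastmath=True)
def _set_rates(i, ci, m, p, gm, gp, crowd, M, P, bM, bP):
    """Refresh cell i's rates from its crowding sum; returns the change in
    (sum of movement rates, sum of proliferation rates)."""
    crowd[i] = ci
    nM = m - gm * ci
    if nM < 0.0:
        nM = 0.0
    nP = p - gp * ci
    if nP < 0.0:
        nP = 0.0
    b = i // _BLK
    dM = nM - M[i]
    dP = nP - P[i]
    bM[b] += dM
    bP[b] += dP
    M[i] = nM
    P[i] = nP
    return dM, dP


@njit(cache=True, inline="always", fastmath=True)
def _pick(u, blk, vals, n):
    nb = (n + _BLK - 1) // _BLK
    b = 0
    for bb in range(nb):
        b = bb
        if u < blk[bb]:
            break
        u -= blk[bb]
    lo = b * _BLK
    hi = lo + _BLK
    if hi > n:
        hi = n
    last = -1
    for i in range(lo, hi):
        v = vals[i]
        if v > 0.0:
            last = i
            if u < v:
                return i
            u -= v
    if last >= 0:
        return last
    for i in range(n):
        if vals[i] > 0.0:
            return i
    return 0


@njit(cache=True, inline="always", fastmath=True)
def _sample_unit_direction(bx, by):
    """Unit step vector with direction ~ vonMises(arg(b), |b|).

    Best-Fisher rejection sampling (the same algorithm behind numpy's
    vonmises), specialised to return (cos theta, sin theta) directly so the
    caller never takes an atan2/acos/cos/sin round-trip.  |b| = 0 gives a
    uniform direction (Marsaglia polar draw).
    """
    kappa = math.sqrt(bx * bx + by * by)
    # below ~2e-8 the Best-Fisher parameter r - sqrt(2r) ~ kappa^2 underflows
    # to exactly zero; at 1e-6 the distribution is uniform to ~1e-6 anyway
    if kappa < 1e-6:
        while True:
            vx = 2.0 * np.random.random() - 1.0
            vy = 2.0 * np.random.random() - 1.0
            s2 = vx * vx + vy * vy
            if 0.0 < s2 <= 1.0:
                inv = 1.0 / s2
                return (vx * vx - vy * vy) * inv, 2.0 * vx * vy * inv
    r = 1.0 + math.sqrt(1.0 + 4.0 * kappa * kappa)
    rho = (r - math.sqrt(2.0 * r)) / (2.0 * kappa)
    sv = (1.0 + rho * rho) / (2.0 * rho)
    while True:
        Z = math.cos(math.pi * np.random.random())
        denom = sv + Z
        if denom <= 0.0:  # only approachable in the kappa -> inf limit
            continue
        W = (1.0 + sv * Z) / denom
        Y = kappa * (sv - W)
        V = np.random.random()
        if Y * (2.0 - Y) - V >= 0.0:
            break
        if V <= 0.0:  # log(Y/V) -> +inf: accept (V = 0 has measure zero)
            break
        if Y > 0.0 and math.log(Y / V) + 1.0 - Y >= 0.0:
            break
    # W = cos(theta - mu); rotate by mu = arg(b) with a random reflection
    cmu = bx / kappa
    smu = by / kappa
    sind = math.sqrt(max(0.0, 1.0 - W * W))
    if np.random.random() < 0.5:
        sind = -sind
    return cmu * W - smu * sind, smu * W + cmu * sind


@njit(cache=True, fastmath=True)
def _build_grid_neighbours(gx, gy):
    """Periodic 3x3 neighbourhood of every grid cell, without double visits
    when an axis has fewer than 3 cells."""
    ncell = gx * gy
    nbr = np.empty((ncell, 9), np.int32)
    nnbr = np.empty(ncell, np.int32)
    if gx >= 3:
        offx = np.array([-1, 0, 1], np.int64)
    elif gx == 2:
        offx = np.array([0, 1], np.int64)
    else:
        offx = np.array([0], np.int64)
    if gy >= 3:
        offy = np.array([-1, 0, 1], np.int64)
    elif gy == 2:
        offy = np.array([0, 1], np.int64)
    else:
        offy = np.array([0], np.int64)
    for cy in range(gy):
        for cx in range(gx):
            c = cy * gx + cx
            q = 0
            for oy in offy:
                for ox in offx:
                    nbr[c, q] = ((cy + oy) % gy) * gx + ((cx + ox) % gx)
                    q += 1
            nnbr[c] = q
    return nbr, nnbr


@njit(cache=True, fastmath=True)
def _gillespie(xs, ys, n0, t0, t_end,
               m, p, d, gm, gp, gb, sigma, phi,
               Lx, Ly, seed, slots):
    """Exact Gillespie simulation; returns (n_final, flag, n_events).

    xs/ys are capacity-sized working arrays holding the initial positions in
    their first n0 slots; they are updated in place.  flag: 0 ok, 1 particle
    capacity exceeded, 2 non-finite rates, 3 grid-cell capacity exceeded.
    """
    np.random.seed(seed)
    cap = xs.shape[0]
    rcut = _CUTOFF_SIGMA * sigma
    rcut2 = rcut * rcut
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    invs2 = 1.0 / (sigma * sigma)
    hx = 0.5 * Lx
    hy = 0.5 * Ly

    gx = max(1, int(Lx / rcut))
    gy = max(1, int(Ly / rcut))
    inv_cwx = gx / Lx
    inv_cwy = gy / Ly
    ncell = gx * gy
    nbr, nnbr = _build_grid_neighbours(gx, gy)

    gcnt = np.zeros(ncell, np.int32)
    gitems = np.empty((ncell, slots), np.int32)
    cellof = np.zeros(cap, np.int32)

    crowd = np.zeros(cap)
    M = np.zeros(cap)
    P = np.zeros(cap)
    nblk = (cap + _BLK - 1) // _BLK
    bM = np.zeros(nblk)
    bP = np.zeros(nblk)
    sM = 0.0
    sP = 0.0

    n = n0
    for i in range(n):
        cx = min(int(xs[i] * inv_cwx), gx - 1)
        cy = min(int(ys[i] * inv_cwy), gy - 1)
        c = cy * gx + cx
        k = gcnt[c]
        if k >= slots:
            return n, 3, 0
        gitems[c, k] = i
        gcnt[c] = k + 1
        cellof[i] = c

    # initial crowding sums via the grid
    for i in range(n):
        xi = xs[i]
        yi = ys[i]
        c = cellof[i]
        ci = 0.0
        for q in range(nnbr[c]):
            cc = nbr[c, q]
            for k in range(gcnt[cc]):
                j = gitems[cc, k]
                if j == i:
                    continue
                dx = xi - xs[j]
                dx += Lx * ((dx < -hx) - (dx > hx))
                dy = yi - ys[j]
                dy += Ly * ((dy < -hy) - (dy > hy))
                r2 = dx * dx + dy * dy
                if r2 < rcut2:
                    ci += math.exp(-r2 * inv2s2)
        dM, dP = _set_rates(i, ci, m, p, gm, gp, crowd, M, P, bM, bP)
        sM += dM
        sP += dP

    # scratch neighbour list for the event updates; wcache[j] holds cell j's
    # kernel weight against the mover's old position during a move update
    nb_idx = np.empty(9 * slots, np.int64)
    nb_w = np.empty(9 * slots)
    wcache = np.zeros(cap)

    t = t0
    events = 0
    refresh = 0
    while True:
        R = sM + sP + n * d
        if not np.isfinite(R):
            return n, 2, events
        if R <= 1e-14:
            break
        t += np.random.exponential(1.0 / R)
        if t > t_end:
            break
        events += 1
        refresh += 1
        if refresh >= 16384:
            # shed float drift in the incremental block sums
            refresh = 0
            sM = 0.0
            sP = 0.0
            for b in range(nblk):
                bM[b] = 0.0
                bP[b] = 0.0
            for i in range(n):
                bM[i // _BLK] += M[i]
                bP[i // _BLK] += P[i]
                sM += M[i]
                sP += P[i]
            R = sM + sP + n * d

        u = np.random.random() * R
        if u < sM:
            i = _pick(u, bM, M, n)
            kind = 0
        elif u < sM + sP:
            i = _pick(u - sM, bP, P, n)
            kind = 1
        else:
            i = int(np.random.random() * n)
            if i >= n:
                i = n - 1
            kind = 2

        xi = xs[i]
        yi = ys[i]
        ctr = cellof[i]
        # neighbours of i at its current position, with kernel weights
        nn = 0
        bx = 0.0
        by = 0.0
        for q in range(nnbr[ctr]):
            cc = nbr[ctr, q]
            for k in range(gcnt[cc]):
                j = gitems[cc, k]
                if j == i:
                    continue
                dx = xi - xs[j]
                dx += Lx * ((dx < -hx) - (dx > hx))
                dy = yi - ys[j]
                dy += Ly * ((dy < -hy) - (dy > hy))
                r2 = dx * dx + dy * dy
                if r2 < rcut2:
                    w = math.exp(-r2 * inv2s2)
                    nb_idx[nn] = j
                    nb_w[nn] = w
                    nn += 1
                    bx += w * dx
                    by += w * dy

        if kind == 2:
            # death: neighbours lose i's kernel contribution
            for k in range(nn):
                j = nb_idx[k]
                dM, dP = _set_rates(j, crowd[j] - nb_w[k], m, p, gm, gp,
                                    crowd, M, P, bM, bP)
                sM += dM
                sP += dP
            b = i // _BLK
            bM[b] -= M[i]
            bP[b] -= P[i]
            sM -= M[i]
            sP -= P[i]
            M[i] = 0.0
            P[i] = 0.0
            cnt = gcnt[ctr]
            for k in range(cnt):
                if gitems[ctr, k] == i:
                    gitems[ctr, k] = gitems[ctr, cnt - 1]
                    gcnt[ctr] = cnt - 1
                    break
            jlast = n - 1
            if i != jlast:
                # keep the live-cell arrays dense: move the last cell into slot i
                cl = cellof[jlast]
                cnt = gcnt[cl]
                for k in range(cnt):
                    if gitems[cl, k] == jlast:
                        gitems[cl, k] = i
                        break
                cellof[i] = cl
                xs[i] = xs[jlast]
                ys[i] = ys[jlast]
                crowd[i] = crowd[jlast]
                bi = i // _BLK
                bl = jlast // _BLK
                bM[bi] += M[jlast]
                bP[bi] += P[jlast]
                bM[bl] -= M[jlast]
                bP[bl] -= P[jlast]
                M[i] = M[jlast]
                P[i] = P[jlast]
                M[jlast] = 0.0
                P[jlast] = 0.0
            n -= 1
            continue

        # move or proliferate: sample a step direction from the bias
        ux, uy = _sample_unit_direction(gb * invs2 * bx, gb * invs2 * by)
        px = xi + phi * ux
        py = yi + phi * uy
        px = px % Lx
        if px >= Lx or px < 0.0:
            px = 0.0
        py = py % Ly
        if py >= Ly or py < 0.0:
            py = 0.0

        if kind == 0:
            # move: take i out of the grid; its old-position contributions are
            # retired below, merged with the new-position pass where possible
            cnt = gcnt[ctr]
            for k in range(cnt):
                if gitems[ctr, k] == i:
                    gitems[ctr, k] = gitems[ctr, cnt - 1]
                    gcnt[ctr] = cnt - 1
                    break
            for q2 in range(nn):
                wcache[nb_idx[q2]] = nb_w[q2]
            target = i
        else:
            # proliferate: daughter occupies the next free slot
            if n >= cap:
                return n, 1, events
            target = n

        # ... and insert the moved cell / daughter at the new position
        ncx = min(int(px * inv_cwx), gx - 1)
        ncy = min(int(py * inv_cwy), gy - 1)
        cnew = ncy * gx + ncx
        ci = 0.0
        for q in range(nnbr[cnew]):
            cc = nbr[cnew, q]
            for k in range(gcnt[cc]):
                j = gitems[cc, k]
                dx = px - xs[j]
                dx += Lx * ((dx < -hx) - (dx > hx))
                dy = py - ys[j]
                dy += Ly * ((dy < -hy) - (dy > hy))
                r2 = dx * dx + dy * dy
                if r2 < rcut2:
                    w = math.exp(-r2 * inv2s2)
                    ci += w
                    wold = 0.0
                    if kind == 0:
                        # merge with the retraction of i's old contribution
                        wold = wcache[j]
                        wcache[j] = 0.0
                    dM, dP = _set_rates(j, crowd[j] + w - wold, m, p, gm, gp,
                                        crowd, M, P, bM, bP)
                    sM += dM
                    sP += dP
        if kind == 0:
            # old neighbours now out of range of the new position
            for q2 in range(nn):
                j = nb_idx[q2]
                w = wcache[j]
                if w > 0.0:
                    wcache[j] = 0.0
                    dM, dP = _set_rates(j, crowd[j] - w, m, p, gm, gp,
                                        crowd, M, P, bM, bP)
                    sM += dM
                    sP += dP
        xs[target] = px
        ys[target] = py
        dM, dP = _set_rates(target, ci, m, p, gm, gp, crowd, M, P, bM, bP)
        sM += dM
        sP += dP
        k = gcnt[cnew]
        if k >= slots:
            return n, 3, events
        gitems[cnew, k] = target
        gcnt[cnew] = k + 1
        cellof[target] = cnew
        if kind == 1:
            n += 1

    return n, 0, events


def _simulate_arrays(x0: np.ndarray, y0: np.ndarray, t0: float, t_end: float,
                     params: ModelParams, domain: Domain,
                     seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Array-level entry point to the fast engine (used by the inference loop)."""
    n0 = x0.shape[0]
    if n0 == 0:
        return x0.copy(), y0.copy()
    cap = max(1024, int(n0 * 3.5) + 64)
    slots = 24
    while True:
        xs = np.empty(cap)
        ys = np.empty(cap)
        xs[:n0] = x0
        ys[:n0] = y0
        n, flag, _ = _gillespie(
            xs, ys, n0, t0, t_end,
            params.m, params.p, params.d,
            params.gamma_m, params.gamma_p, params.gamma_b,
            params.sigma, params.phi,
            domain.width_x, domain.width_y, seed, slots,
        )
        if flag == 2:
            raise FloatingPointError("non-finite total rate during simulation")
        if flag == 0:
            return xs[:n].copy(), ys[:n].copy()
        if flag == 1:
            cap *= 2  # population outgrew capacity; rerun with more head-room
        else:
            slots *= 2  # locally dense clump outgrew a grid cell


def _simulate_reference(initial: CellPopulation, params: ModelParams,
                        t_end: float, rng: np.random.Generator,
                        record_events: bool = False):
    """Plain-Python Gillespie with full rate recomputation after each event.

    O(N^2) per event; an independent oracle for the fast engine on small
    populations.
    """
    pop = CellPopulation(initial.positions.copy(), initial.time, initial.domain)
    events: List[SimEvent] = []
    t = pop.time
    while True:
        n = pop.size
        if n == 0:
            break
        mrates = np.array([movement_rate(i, pop, params) for i in range(n)])
        prates = np.array([proliferation_rate(i, pop, params) for i in range(n)])
        total = mrates.sum() + prates.sum() + n * params.d
        if not np.isfinite(total):
            raise FloatingPointError("non-finite total rate during simulation")
        if total <= 1e-14:
            break
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        u = rng.uniform(0.0, total)
        if u < mrates.sum():
            i = int(np.searchsorted(np.cumsum(mrates), u, side="right"))
            kind = "move"
        elif u < mrates.sum() + prates.sum():
            i = int(np.searchsorted(np.cumsum(prates), u - mrates.sum(),
                                    side="right"))
            kind = "proliferate"
        else:
            i = int(rng.integers(n))
            kind = "die"
        i = min(i, n - 1)
        direction = None
        if kind != "die":
            direction = sample_direction(bias_vector(i, pop, params), rng)
        event = SimEvent(kind, i, t, direction)
        pop = apply_event(pop, event, params)
        if record_events:
            events.append(event)
    pop = CellPopulation(pop.positions, time=t_end, domain=pop.domain)
    return (pop, events) if record_events else pop


def simulate(initial: CellPopulation, params: ModelParams, t_end: float,
             rng=None, engine: str = "fast"):
    """Simulate the model exactly from ``initial`` to time ``t_end``.

    Parameters
    ----------
    initial : CellPopulation
        Starting configuration (its ``time`` is the start time).
    params : ModelParams
    t_end : float
        End time in hours; must exceed the start time.
    rng : numpy Generator or int seed, optional
        Source of randomness; trajectories are reproducible given the seed.
    engine : {"fast", "reference"}
        "fast" uses the compiled spatial-hash engine; "reference" the
        plain-Python full-recompute engine.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial population time")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if engine == "reference":
        return _simulate_reference(initial, params, t_end, rng)
    if engine != "fast":
        raise ValueError(f"unknown engine {engine!r}")
    if initial.size == 0:
        return CellPopulation(initial.positions.copy(), t_end, initial.domain)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    x, y = _simulate_arrays(
        np.ascontiguousarray(initial.positions[:, 0]),
        np.ascontiguousarray(initial.positions[:, 1]),
        initial.time, t_end, params, initial.domain, seed,
    )
    return CellPopulation(np.column_stack([x, y]), t_end, initial.domain)
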