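"""Trajectory and landscape simulators for the Monte Carlo study.

Three movement models generate discretized trajectories biased toward a
fixed target:

* ``discrete_choice`` — on a categorical habitat raster, the walker
  moves to one of the patch-wise nearest pixels of habitats 2 and 3
  lying beyond a minimum distance, chosen with probability proportional
  to exp(kappa1 cos(y_j - y_prev) + kappa2 cos(y_j - psi));
* ``consensus`` — step angles drawn from vM(mu_t, kappa * l_t), the
  consensus BCRW, with fixed step length;
* ``angular`` — step angles are mu_t plus vM(0, error_kappa) noise.

The standard experiment places two independent walkers at random starts
in the northwest and southeast quarter-quadrants of a 1024 x 1024 map,
biased toward the center pixel, observed for 61 steps each, which gives
120 usable likelihood records.

Coordinates are continuous planar x (east) / y (north); rasters put row
0 at the north edge with pixel centers at half-integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numpy as np
from scipy import ndimage

from .circular import mean_direction, sample_von_mises, wrap_angle
from .estimators import StepSeries

__all__ = [
    "Landscape",
    "SimScenario",
    "Trajectory",
    "StrandedWalkerError",
    "simulate_landscape",
    "simulate_discrete_choice",
    "simulate_consensus",
    "simulate_angular",
    "simulate_pixel_trail",
    "run_two_animal_replicate",
    "default_scenarios",
    "ERROR_KAPPA_BY_PAIR",
]

#: error concentrations of the angular simulation model for the three
#: canonical (kappa1, kappa2) pairs
ERROR_KAPPA_BY_PAIR = {(2.0, 2.0): 3.0, (2.0, 0.5): 2.0, (0.5, 0.5): 0.75}


class StrandedWalkerError(RuntimeError):
    """No candidate pixel exists beyond the minimum distance."""


_FILTER_CACHE: dict = {}


def _exp_filter(rows, cols, corr_range):
    """Square-root spectrum of the torus-wrapped exponential kernel (cached)."""
    key = (rows, cols, float(corr_range))
    if key not in _FILTER_CACHE:
        dr = np.minimum(np.arange(rows), rows - np.arange(rows))
        dc = np.minimum(np.arange(cols), cols - np.arange(cols))
        dist = np.hypot(dr[:, None], dc[None, :])
        spec = np.clip(np.fft.fft2(np.exp(-dist / corr_range)).real, 0.0, None)
        _FILTER_CACHE.clear()  # keep at most one 1024x1024 filter in memory
        _FILTER_CACHE[key] = np.sqrt(spec)
    return _FILTER_CACHE[key]


@dataclass
class Landscape:
    """Categorical habitat raster with codes {1, 2, 3}.

    Pixel (row, col) has its center at x = (col + 1/2) * pixel_size,
    y = (rows - row - 1/2) * pixel_size (row 0 at the north edge).  The
    movement target is the center pixel.
    """

    grid: np.ndarray
    pixel_size: float = 1.0
    field: Optional[np.ndarray] = None  # latent Gaussian field, kept for diagnostics

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")

    @property
    def rows(self) -> int:
        return self.grid.shape[0]

    @property
    def cols(self) -> int:
        return self.grid.shape[1]

    @property
    def target_pixel(self) -> tuple[int, int]:
        return (self.rows // 2, self.cols // 2)

    def pixel_center(self, row, col) -> tuple:
        x = (np.asarray(col) + 0.5) * self.pixel_size
        y = (self.rows - np.asarray(row) - 0.5) * self.pixel_size
        return x, y

    @property
    def target_xy(self) -> tuple[float, float]:
        r, c = self.target_pixel
        x, y = self.pixel_center(r, c)
        return float(x), float(y)

    def proportions(self) -> dict[int, float]:
        vals, counts = np.unique(self.grid, return_counts=True)
        return {int(v): c / self.grid.size for v, c in zip(vals, counts)}

    @cached_property
    def _candidate_pool(self):
        """Habitat-2/3 pixel centers grouped into 8-connected patches.

        Returns (x, y, seg_starts): pixel centers concatenated in
        patch-major, row-major order, with ``seg_starts`` the first
        index of each patch segment.
        """
        xs, ys, starts = [], [], []
        offset = 0
        structure = np.ones((3, 3), dtype=int)
        for code in (2, 3):
            labels, n = ndimage.label(self.grid == code, structure=structure)
            if n == 0:
                raise ValueError(f"landscape lacks habitat {code}")
            order = np.argsort(labels.ravel(), kind="stable")
            flat = labels.ravel()[order]
            keep = flat > 0
            idx = order[keep]
            rows_, cols_ = np.unravel_index(idx, self.grid.shape)
            x, y = self.pixel_center(rows_, cols_)
            xs.append(x)
            ys.append(y)
            seg = np.flatnonzero(np.r_[True, np.diff(flat[keep]) != 0]) + offset
            starts.append(seg)
            offset += idx.size
        return np.concatenate(xs), np.concatenate(ys), np.concatenate(starts)


def simulate_landscape(
    rows: int,
    cols: int,
    proportions=(0.8, 0.1, 0.1),
    corr_range: float = 20.0,
    rng: Optional[np.random.Generator] = None,
    pixel_size: float = 1.0,
) -> Landscape:
    """Neutral habitat map from a thresholded Gaussian random field.

    A stationary Gaussian field with (torus-wrapped) exponential spatial
    correlation of the given range is simulated spectrally and cut at
    its empirical quantiles, so habitat code 1 occupies the lowest
    ``proportions[0]`` fraction of values, code 2 the next, code 3 the
    rest — exact up to integer pixel counts.  ``corr_range = 0`` gives a
    spatially independent field.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != 3 or np.any(proportions <= 0) or abs(proportions.sum() - 1) > 1e-9:
        raise ValueError("proportions must be three positive fractions summing to 1")
    if corr_range < 0:
        raise ValueError("corr_range must be >= 0")
    n = rows * cols
    counts = np.round(proportions * n).astype(int)
    counts[2] = n - counts[0] - counts[1]
    if np.any(counts < 1):
        raise ValueError("grid too small to host all three habitat codes")
    if rng is None:
        rng = np.random.default_rng()
    noise = rng.standard_normal((rows, cols))
    if corr_range == 0:
        fld = noise
    else:
        # spectral synthesis on the torus: filter white noise so the
        # field has (approximately) exponential correlation of the range
        fld = np.fft.ifft2(np.fft.fft2(noise) * _exp_filter(rows, cols, corr_range)).real
        fld /= max(fld.std(), 1e-300)
    order = np.argsort(fld.ravel(), kind="stable")
    codes = np.empty(n, dtype=np.int16)
    codes[order[: counts[0]]] = 1
    codes[order[counts[0] : counts[0] + counts[1]]] = 2
    codes[order[counts[0] + counts[1] :]] = 3
    return Landscape(grid=codes.reshape(rows, cols), pixel_size=pixel_size, field=fld)


@dataclass
class Trajectory:
    """Simulated path: positions plus the angles used to generate it."""

    animal_id: str
    positions: np.ndarray  # (T+1, 2) planar x/y
    y: np.ndarray  # (T,) step angles
    psi: np.ndarray  # (T,) target bearings at each step's origin
    d: np.ndarray  # (T,) step lengths

    def to_step_series(self) -> StepSeries:
        T = self.y.size
        return StepSeries(
            animal=np.repeat(self.animal_id, T),
            t=np.arange(T),
            y=self.y,
            psi1=self.psi,
            d=self.d,
        )


def _bearing(frm, to) -> float:
    dx, dy = to[0] - frm[0], to[1] - frm[1]
    if dx == 0 and dy == 0:
        return 0.0
    return math.atan2(dy, dx)


def _candidate_pixels(landscape: Landscape, pos, min_dist: float):
    """Patch-wise nearest habitat-2/3 pixel centers beyond ``min_dist``.

    Distance ties break to the lowest row-major pixel index within the
    patch (the stored order).
    """
    px, py, seg_starts = landscape._candidate_pool
    d2 = (px - pos[0]) ** 2 + (py - pos[1]) ** 2
    d2 = np.where(d2 > min_dist**2, d2, np.inf)
    mins = np.minimum.reduceat(d2, seg_starts)
    seg_len = np.diff(np.r_[seg_starts, d2.size])
    match = d2 == np.repeat(mins, seg_len)
    m_idx = np.flatnonzero(match)
    if m_idx.size == 0:
        raise StrandedWalkerError("no habitat-2/3 pixel beyond the minimum distance")
    seg_of = np.searchsorted(seg_starts, m_idx, side="right") - 1
    _, first = np.unique(seg_of, return_index=True)
    idx = m_idx[first]
    idx = idx[np.isfinite(d2[idx])]
    if idx.size == 0:
        raise StrandedWalkerError("no habitat-2/3 pixel beyond the minimum distance")
    return px[idx], py[idx], np.sqrt(d2[idx])


def discrete_choice_probabilities(bearings, y_prev, psi, kappa1, kappa2):
    """Softmax selection probabilities over candidate bearings."""
    lin = kappa1 * np.cos(bearings - y_prev) + kappa2 * np.cos(bearings - psi)
    lin -= lin.max()
    w = np.exp(lin)
    return w / w.sum()


def simulate_discrete_choice(
    landscape: Landscape,
    start: tuple[int, int],
    T: int,
    kappa1: float,
    kappa2: float,
    min_dist: float = 60.0,
    rng: Optional[np.random.Generator] = None,
    y0: Optional[float] = None,
    animal_id: str = "A1",
) -> Trajectory:
    """Discrete-choice walk on a habitat raster toward the center pixel.

    At each step the candidates are the nearest pixel of every
    8-connected habitat-2 and habitat-3 patch lying more than
    ``min_dist`` away; one is selected with softmax probabilities
    combining persistence and target attraction.  Step lengths vary
    (distance to the chosen pixel).
    """
    if rng is None:
        rng = np.random.default_rng()
    r0, c0 = start
    if not (0 <= r0 < landscape.rows and 0 <= c0 < landscape.cols):
        raise ValueError("start pixel outside the grid")
    x0, ycoord0 = landscape.pixel_center(r0, c0)
    pos = np.array([float(x0), float(ycoord0)])
    target = np.asarray(landscape.target_xy)
    y_prev = rng.uniform(-math.pi, math.pi) if y0 is None else y0
    positions = [pos.copy()]
    angles, psis, ds = [], [], []
    for _ in range(T):
        psi = _bearing(pos, target)
        cx, cy, cd = _candidate_pixels(landscape, pos, min_dist)
        bearings = np.arctan2(cy - pos[1], cx - pos[0])
        probs = discrete_choice_probabilities(bearings, y_prev, psi, kappa1, kappa2)
        k = rng.choice(probs.size, p=probs)
        y_t = wrap_angle(bearings[k])
        pos = np.array([cx[k], cy[k]])
        positions.append(pos.copy())
        angles.append(y_t)
        psis.append(wrap_angle(psi))
        ds.append(cd[k])
        y_prev = y_t
    return Trajectory(animal_id, np.array(positions), np.array(angles), np.array(psis), np.array(ds))


def _walk_continuous(
    T, step_len, start, target, y0, rng, animal_id, draw_angle
) -> Trajectory:
    pos = np.asarray(start, dtype=float).copy()
    target = np.asarray(target, dtype=float)
    positions = [pos.copy()]
    angles, psis, ds = [], [], []
    y_prev = None
    for t in range(T):
        psi = _bearing(pos, target)
        if t == 0:
            y_t = rng.uniform(-math.pi, math.pi) if y0 is None else wrap_angle(y0)
        else:
            y_t = draw_angle(y_prev, psi)
        pos = pos + step_len * np.array([math.cos(y_t), math.sin(y_t)])
        positions.append(pos.copy())
        angles.append(y_t)
        psis.append(wrap_angle(psi))
        ds.append(step_len)
        y_prev = y_t
    return Trajectory(animal_id, np.array(positions), np.array(angles), np.array(psis), np.array(ds))


def simulate_consensus(
    T: int,
    kappa: float,
    beta: float,
    step_len: float = 60.0,
    start=(0.0, 0.0),
    target=(0.0, 0.0),
    y0: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    animal_id: str = "A1",
) -> Trajectory:
    """Consensus-model walk: y_t ~ vM(mu_t, kappa * l_t), fixed step length."""
    if T < 2:
        raise ValueError("T must be >= 2")
    if rng is None:
        rng = np.random.default_rng()

    def draw(y_prev, psi):
        cv = mean_direction(y_prev, psi, beta)
        return float(sample_von_mises(cv.direction, kappa * cv.length, 1, rng)[0])

    return _walk_continuous(T, step_len, start, target, y0, rng, animal_id, draw)


def simulate_angular(
    T: int,
    beta: float,
    error_kappa: float,
    step_len: float = 60.0,
    start=(0.0, 0.0),
    target=(0.0, 0.0),
    y0: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    animal_id: str = "A1",
) -> Trajectory:
    """Angular-model walk: y_t = mu_t + vM(0, error_kappa) noise, wrapped."""
    if T < 2:
        raise ValueError("T must be >= 2")
    if rng is None:
        rng = np.random.default_rng()

    def draw(y_prev, psi):
        cv = mean_direction(y_prev, psi, beta)
        return wrap_angle(cv.direction + float(sample_von_mises(0.0, error_kappa, 1, rng)[0]))

    return _walk_continuous(T, step_len, start, target, y0, rng, animal_id, draw)


def simulate_pixel_trail(
    grid_shape: tuple[int, int],
    start: tuple[int, int],
    target_pixel: tuple[int, int],
    gap_pixels,
    n_steps: int,
    kappa1: float,
    kappa2: float,
    kappa3: float,
    rng: Optional[np.random.Generator] = None,
    pixel_size: float = 10.0,
):
    """Raster trail generated by discrete choice among 7 neighbor pixels.

    At each position the previously occupied pixel is excluded, leaving
    7 alternatives chosen with probability proportional to
    exp(kappa1 cos(y_j - y_prev) + kappa2 cos(y_j - psi1) +
    kappa3 cos(y_j - psi2)), psi1 the bearing to ``target_pixel`` and
    psi2 the bearing to the nearest of ``gap_pixels``.  Returns
    ``(path, targets)`` ready for :func:`movebias.ssf.trail_ssf_design`.
    """
    from .ssf import NEIGHBOR_BEARINGS, NEIGHBOR_OFFSETS, _pixel_bearing

    if rng is None:
        rng = np.random.default_rng()
    rows, cols = grid_shape
    gaps = np.atleast_2d(np.asarray(gap_pixels, dtype=float))
    cur = np.asarray(start, dtype=int)
    prev = None
    y_prev = rng.uniform(-math.pi, math.pi)
    path = [cur.copy()]
    psi1s, psi2s = [], []

    def bearings_from(px):
        p1 = _pixel_bearing(px, target_pixel, pixel_size)
        d2 = ((gaps - px) ** 2).sum(axis=1)
        nearest = gaps[int(np.argmin(d2))]
        p2 = _pixel_bearing(px, nearest, pixel_size)
        return p1, p2

    p1, p2 = bearings_from(cur)
    psi1s.append(p1)
    psi2s.append(p2)
    for _ in range(n_steps):
        neighbors = cur + NEIGHBOR_OFFSETS
        inside = (
            (neighbors[:, 0] >= 0)
            & (neighbors[:, 0] < rows)
            & (neighbors[:, 1] >= 0)
            & (neighbors[:, 1] < cols)
        )
        keep = inside if prev is None else inside & ~np.all(neighbors == prev, axis=1)
        alts = neighbors[keep]
        brg = NEIGHBOR_BEARINGS[keep]
        lin = (
            kappa1 * np.cos(brg - y_prev)
            + kappa2 * np.cos(brg - p1)
            + kappa3 * np.cos(brg - p2)
        )
        lin -= lin.max()
        w = np.exp(lin)
        k = rng.choice(w.size, p=w / w.sum())
        prev, cur = cur, alts[k]
        y_prev = brg[k]
        path.append(cur.copy())
        p1, p2 = bearings_from(cur)
        psi1s.append(p1)
        psi2s.append(p2)
    return np.array(path), {"psi1": np.array(psi1s), "psi2": np.array(psi2s)}


@dataclass
class SimScenario:
    """One Monte Carlo simulation condition.

    ``model`` is ``discrete_choice``, ``consensus`` or ``angular``;
    (kappa1, kappa2) are the persistence/bias concentrations, so the
    bias strength is beta = kappa2/kappa1.  The angular model needs an
    ``error_kappa``; if omitted it is looked up from the canonical
    pair-to-concentration mapping.  Defaults are the standard design:
    61 steps per animal, step length 60 map units, a 1024 x 1024
    landscape with habitat fractions (0.8, 0.1, 0.1).
    """

    model: str
    kappa1: float
    kappa2: float
    error_kappa: Optional[float] = None
    T: int = 61
    step_len: float = 60.0
    landscape_shape: tuple[int, int] = (1024, 1024)
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    corr_range: float = 20.0

    def __post_init__(self):
        if self.model not in ("discrete_choice", "consensus", "angular"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.model == "angular" and self.error_kappa is None:
            self.error_kappa = ERROR_KAPPA_BY_PAIR.get((self.kappa1, self.kappa2))
            if self.error_kappa is None:
                raise ValueError("error_kappa required for the angular model")

    @property
    def beta(self) -> float:
        return self.kappa2 / self.kappa1

    @property
    def label(self) -> str:
        return f"{self.model}:{self.kappa1:g},{self.kappa2:g}"


def default_scenarios() -> list[SimScenario]:
    """The nine standard conditions: three models x three (kappa1, kappa2) pairs."""
    pairs = [(2.0, 2.0), (2.0, 0.5), (0.5, 0.5)]
    return [
        SimScenario(model=m, kappa1=k1, kappa2=k2)
        for m in ("discrete_choice", "consensus", "angular")
        for (k1, k2) in pairs
    ]


def _corner_starts(rows, cols, rng):
    """Random starts in the NW and SE quarter-quadrant pixel blocks."""
    nw = (int(rng.integers(0, rows // 2)), int(rng.integers(0, cols // 2)))
    se = (int(rng.integers(rows // 2, rows)), int(rng.integers(cols // 2, cols)))
    return nw, se


def run_two_animal_replicate(
    scenario: SimScenario,
    landscape: Optional[Landscape] = None,
    rng: Optional[np.random.Generator] = None,
) -> StepSeries:
    """One replicate of the standard two-animal experiment.

    Two independent walkers start at random pixels of the northwest and
    southeast quarter-quadrants and head for the landscape center; the
    pooled series of 2 x T steps carries 2 x (T - 1) usable likelihood
    records (120 for T = 61).  A landscape is required (and only used)
    for the discrete-choice model.
    """
    if rng is None:
        rng = np.random.default_rng()
    if scenario.model == "discrete_choice":
        if landscape is None:
            raise ValueError("discrete_choice requires a landscape")
        rows, cols = landscape.rows, landscape.cols
        target = landscape.target_xy
    else:
        rows, cols = scenario.landscape_shape
        target = ((cols // 2 + 0.5), (rows - rows // 2 - 0.5))
    starts = _corner_starts(rows, cols, rng)
    seeds = rng.integers(0, 2**31, size=2)
    trajs = []
    for aid, start_px, seed in zip(("A1", "A2"), starts, seeds):
        arng = np.random.default_rng(int(seed))
        if scenario.model == "discrete_choice":
            tr = simulate_discrete_choice(
                landscape,
                start_px,
                scenario.T,
                scenario.kappa1,
                scenario.kappa2,
                min_dist=60.0 * landscape.pixel_size,
                rng=arng,
                animal_id=aid,
            )
        else:
            x0 = start_px[1] + 0.5
            ycoord0 = rows - start_px[0] - 0.5
            if scenario.model == "consensus":
                tr = simulate_consensus(
                    scenario.T,
                    kappa=scenario.kappa1,
                    beta=scenario.beta,
                    step_len=scenario.step_len,
                    start=(x0, ycoord0),
                    target=target,
                    rng=arng,
                    animal_id=aid,
                )
            else:
                tr = simulate_angular(
                    scenario.T,
                    beta=scenario.beta,
                    error_kappa=scenario.error_kappa,
                    step_len=scenario.step_len,
                    start=(x0, ycoord0),
                    target=target,
                    rng=arng,
                    animal_id=aid,
                )
        trajs.append(tr.to_step_series())
    return StepSeries.concat(trajs)
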