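"""Radial distribution functions, potentials of mean force, and feature extraction.

This is the tomogram-analysis pipeline applied to 3D centroid sets: an
edge-corrected g(r) estimator, the Boltzmann inversion W(r) = -kT ln g(r)
(stored in kT, so W = -ln g), extraction of the well/barrier geometry that
summarizes each PMF, and number-concentration bookkeeping in particles/m^3.

Edge correction: on fully periodic boxes the estimator uses minimum-image
distances and exact spherical-shell volumes.  On slab geometries (hard walls
on one axis) the per-particle shell volume is cut analytically by the two
wall planes (exact spherical-cap geometry).  With hard walls on two or three
axes the shell-in-box fraction is evaluated by a deterministic
Fibonacci-sphere quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import Environment
from .simulate import Box, ParticleConfiguration

__all__ = [
    "RDFCurve",
    "PMFCurve",
    "PMFFeatures",
    "compute_rdf",
    "average_rdf",
    "rdf_to_pmf",
    "contact_value",
    "pmf_features",
    "number_concentration",
]


# ---------------------------------------------------------------------------
# curve containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RDFCurve:
    """Binned pair-correlation function on half-open bins [r_i, r_{i+1})."""

    bin_edges: np.ndarray          # nm, length nbins+1
    g: np.ndarray                  # dimensionless, length nbins
    pair_counts: np.ndarray        # integer pair counts per bin
    n_particles: int
    number_concentration: float    # particles per m^3

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        object.__setattr__(self, "pair_counts", np.asarray(self.pair_counts))
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(self.pair_counts < 0):
            raise ValueError("pair counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PMFCurve:
    """Potential of mean force W(r) in kT; +inf marks bins where g = 0."""

    bin_centers: np.ndarray
    W: np.ndarray
    temperature_K: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "W", np.asarray(self.W, dtype=float))

    def g(self) -> np.ndarray:
        """Invert back to g(r) = exp(-W); the +inf sentinel maps to g = 0."""
        with np.errstate(over="ignore"):
            return np.exp(-self.W)


@dataclass(frozen=True)
class PMFFeatures:
    """Well/barrier geometry of a PMF: positions in nm, heights in kT.

    ``has_well`` is False (and the numeric fields None) for monotone or
    purely repulsive profiles — absent features are flagged, never
    fabricated.
    """

    has_well: bool
    well_position: float | None = None
    well_depth: float | None = None
    barrier_position: float | None = None
    barrier_height: float | None = None
    barrier_minus_well: float | None = None
    secondary_minimum_position: float | None = None


# ---------------------------------------------------------------------------
# RDF estimator
# ---------------------------------------------------------------------------

def _bin_pair_counts(positions: np.ndarray, box: Box, edges: np.ndarray,
                     chunk: int = 256) -> np.ndarray:
    """Histogram of unordered minimum-image pair distances on half-open bins."""
    n = len(positions)
    nbins = len(edges) - 1
    counts = np.zeros(nbins, dtype=np.int64)
    L = np.asarray(box.lengths)
    periodic = np.asarray(box.periodic)
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        block = positions[start:stop]          # (B, 3)
        delta = positions[None, :, :] - block[:, None, :]   # (B, N, 3)
        for k in range(3):
            if periodic[k]:
                delta[..., k] -= L[k] * np.round(delta[..., k] / L[k])
        d = np.sqrt(np.einsum("bnk,bnk->bn", delta, delta))
        # keep j > i only
        jj = np.arange(n)[None, :]
        ii = np.arange(start, stop)[:, None]
        d = d[jj > ii]
        idx = np.searchsorted(edges, d, side="right") - 1
        valid = (idx >= 0) & (idx < nbins)
        counts += np.bincount(idx[valid], minlength=nbins)
    return counts


def _cap_volume(r: float | np.ndarray, d: np.ndarray) -> np.ndarray:
    """Volume of the spherical cap of a radius-r sphere beyond a plane at distance d."""
    h = np.clip(r - d, 0.0, 2.0 * r)  # cap height
    return np.pi * h * h * (3.0 * r - h) / 3.0


def _sphere_in_slab_volume(r: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Volume of a radius-r sphere (per center) inside the slab lo <= axis <= hi.

    ``lo`` and ``hi`` are signed distances from each sphere center to the two
    wall planes (lo towards the lower wall, hi towards the upper one); both
    are non-negative for centers inside the slab.
    """
    v = np.full_like(lo, 4.0 * np.pi * r**3 / 3.0, dtype=float)
    v -= _cap_volume(r, lo)
    v -= _cap_volume(r, hi)
    return v


def _fibonacci_directions(m: int = 2000) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(m) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / m
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def _expected_pairs(positions: np.ndarray, box: Box, edges: np.ndarray) -> np.ndarray:
    """Ideal-gas expectation of unordered pair counts per bin, edge-corrected."""
    n = len(positions)
    V = box.volume_nm3
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    hard_axes = [k for k in range(3) if not box.periodic[k]]
    if not hard_axes:
        return n * (n - 1) / 2.0 * shell / V
    if len(hard_axes) == 1:
        k = hard_axes[0]
        z = positions[:, k]
        lo = z
        hi = box.lengths[k] - z
        acc = np.zeros(len(edges) - 1)
        for b in range(len(edges) - 1):
            v_in = (_sphere_in_slab_volume(edges[b + 1], lo, hi)
                    - _sphere_in_slab_volume(edges[b], lo, hi))
            acc[b] = np.sum(v_in)
        return (n - 1) / (2.0 * V) * acc
    # 2-3 hard-wall axes: quadrature over shell directions at bin centers
    dirs = _fibonacci_directions()
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = np.zeros(len(centers))
    L = np.asarray(box.lengths)
    for b, rc in enumerate(centers):
        pts = positions[:, None, :] + rc * dirs[None, :, :]   # (N, M, 3)
        inside = np.ones(pts.shape[:2], dtype=bool)
        for k in hard_axes:
            inside &= (pts[..., k] >= 0.0) & (pts[..., k] <= L[k])
        frac = inside.mean(axis=1)
        acc[b] = np.sum(frac) * shell[b]
    return (n - 1) / (2.0 * V) * acc


def compute_rdf(config: ParticleConfiguration, bin_width: float,
                r_max: float) -> RDFCurve:
    """Edge-corrected radial distribution function from a centroid set.

    g(r) is the observed unordered pair count per half-open bin divided by
    the count expected for an ideal gas at the same number concentration.
    On periodic axes distances use the minimum image and ``r_max`` must not
    exceed half the smallest periodic edge.
    """
    n = config.n_particles
    if n < 2:
        raise ValueError("RDF needs at least 2 particles")
    if bin_width <= 0 or r_max <= bin_width:
        raise ValueError("need 0 < bin_width < r_max")
    per_edges = [config.box.lengths[k] for k in range(3) if config.box.periodic[k]]
    if per_edges and r_max > min(per_edges) / 2.0 + 1e-12:
        raise ValueError(
            f"r_max {r_max} nm exceeds half the smallest periodic edge "
            f"({min(per_edges) / 2:.3f} nm)")
    nbins = int(np.ceil(r_max / bin_width - 1e-12))
    edges = np.arange(nbins + 1) * bin_width
    counts = _bin_pair_counts(config.positions, config.box, edges)
    expected = _expected_pairs(config.positions, config.box, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFCurve(bin_edges=edges, g=g, pair_counts=counts, n_particles=n,
                    number_concentration=n / config.box.volume_m3)


def average_rdf(frames: list[ParticleConfiguration], bin_width: float,
                r_max: float) -> RDFCurve:
    """Pooled g(r) over sampled frames: summed counts over summed expectations.

    The frames must share box and particle count (a single MC trajectory).
    """
    if not frames:
        raise ValueError("no frames to average")
    n = frames[0].n_particles
    box = frames[0].box
    for f in frames[1:]:
        if f.n_particles != n or f.box != box:
            raise ValueError("frames must share box and particle count")
    first = compute_rdf(frames[0], bin_width, r_max)
    edges = first.bin_edges
    counts = first.pair_counts.astype(np.int64).copy()
    expected = _expected_pairs(frames[0].positions, box, edges)
    for f in frames[1:]:
        counts += _bin_pair_counts(f.positions, box, edges)
        expected += _expected_pairs(f.positions, box, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFCurve(bin_edges=edges, g=g, pair_counts=counts, n_particles=n,
                    number_concentration=n / box.volume_m3)


# ---------------------------------------------------------------------------
# PMF
# ---------------------------------------------------------------------------

def rdf_to_pmf(rdf: RDFCurve, env: Environment | None = None) -> PMFCurve:
    """Boltzmann inversion W(r) = -ln g(r) in kT; g = 0 maps to +inf."""
    env = env or Environment()
    with np.errstate(divide="ignore"):
        W = np.where(rdf.g > 0, -np.log(np.where(rdf.g > 0, rdf.g, 1.0)), np.inf)
    return PMFCurve(bin_centers=rdf.bin_centers, W=W, temperature_K=env.temperature_K)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def _local_extrema(y: np.ndarray, prominence: float) -> tuple[list[int], list[int]]:
    """Prominence-filtered local minima and maxima of a 1D profile.

    The left edge counts as a minimum candidate when the profile climbs by
    more than ``prominence`` before its first descent — the contact well of a
    hard-core PMF sits at the edge of the finite domain and has no left
    neighbor.
    """
    from scipy.signal import find_peaks

    maxima = list(find_peaks(y, prominence=prominence)[0])
    minima = list(find_peaks(-y, prominence=prominence)[0])
    first_max = maxima[0] if maxima else len(y) - 1
    if (not minima or minima[0] > first_max) and y[first_max] - y[0] > prominence:
        if first_max > 0:
            minima.insert(0, 0)
    return minima, maxima


def pmf_features(pmf: PMFCurve, smoothing_window: int = 3,
                 noise_floor_kT: float = 0.05,
                 min_prominence_kT: float = 0.15) -> PMFFeatures:
    """Extract well/barrier/secondary-minimum geometry from a PMF.

    Works on the longest finite tail of the curve (the hard-core region,
    where W = +inf, is skipped).  A centered moving average (default 3 bins)
    suppresses spurious counting-noise extrema and extrema must clear a
    prominence of ``min_prominence_kT``; reported positions and heights come
    from the smoothed curve.  The secondary minimum beyond the barrier is
    reported only if it dips more than ``noise_floor_kT`` below the large-r
    plateau.
    """
    finite = np.isfinite(pmf.W)
    if finite.sum() < 3:
        return PMFFeatures(has_well=False)
    # longest contiguous finite run (typically everything beyond the core)
    runs = []
    start = None
    for i, f in enumerate(finite):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(finite)))
    lo, hi = max(runs, key=lambda ab: ab[1] - ab[0])
    r = pmf.bin_centers[lo:hi]
    w = _moving_average(pmf.W[lo:hi], smoothing_window)
    if len(w) < 3:
        return PMFFeatures(has_well=False)

    minima, maxima = _local_extrema(w, min_prominence_kT)
    # first barrier = first local max preceded by at least one local min
    first_barrier = None
    for m in maxima:
        if any(k < m for k in minima):
            first_barrier = m
            break
    if first_barrier is None:
        return PMFFeatures(has_well=False)
    well_candidates = [k for k in minima if k < first_barrier]
    well_idx = min(well_candidates, key=lambda k: w[k])
    # barrier = highest local max beyond the well, before the large-r plateau
    barrier_idx = max((m for m in maxima if m > well_idx), key=lambda m: w[m])

    plateau = float(np.mean(w[max(len(w) - max(3, len(w) // 10), barrier_idx + 1):]))
    secondary = None
    for k in minima:
        if k > barrier_idx and plateau - w[k] > noise_floor_kT:
            secondary = float(r[k])
            break

    well_depth = float(w[well_idx])
    barrier_height = float(w[barrier_idx])
    return PMFFeatures(
        has_well=True,
        well_position=float(r[well_idx]),
        well_depth=well_depth,
        barrier_position=float(r[barrier_idx]),
        barrier_height=barrier_height,
        barrier_minus_well=barrier_height - well_depth,
        secondary_minimum_position=secondary,
    )


def contact_value(rdf: RDFCurve, sigma: float, window: float = 0.05) -> float:
    """g(sigma+): linear extrapolation of g over [sigma, (1+window) sigma].

    The pair correlation of a hard-core fluid is discontinuous at contact;
    the standard estimate fits the first bins above sigma and evaluates the
    fit at sigma.
    """
    c = rdf.bin_centers
    sel = (c >= sigma) & (c < sigma * (1.0 + window))
    if sel.sum() < 2:
        raise ValueError("not enough bins above sigma for contact extrapolation")
    slope, intercept = np.polyfit(c[sel], rdf.g[sel], 1)
    return float(slope * sigma + intercept)


def number_concentration(config: ParticleConfiguration) -> float:
    """Number concentration N/V in particles per m^3."""
    return config.n_particles / config.box.volume_m3
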