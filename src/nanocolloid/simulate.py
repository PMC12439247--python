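"""Synthetic dispersion generator: Metropolis Monte Carlo and forward SAXS.

Stands in for the experimental inputs of the analysis pipeline.  The Monte
Carlo sampler produces 3D centroid configurations of hard-core + two-Yukawa
particles in a periodic box or a bounded slab (emulating the particle
coordinates segmented from cryo-ET tomograms of vitrified films); the SAXS
synthesizer produces 1D scattering curves I(q) = scale * <P(q)> * S(q) + bg
with multiplicative Gaussian noise (emulating reduced beamline data).

Every stochastic artifact is driven by a single integer seed; sub-seeds for
series members are derived deterministically, so identical (config, seed)
yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .potentials import TwoYukawaPotential

__all__ = [
    "Box",
    "ParticleConfiguration",
    "SimulationConfig",
    "SyntheticSAXSSpec",
    "MCStats",
    "run_mc",
    "synthesize_saxs",
    "concentration_series",
    "pair_distances",
]

NM3_PER_M3 = 1e27  # 1 m^3 = 1e27 nm^3


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned simulation box: edge lengths (nm) and per-axis boundary mode.

    ``periodic[k]`` True means minimum-image wrapping on axis k; False means
    hard walls at 0 and ``lengths[k]`` (the slab mode used to emulate
    vitrified films, typically periodic in x,y and walled in z).
    """

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or len(self.periodic) != 3:
            raise ValueError("box needs 3 edge lengths and 3 boundary flags")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("box edges must be positive")
        object.__setattr__(self, "lengths", tuple(float(L) for L in self.lengths))
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))

    @classmethod
    def cube(cls, L: float, periodic: bool = True) -> "Box":
        return cls((L, L, L), (periodic,) * 3)

    @classmethod
    def slab(cls, Lx: float, Ly: float, thickness: float) -> "Box":
        """Periodic in x,y; hard walls in z (vitrified-film geometry)."""
        return cls((Lx, Ly, thickness), (True, True, False))

    @property
    def volume_nm3(self) -> float:
        return self.lengths[0] * self.lengths[1] * self.lengths[2]

    @property
    def volume_m3(self) -> float:
        return self.volume_nm3 / NM3_PER_M3

    def min_image(self, delta: np.ndarray) -> np.ndarray:
        """Apply minimum-image convention on periodic axes to displacement(s)."""
        delta = np.array(delta, dtype=float, copy=True)
        L = np.asarray(self.lengths)
        for k in range(3):
            if self.periodic[k]:
                delta[..., k] -= L[k] * np.round(delta[..., k] / L[k])
        return delta

    def contains(self, positions: np.ndarray) -> bool:
        """All coordinates within [0, L] on hard-wall axes."""
        for k in range(3):
            if not self.periodic[k]:
                c = positions[..., k]
                if np.any(c < 0) or np.any(c > self.lengths[k]):
                    return False
        return True


def pair_distances(positions: np.ndarray, box: Box) -> np.ndarray:
    """Condensed vector of all unordered pair distances (minimum image)."""
    n = len(positions)
    if n < 2:
        return np.empty(0)
    iu, ju = np.triu_indices(n, k=1)
    delta = box.min_image(positions[iu] - positions[ju])
    return np.sqrt(np.einsum("ij,ij->i", delta, delta))


@dataclass(frozen=True)
class ParticleConfiguration:
    """3D particle centroids (nm) in a bounded box.

    ``potential_used`` records the interaction the frame was equilibrated
    under (None for imported centroid sets); ``provenance`` records the seed
    and sweep index, or "imported".
    """

    positions: np.ndarray
    box: Box
    potential_used: TwoYukawaPotential | None = None
    provenance: str = "imported"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        if not self.box.contains(pos):
            raise ValueError("coordinates outside box on hard-wall axis")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def validate_hard_core(self, tol: float = 0.0) -> None:
        """Raise if any pair distance is below sigma of the attached potential."""
        if self.potential_used is None:
            return
        sigma = self.potential_used.sigma
        d = pair_distances(self.positions, self.box)
        if d.size and d.min() < sigma - tol:
            raise ValueError(
                f"hard-core violation: min pair distance {d.min():.4f} nm < sigma {sigma} nm"
            )


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Metropolis MC run specification.

    Sweeps are N attempted single-particle moves.  ``max_displacement`` is
    the half-width of the uniform trial displacement cube; it is auto-tuned
    toward 30-50% acceptance during equilibration and frozen for production.
    """

    n_particles: int
    box: Box
    potential: TwoYukawaPotential
    n_sweeps_equilibration: int = 200
    n_sweeps_production: int = 500
    sample_interval: int = 10
    max_displacement: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_particles", "n_sweeps_equilibration", "n_sweeps_production",
                     "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        sigma = self.potential.sigma
        hs_volume = self.n_particles * (math.pi / 6.0) * sigma**3
        if self.box.volume_nm3 <= hs_volume:
            raise ValueError(
                f"infeasible packing: box volume {self.box.volume_nm3:.3g} nm^3 "
                f"<= total hard-core volume {hs_volume:.3g} nm^3"
            )

    @property
    def volume_fraction(self) -> float:
        return (self.n_particles * (math.pi / 6.0) * self.potential.sigma**3
                / self.box.volume_nm3)


@dataclass(frozen=True)
class MCStats:
    attempted: int
    accepted: int
    max_displacement: float  # frozen production value, nm

    @property
    def acceptance_fraction(self) -> float:
        return self.accepted / self.attempted if self.attempted else float("nan")


def _initial_lattice(config: SimulationConfig) -> np.ndarray:
    """Simple-cubic start with spacing >= sigma (overlap-free by construction)."""
    n = config.n_particles
    L = np.asarray(config.box.lengths)
    sigma = config.potential.sigma
    m = math.ceil(n ** (1.0 / 3.0))
    while m**3 < n:  # guard rounding
        m += 1
    spacing = L / m
    if np.any(spacing < sigma):
        raise ValueError(
            f"infeasible packing: simple-cubic spacing {spacing.min():.3f} nm < "
            f"sigma {sigma} nm for N={n}"
        )
    idx = np.arange(m)
    grid = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    return (grid[:n] + 0.5) * spacing


def _tail_energy(d2: np.ndarray, sigma: float, Ks, Zs, rcut2: float) -> float:
    """Sum of Yukawa tail energies over squared distances (no overlaps inside)."""
    sel = d2 < rcut2
    if not np.any(sel):
        return 0.0
    x = np.sqrt(d2[sel]) / sigma
    e = 0.0
    for K, Z in zip(Ks, Zs):
        if K != 0.0:
            e += np.sum(-K * np.exp(-Z * (x - 1.0)) / x)
    return float(e)


def _particle_energy(pos: np.ndarray, i: int, xi: np.ndarray, box: Box,
                     sigma2: float, sigma: float, Ks, Zs, rcut2: float,
                     interacting: bool) -> float:
    """Energy of particle i at trial position xi against all others; inf on overlap."""
    delta = box.min_image(pos - xi)
    d2 = np.einsum("ij,ij->i", delta, delta)
    d2[i] = np.inf
    if np.any(d2 < sigma2):
        return float("inf")
    if not interacting:
        return 0.0
    return _tail_energy(d2, sigma, Ks, Zs, rcut2)


def run_mc(config: SimulationConfig) -> tuple[list[ParticleConfiguration], MCStats]:
    """Run Metropolis MC; return sampled production frames and acceptance stats.

    Trial moves are uniform displacements of single particles; acceptance is
    min(1, exp(-dbetaV)).  Hard-core overlaps and hard-wall crossings are
    rejected outright.  The Yukawa tails are truncated at
    r_cut = sigma * (1 + 8/Z_min) (error < e^-8 kT), with no tail correction.
    """
    pot = config.potential
    sigma = pot.sigma
    sigma2 = sigma * sigma
    Ks = [t.K for t in pot.terms]
    Zs = [t.Z for t in pot.terms]
    interacting = any(K != 0.0 for K in Ks)
    if interacting:
        zmin = min(Z for K, Z in zip(Ks, Zs) if K != 0.0)
        rcut = sigma * (1.0 + 8.0 / zmin)
    else:
        rcut = sigma
    rcut2 = rcut * rcut

    box = config.box
    L = np.asarray(box.lengths)
    periodic = np.asarray(box.periodic)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pos = _initial_lattice(config)
    n = config.n_particles
    step = float(config.max_displacement)

    def sweep(step: float) -> int:
        accepted = 0
        picks = rng.integers(0, n, size=n)
        disp = rng.uniform(-step, step, size=(n, 3))
        us = rng.random(n)
        for t in range(n):
            i = int(picks[t])
            xi_old = pos[i]
            xi_new = xi_old + disp[t]
            # boundary handling: wrap periodic axes, reject wall crossings
            reject = False
            xi_new = xi_new.copy()
            for k in range(3):
                if periodic[k]:
                    xi_new[k] -= L[k] * math.floor(xi_new[k] / L[k])
                elif xi_new[k] < 0.0 or xi_new[k] > L[k]:
                    reject = True
                    break
            if reject:
                continue
            e_new = _particle_energy(pos, i, xi_new, box, sigma2, sigma, Ks, Zs,
                                     rcut2, interacting)
            if e_new == float("inf"):
                continue
            e_old = _particle_energy(pos, i, xi_old, box, sigma2, sigma, Ks, Zs,
                                     rcut2, interacting)
            de = e_new - e_old
            if de <= 0.0 or us[t] < math.exp(-de):
                pos[i] = xi_new
                accepted += 1
        return accepted

    # equilibration with step-size tuning every 50 sweeps toward 30-50%
    window_acc = window_att = 0
    for s in range(config.n_sweeps_equilibration):
        window_acc += sweep(step)
        window_att += n
        if (s + 1) % 50 == 0:
            rate = window_acc / window_att
            if rate < 0.30:
                step = max(step * 0.8, 0.01 * sigma)
            elif rate > 0.50:
                step = min(step * 1.2, min(box.lengths) / 4.0)
            window_acc = window_att = 0

    frames: list[ParticleConfiguration] = []
    accepted = 0
    for s in range(1, config.n_sweeps_production + 1):
        accepted += sweep(step)
        if s % config.sample_interval == 0:
            frames.append(ParticleConfiguration(
                positions=pos.copy(), box=box, potential_used=pot,
                provenance=f"seed={config.seed};sweep={s}"))
    stats = MCStats(attempted=config.n_sweeps_production * n, accepted=accepted,
                    max_displacement=step)
    return frames, stats


def concentration_series(base: SimulationConfig, concentrations_m3: list[float],
                         tol: float = 0.01) -> list[list[ParticleConfiguration]]:
    """Run one MC series per requested number concentration (particles/m^3).

    Particle counts are N = round(c * V); a request whose rounded count
    misses the target by more than ``tol`` (relative) is an error — use a
    bigger box.  Each member gets an independent sub-seed derived from the
    base seed by position, so duplicate concentrations yield distinct frames.
    """
    out: list[list[ParticleConfiguration]] = []
    V_m3 = base.box.volume_m3
    for idx, c in enumerate(concentrations_m3):
        n = int(round(c * V_m3))
        if n < 2:
            raise ValueError(f"concentration {c:g} m^-3 gives N={n} < 2 in this box")
        achieved = n / V_m3
        if abs(achieved - c) / c > tol:
            raise ValueError(
                f"cannot hit {c:g} m^-3 within {tol:.0%} in this box "
                f"(achievable {achieved:g})")
        sub_seed = int(np.random.SeedSequence(base.seed, spawn_key=(idx,))
                       .generate_state(1, dtype=np.uint32)[0]) % (2**31)
        cfg = replace(base, n_particles=n, seed=sub_seed)
        frames, _ = run_mc(cfg)
        out.append(frames)
    return out


# ---------------------------------------------------------------------------
# forward SAXS synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSAXSSpec:
    """Specification for a synthetic scattering curve.

    I(q) = scale * <P(q)> * S(q; potential, phi) + background, then each point
    is multiplied by (1 + eps_q) with eps_q ~ N(0, noise_relative_sd) i.i.d.
    The reported uncertainty column is noise_relative_sd * I_noiseless.
    """

    q_grid: np.ndarray
    form_factor: "LogNormalSphereFF"  # noqa: F821 - defined in saxs module
    potential: TwoYukawaPotential
    volume_fraction: float
    scale: float = 1.0
    background: float = 0.0
    noise_relative_sd: float = 0.01
    seed: int = 0
    closure: str = "hnc"

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        object.__setattr__(self, "q_grid", q)
        if not (0.0 < self.volume_fraction < 0.5):
            raise ValueError("volume_fraction must lie in (0, 0.5)")
        if self.noise_relative_sd < 0:
            raise ValueError("noise_relative_sd must be >= 0")


def synthesize_saxs(spec: SyntheticSAXSSpec):
    """Generate a seeded synthetic SAXS curve from a known potential.

    Volume fractions below 1e-8 short-circuit to S(q) = 1 (ideal dilution),
    making the dilute limit exact rather than solver-limited.
    """
    from .saxs import SAXSCurve, SolutionState, average_form_factor, oz_structure_factor

    q = spec.q_grid
    pbar = average_form_factor(q, spec.form_factor)
    if spec.volume_fraction < 1e-8:
        S = np.ones_like(q)
    else:
        S = oz_structure_factor(spec.potential,
                                SolutionState.from_volume_fraction(
                                    spec.volume_fraction, spec.potential.sigma),
                                q, closure=spec.closure)
    I0 = spec.scale * pbar * S + spec.background
    if spec.noise_relative_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        eps = rng.normal(0.0, spec.noise_relative_sd, size=q.shape)
        I = I0 * (1.0 + eps)
        sigma_I = spec.noise_relative_sd * I0
    else:
        I = I0.copy()
        sigma_I = None
    return SAXSCurve(q=q, I=I, sigma_I=sigma_I)
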