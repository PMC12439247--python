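"""Hard-core two-Yukawa pair potentials for ligand-coated nanoparticles.

The pair interaction potential (PIP) used throughout this package is a hard
core of diameter ``sigma`` plus two screened-Coulomb (Yukawa) tails::

    beta V(r) = +inf                                    r < sigma
    beta V(r) = - sum_i K_i * exp(-Z_i (x - 1)) / x     x = r / sigma >= 1

Each term has a dimensionless strength ``K`` (in kT at contact; K > 0 is
attractive under the sign convention above) and a dimensionless inverse
range ``Z = 1/lambda``, where ``lambda`` is the decay length in units of
``sigma``.  One term typically models short-range hydrophobic attraction,
the other screened electrostatic repulsion, but the terms are stored signed
and the attractive/repulsive labels are always computed from ``sign(K)``.

All energies in this package are expressed in units of kT; conversion to
joules happens only at I/O boundaries via :class:`Environment`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_JK",
    "YukawaTerm",
    "TwoYukawaPotential",
    "Environment",
    "evaluate_potential",
    "decompose_potential",
]

#: Boltzmann constant in J/K (CODATA exact value).
BOLTZMANN_JK = 1.380649e-23

#: Default temperature: 20 degC, the stated measurement temperature.
DEFAULT_TEMPERATURE_K = 293.15


@dataclass(frozen=True)
class YukawaTerm:
    """One Yukawa tail: strength ``K`` (kT, signed) and inverse range ``Z``.

    ``K > 0`` is attractive.  ``Z = 1/lambda`` with ``lambda`` the decay
    range in units of the hard-core diameter.
    """

    K: float
    Z: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.K):
            raise ValueError(f"K must be finite, got {self.K}")
        if not (self.Z > 0 and math.isfinite(self.Z)):
            raise ValueError(f"Z must be positive and finite, got {self.Z}")

    @classmethod
    def from_range(cls, K: float, lam: float) -> "YukawaTerm":
        """Construct from a decay range ``lambda`` (units of sigma); Z = 1/lambda."""
        return cls(K=K, Z=1.0 / lam)

    @property
    def range(self) -> float:
        """Decay range lambda = 1/Z in units of sigma."""
        return 1.0 / self.Z

    @property
    def attractive(self) -> bool:
        return self.K > 0


@dataclass(frozen=True)
class Environment:
    """Thermal environment: all potentials/PMFs are in kT at this temperature."""

    temperature_K: float = DEFAULT_TEMPERATURE_K
    solvent: str = "H2O"
    dielectric_constant: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValueError("temperature must be positive")

    @property
    def kT_J(self) -> float:
        """Thermal energy in joules."""
        return BOLTZMANN_JK * self.temperature_K


@dataclass(frozen=True)
class TwoYukawaPotential:
    """Hard core (diameter ``sigma`` in nm) plus two signed Yukawa terms."""

    sigma: float
    term_1: YukawaTerm
    term_2: YukawaTerm
    environment: Environment = field(default_factory=Environment)

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def terms(self) -> tuple[YukawaTerm, YukawaTerm]:
        return (self.term_1, self.term_2)

    def __call__(self, r):
        return evaluate_potential(self, r)

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def hard_sphere(cls, sigma: float) -> "TwoYukawaPotential":
        """Pure hard sphere: both Yukawa strengths zero."""
        return cls(sigma=sigma, term_1=YukawaTerm(0.0, 1.0), term_2=YukawaTerm(0.0, 1.0))

    # -- serialization ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sigma_nm": self.sigma,
            "K1": self.term_1.K,
            "Z1": self.term_1.Z,
            "K2": self.term_2.K,
            "Z2": self.term_2.Z,
            "temperature_K": self.environment.temperature_K,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoYukawaPotential":
        return cls(
            sigma=d["sigma_nm"],
            term_1=YukawaTerm(d["K1"], d["Z1"]),
            term_2=YukawaTerm(d["K2"], d["Z2"]),
            environment=Environment(temperature_K=d.get("temperature_K", DEFAULT_TEMPERATURE_K)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TwoYukawaPotential":
        return cls.from_dict(json.loads(s))


def _yukawa_tail(K: float, Z: float, x: np.ndarray) -> np.ndarray:
    """-K exp(-Z(x-1))/x on x >= 1 (caller guarantees the domain)."""
    return -K * np.exp(-Z * (x - 1.0)) / x


def evaluate_potential(pot: TwoYukawaPotential, r) -> np.ndarray | float:
    """Evaluate beta*V(r) in kT at separation(s) ``r`` (nm).

    Returns +inf inside the hard core (r < sigma).  Raises ``ValueError``
    for any r <= 0 (separations are physical distances).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("separation r must be positive")
    x = r_arr / pot.sigma
    if x.ndim == 0:
        if x >= 1.0:
            return float(sum(_yukawa_tail(t.K, t.Z, x) for t in pot.terms))
        return float("inf")
    out = np.full_like(x, np.inf)
    outside = x >= 1.0
    if np.any(outside):
        xo = x[outside]
        out[outside] = sum(_yukawa_tail(t.K, t.Z, xo) for t in pot.terms)
    return out


def decompose_potential(pot: TwoYukawaPotential, r_grid):
    """Split beta*V on ``r_grid`` (all >= sigma) into attractive/repulsive parts.

    The attractive curve sums the terms with K > 0, the repulsive one the
    terms with K < 0; the two add up to the total exactly.  Returns
    ``(total, attractive, repulsive)`` arrays in kT.
    """
    r_arr = np.asarray(r_grid, dtype=float)
    if np.any(r_arr < pot.sigma):
        raise ValueError("decomposition grid must satisfy r >= sigma")
    x = r_arr / pot.sigma
    att = np.zeros_like(x)
    rep = np.zeros_like(x)
    for t in pot.terms:
        contrib = _yukawa_tail(t.K, t.Z, x)
        if t.K > 0:
            att += contrib
        elif t.K < 0:
            rep += contrib
    total = att + rep
    return total, att, rep
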