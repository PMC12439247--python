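"""Small-angle scattering: forward model and 2-Yukawa structure-factor fitting.

The measured intensity of a dispersion of quasi-monodisperse spheres is
modelled in the decoupling approximation as::

    I(q) = scale * <P(q)> * S(q) + background

with ``<P(q)>`` the intensity-weighted (<V^2 P>/<V^2>) form factor of spheres
with a log-normal radius distribution (fixed from a dilute measurement), and
``S(q)`` the structure factor of an effective one-component fluid of
hard-core + two-Yukawa particles at volume fraction phi.

S(q) comes from a numerical Ornstein-Zernike solver (Picard iteration with
fast sine transforms) under an explicit closure: Percus-Yevick (PY) or
hypernetted chain (HNC, the default for potentials with Yukawa tails).
The Wertheim closed-form PY hard-sphere structure factor is provided as an
independent analytic reference used for validation, never as the solver.

The inverse problem — weighted least squares on I(q) for the Yukawa
strengths/ranges, volume fraction, scale and background — is solved with
lmfit, and fitted potentials can be decomposed into their attractive and
repulsive components for paired-condition comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.interpolate import CubicSpline

import lmfit

from .potentials import Environment, TwoYukawaPotential, YukawaTerm, decompose_potential

__all__ = [
    "SAXSCurve",
    "LogNormalSphereFF",
    "SolutionState",
    "SAXSFitResult",
    "OZConvergenceError",
    "sphere_form_factor",
    "average_form_factor",
    "oz_structure_factor",
    "hard_sphere_sq_py",
    "fit_saxs",
    "decompose_fit",
]

NM3_PER_M3 = 1e27


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAXSCurve:
    """1D scattering curve: q (nm^-1, strictly increasing), I, optional sigma_I."""

    q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma_I is not None:
            object.__setattr__(self, "sigma_I", np.asarray(self.sigma_I, dtype=float))
        if q.ndim != 1 or len(q) != len(I):
            raise ValueError("q and I must be 1D arrays of equal length")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(I)):
            raise ValueError("intensities must be finite")

    def weights(self) -> np.ndarray:
        """1/sigma_I, with the counting-statistics fallback sigma ~ sqrt(I)."""
        if self.sigma_I is not None:
            return 1.0 / self.sigma_I
        return 1.0 / np.sqrt(np.clip(np.abs(self.I), 1e-300, None))


@dataclass(frozen=True)
class LogNormalSphereFF:
    """Log-normal polydisperse sphere form factor (median radius in nm).

    ``fixed=True`` records that the distribution was calibrated on a dilute
    measurement and is held constant during structure-factor fits.
    """

    median_radius: float
    lognormal_sigma: float
    fixed: bool = True

    def __post_init__(self) -> None:
        if self.median_radius <= 0:
            raise ValueError("median_radius must be positive")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass(frozen=True)
class SolutionState:
    """Concentration of the dispersion: volume fraction + number concentration.

    The two are linked by phi = n * (pi/6) sigma^3 for effective hard-core
    diameter sigma; both are carried so reports can quote either.
    """

    volume_fraction: float
    number_concentration: float   # particles per m^3

    def __post_init__(self) -> None:
        if not (0.0 < self.volume_fraction < 0.5):
            raise ValueError("volume fraction must lie in (0, 0.5)")

    @classmethod
    def from_volume_fraction(cls, phi: float, sigma_nm: float) -> "SolutionState":
        n_m3 = phi / ((math.pi / 6.0) * sigma_nm**3 / NM3_PER_M3)
        return cls(volume_fraction=phi, number_concentration=n_m3)

    @classmethod
    def from_number_concentration(cls, n_m3: float, sigma_nm: float) -> "SolutionState":
        phi = n_m3 * (math.pi / 6.0) * sigma_nm**3 / NM3_PER_M3
        return cls(volume_fraction=phi, number_concentration=n_m3)


class OZConvergenceError(RuntimeError):
    """Raised when the Picard iteration fails; carries the residual history."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# form factor
# ---------------------------------------------------------------------------

def sphere_form_factor(q, radius: float):
    """Normalized sphere form factor P(q) = [3 j1(qR)/(qR)]^2, P(0) = 1."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("q must be non-negative")
    x = q_arr * radius
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    # series 1 - x^2/10 + ... for the amplitude near x = 0
    amp = np.where(small, 1.0 - x * x / 10.0, amp)
    out = amp * amp
    return float(out) if np.isscalar(q) or np.asarray(q).ndim == 0 else out


def average_form_factor(q_grid, ff: LogNormalSphereFF, rel_tol: float = 1e-6,
                        max_nodes: int = 320) -> np.ndarray:
    """Intensity-weighted polydisperse form factor <V^2 P>/<V^2>.

    Averages over the log-normal radius density by Gauss-Hermite quadrature
    in log-radius, doubling the node count until the result is stable to
    ``rel_tol`` (relative, max over q).  Raises if the quadrature does not
    converge within ``max_nodes`` nodes.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if ff.lognormal_sigma == 0.0:
        return sphere_form_factor(q, ff.median_radius)

    def quad(n_nodes: int) -> np.ndarray:
        t, wts = np.polynomial.hermite.hermgauss(n_nodes)
        # R = R_med * exp(sigma * sqrt(2) t), t-weighting e^{-t^2}
        radii = ff.median_radius * np.exp(ff.lognormal_sigma * math.sqrt(2.0) * t)
        v2 = radii**6
        num = np.zeros_like(q)
        den = 0.0
        for Ri, v2i, wi in zip(radii, v2, wts):
            num += wi * v2i * sphere_form_factor(q, Ri)
            den += wi * v2i
        return num / den

    n = 20
    prev = quad(n)
    while n < max_nodes:
        n *= 2
        cur = quad(n)
        rel = np.max(np.abs(cur - prev) / np.clip(np.abs(cur), 1e-300, None))
        if rel < rel_tol:
            return cur
        prev = cur
    raise RuntimeError(
        f"form-factor quadrature did not converge to {rel_tol} within {max_nodes} nodes")


# ---------------------------------------------------------------------------
# Ornstein-Zernike solver
# ---------------------------------------------------------------------------

_N_GRID = 4096
_DR_OVER_SIGMA = 1.0 / 64.0


def _radial_dst(x: np.ndarray) -> np.ndarray:
    # DST-I: y[m] = 2 sum_j x[j] sin(pi (j+1)(m+1) / (N+1))
    return scipy.fft.dst(x, type=1)


def oz_structure_factor(potential: TwoYukawaPotential, solution: SolutionState,
                        q_grid, closure: str = "hnc",
                        tol: float = 1e-8, max_iter: int = 10000,
                        mixing: float = 0.15,
                        full_output: bool = False,
                        warm_start: np.ndarray | None = None,
                        state: dict | None = None):
    """Structure factor S(q) of the hard-core 2-Yukawa fluid from the OZ equation.

    Solves the Ornstein-Zernike relation with the chosen closure ("py" or
    "hnc") by Picard iteration on the indirect correlation gamma = h - c,
    using fast sine transforms on a radial grid of 4096 points with
    dr = sigma/64.  Converged when the max-norm change in gamma is below
    ``tol``; the mixing parameter adapts (halving on residual growth).

    Returns S evaluated on ``q_grid`` (cubic interpolation from the solver's
    k-grid); with ``full_output=True`` returns (S, g(r), r) as well.
    """
    closure = closure.lower()
    if closure not in ("py", "hnc"):
        raise ValueError(f"unknown closure {closure!r}; use 'py' or 'hnc'")
    sigma = potential.sigma
    phi = solution.volume_fraction
    rho = 6.0 * phi / (math.pi * sigma**3)   # nm^-3

    n = _N_GRID
    dr = sigma * _DR_OVER_SIGMA
    r = dr * np.arange(1, n + 1)
    dk = math.pi / ((n + 1) * dr)
    k = dk * np.arange(1, n + 1)

    core = r < sigma
    beta_v = np.zeros(n)
    x = r / sigma
    outside = ~core
    for t in potential.terms:
        beta_v[outside] += -t.K * np.exp(-t.Z * (x[outside] - 1.0)) / x[outside]
    def boltzmann_factor(scale: float) -> np.ndarray:
        emb = np.where(core, 0.0, np.exp(-np.clip(scale * beta_v, -700, 700)))
        # The hard-core jump of e^{-betaV} sits exactly on the node r = sigma
        # (dr = sigma/64); assigning that node the jump midpoint restores
        # second-order accuracy of the sine-transform discretization.
        j_core = int(round(sigma / dr)) - 1
        if 0 <= j_core < n and abs(r[j_core] - sigma) < 1e-9 * sigma:
            emb[j_core] = 0.5 * math.exp(-min(max(scale * beta_v[j_core], -700), 700))
        return emb

    fw = 2.0 * math.pi * dr          # forward FT prefactor with DST-I/2
    bw = dk / (4.0 * math.pi**2)     # inverse prefactor

    residuals: list[float] = []

    def oz_step(emb: np.ndarray, gamma: np.ndarray, it: int) -> tuple[np.ndarray, np.ndarray]:
        """One fixed-point map gamma -> F(gamma); returns (F(gamma), c_hat)."""
        if closure == "py":
            c = emb * (1.0 + gamma) - 1.0 - gamma
        else:  # HNC
            c = emb * np.exp(np.clip(gamma, -700, 700)) - 1.0 - gamma
        c_hat = fw / k * _radial_dst(r * c)
        denom = 1.0 - rho * c_hat
        if np.any(denom <= 0):
            residuals.append(float("inf"))   # mark the diverged step in the history
            raise OZConvergenceError(
                f"OZ iteration unstable (1 - rho*c_hat <= 0) at iteration {it}",
                residuals)
        gamma_hat = rho * c_hat * c_hat / denom
        return bw / r * _radial_dst(k * gamma_hat), c_hat

    def picard(emb: np.ndarray, gamma: np.ndarray,
               accelerate: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Damped fixed-point iteration, optionally Ng-accelerated.

        Ng's scheme (two-history Anderson mixing) extrapolates from the last
        two iterates and typically converges in tens of sweeps where plain
        Picard needs hundreds; near-unstable states can overshoot, so the
        caller falls back to the plain damped iteration on failure.
        """
        alpha = mixing
        prev_res = np.inf
        hist: list[tuple[np.ndarray, np.ndarray]] = []   # (gamma_in, F(gamma_in))
        for it in range(max_iter):
            f_cur, c_hat = oz_step(emb, gamma, it)
            d_cur = f_cur - gamma
            res = float(np.max(np.abs(d_cur)))
            residuals.append(res)
            if res < tol:
                return gamma, c_hat
            stepped = False
            if accelerate and len(hist) == 2:
                (g1, f1), (g2, f2) = hist
                d1, d2 = f1 - g1, f2 - g2
                u1, u2 = d_cur - d1, d_cur - d2
                a11, a12, a22 = u1 @ u1, u1 @ u2, u2 @ u2
                b1, b2 = d_cur @ u1, d_cur @ u2
                det = a11 * a22 - a12 * a12
                if det > 0:
                    c1 = (b1 * a22 - b2 * a12) / det
                    c2 = (b2 * a11 - b1 * a12) / det
                    if np.isfinite(c1) and np.isfinite(c2) and abs(c1) + abs(c2) < 1e6:
                        cand = (1.0 - c1 - c2) * f_cur + c1 * f1 + c2 * f2
                        if np.all(np.isfinite(cand)):
                            gamma = cand
                            stepped = True
            if not stepped:
                gamma = gamma + alpha * d_cur
                if res > prev_res:
                    alpha = max(alpha * 0.5, 0.01)
                elif it % 20 == 19:
                    alpha = min(alpha * 1.3, 0.8)
            hist.append((f_cur - d_cur, f_cur))
            hist = hist[-2:]
            prev_res = res
        raise OZConvergenceError(
            f"OZ solver did not reach tol={tol:g} in {max_iter} iterations "
            f"(last residual {residuals[-1]:.3g})", residuals)

    # Direct solve from gamma = 0 (or a caller-provided warm start, e.g. the
    # previous trial point of a fit); on failure, retry with a continuation
    # ramp that switches the Yukawa tails on gradually (the hard core stays
    # full), carrying gamma between stages.
    gamma0 = np.zeros(n) if warm_start is None else np.asarray(warm_start, dtype=float)
    try:
        gamma, c_hat = picard(boltzmann_factor(1.0), gamma0.copy())
    except OZConvergenceError:
        try:
            # Ng extrapolation can overshoot near instability; plain damped
            # Picard is slower but monotone
            gamma, c_hat = picard(boltzmann_factor(1.0), gamma0.copy(),
                                  accelerate=False)
        except OZConvergenceError:
            gamma = np.zeros(n)
            for stage in np.linspace(0.1, 1.0, 10):
                try:
                    gamma, c_hat = picard(boltzmann_factor(float(stage)), gamma,
                                          accelerate=False)
                except OZConvergenceError as err:
                    raise OZConvergenceError(
                        f"OZ solver failed at continuation stage {stage:.1f} "
                        f"(phi={phi:g}): {err}", residuals) from err

    if state is not None:
        state["gamma"] = gamma.copy()
    s_k = 1.0 / (1.0 - rho * c_hat)
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    spline = CubicSpline(k, s_k)
    s_q = np.where(q <= k[0], s_k[0], np.where(q >= k[-1], s_k[-1], spline(q)))
    if not full_output:
        return s_q
    emb = boltzmann_factor(1.0)
    if closure == "py":
        g_r = emb * (1.0 + gamma)
    else:
        g_r = emb * np.exp(np.clip(gamma, -700, 700))
    return s_q, g_r, r


def hard_sphere_sq_py(q, sigma: float, phi: float):
    """Wertheim's closed-form Percus-Yevick hard-sphere structure factor.

    Independent analytic reference for validating the numerical OZ solver;
    not used by the solver itself.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    s = q * sigma
    a = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    b = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    d = phi * a / 2.0
    out = np.empty_like(s)
    small = s < 1e-3
    sl = np.where(small, 1.0, s)
    sin_s, cos_s = np.sin(sl), np.cos(sl)
    nc = -24.0 * phi * (
        a * (sin_s - sl * cos_s) / sl**3
        + b * (2.0 * sl * sin_s + (2.0 - sl**2) * cos_s - 2.0) / sl**4
        + d * (-sl**4 * cos_s
               + 4.0 * ((3.0 * sl**2 - 6.0) * cos_s + (sl**3 - 6.0 * sl) * sin_s + 6.0)
               ) / sl**6
    )
    out = 1.0 / (1.0 - nc)
    # q -> 0 compressibility limit
    s0 = (1.0 - phi) ** 4 / (1.0 + 2.0 * phi) ** 2
    out[small] = s0
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "scale": (1e-12, np.inf),
    "background": (0.0, np.inf),
    "K1": (-50.0, 50.0),
    "Z1": (0.05, 50.0),
    "K2": (-50.0, 50.0),
    "Z2": (0.05, 50.0),
    "phi": (1e-6, 0.45),
    "sigma": (0.1, 1000.0),
}

_DEFAULT_VARY = ("scale", "background", "K1", "Z1", "K2", "Z2", "phi")


@dataclass(frozen=True)
class SAXSFitResult:
    """Outcome of a 2-Yukawa structure-factor fit."""

    potential: TwoYukawaPotential
    solution: SolutionState
    scale: float
    background: float
    uncertainties: dict[str, float | None]
    redchi: float
    success: bool
    closure: str
    nfev: int
    message: str
    fixed_params: dict[str, float] = field(default_factory=dict)

    def params_dict(self) -> dict[str, float]:
        return {
            "sigma": self.potential.sigma,
            "K1": self.potential.term_1.K,
            "Z1": self.potential.term_1.Z,
            "K2": self.potential.term_2.K,
            "Z2": self.potential.term_2.Z,
            "phi": self.solution.volume_fraction,
            "scale": self.scale,
            "background": self.background,
        }


def fit_saxs(curve: SAXSCurve, ff: LogNormalSphereFF, initial: dict[str, float],
             vary: tuple[str, ...] | list[str] = _DEFAULT_VARY,
             bounds: dict[str, tuple[float, float]] | None = None,
             closure: str = "hnc",
             environment: Environment | None = None) -> SAXSFitResult:
    """Weighted least-squares fit of I(q) = scale * <P(q)> * S(q) + background.

    ``initial`` must provide {scale, background, K1, Z1, K2, Z2, phi, sigma};
    the form factor is held fixed (calibrated on a dilute measurement), and
    ``vary`` selects the free parameters (sigma is typically fixed).  Points
    are weighted by 1/sigma_I (or the sqrt(I) fallback).  OZ solver failures
    at a trial point contribute a large finite penalty so the optimizer can
    back away rather than crash.  The fit is deterministic for identical
    inputs and initials.
    """
    required = {"scale", "background", "K1", "Z1", "K2", "Z2", "phi", "sigma"}
    missing = required - set(initial)
    if missing:
        raise ValueError(f"initial values missing for {sorted(missing)}")
    n_free = len(vary)
    if len(curve.q) < 5 * n_free:
        raise ValueError(
            f"curve has {len(curve.q)} points; need >= {5 * n_free} for "
            f"{n_free} free parameters")
    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    env = environment or Environment()

    pbar = average_form_factor(curve.q, ff)
    w = curve.weights()

    params = lmfit.Parameters()
    for name in ("scale", "background", "K1", "Z1", "K2", "Z2", "phi", "sigma"):
        lo, hi = bnds[name]
        params.add(name, value=float(initial[name]), vary=name in vary,
                   min=lo, max=hi)

    solver_cache: dict = {}

    def model_intensity(p: lmfit.Parameters) -> np.ndarray:
        pot = TwoYukawaPotential(
            sigma=p["sigma"].value,
            term_1=YukawaTerm(p["K1"].value, p["Z1"].value),
            term_2=YukawaTerm(p["K2"].value, p["Z2"].value),
            environment=env)
        sol = SolutionState.from_volume_fraction(p["phi"].value, pot.sigma)
        # warm-start each solve from the previous trial point's solution:
        # successive optimizer trials differ little, so Picard needs only a
        # few sweeps instead of a cold start
        s_q = oz_structure_factor(pot, sol, curve.q, closure=closure,
                                  warm_start=solver_cache.get("gamma"),
                                  state=solver_cache)
        return p["scale"].value * pbar * s_q + p["background"].value

    def residual(p: lmfit.Parameters) -> np.ndarray:
        try:
            return (model_intensity(p) - curve.I) * w
        except OZConvergenceError:
            # graded penalty: the solver fails where the trial fluid is
            # unstable (too much attraction / too dense); sloping the penalty
            # toward weaker interactions gives the optimizer a way back.
            mag = (abs(p["K1"].value) + abs(p["K2"].value) + 10.0 * p["phi"].value)
            return np.full_like(curve.I, 1e4 * (1.0 + mag))

    minimizer = lmfit.Minimizer(residual, params)
    out = minimizer.minimize(method="least_squares")

    v = {name: out.params[name].value for name in out.params}
    unc = {name: (out.params[name].stderr if out.params[name].vary else None)
           for name in out.params}
    pot = TwoYukawaPotential(sigma=v["sigma"],
                             term_1=YukawaTerm(v["K1"], v["Z1"]),
                             term_2=YukawaTerm(v["K2"], v["Z2"]),
                             environment=env)
    return SAXSFitResult(
        potential=pot,
        solution=SolutionState.from_volume_fraction(v["phi"], v["sigma"]),
        scale=v["scale"], background=v["background"],
        uncertainties=unc, redchi=float(out.redchi), success=bool(out.success),
        closure=closure, nfev=int(out.nfev), message=str(out.message),
        fixed_params={name: v[name] for name in v if name not in vary},
    )


def decompose_fit(result: SAXSFitResult, r_grid,
                  other: SAXSFitResult | None = None) -> dict[str, np.ndarray]:
    """Attractive/repulsive decomposition of a fitted potential on ``r_grid``.

    With ``other`` given, also reports difference curves (result - other) per
    component — the paired-condition comparison layout.  Refuses unconverged
    fits.
    """
    if not result.success:
        raise ValueError("refusing to decompose an unconverged fit")
    r = np.asarray(r_grid, dtype=float)
    total, att, rep = decompose_potential(result.potential, r)
    report = {"r": r, "total": total, "attractive": att, "repulsive": rep}
    if other is not None:
        if not other.success:
            raise ValueError("refusing to decompose an unconverged fit")
        tot2, att2, rep2 = decompose_potential(other.potential, r)
        report["delta_total"] = total - tot2
        report["delta_attractive"] = att - att2
        report["delta_repulsive"] = rep - rep2
    return report
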