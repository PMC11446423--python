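"""Expected site frequency spectra under the Wright-Fisher diffusion.

This module computes the expected density of segregating sites phi(q) for a
mutation with scaled selection coefficient gamma and dominance h, propagates
it through a multi-epoch demography, and samples it binomially to an expected
SFS.  All quantities are per unit theta (the scaled mutation rate of the
region): the neutral constant-size expectation is exactly theta/i.

Sign convention
---------------
``gamma`` here is *signed*, positive when the derived allele is favored:
genotype fitnesses are 1, 1 + gamma*h/N, 1 + gamma/N in the underlying
Wright-Fisher model (gamma = 2*N*s_signed).  Deleterious mutations in the
inference convention (mutant homozygote fitness 1-2s with s in [0, 0.5])
enter the diffusion with ``gamma = -2 * N_anc * s``.  The quasi-stationary
density below is the classical sojourn-time density; with gamma < 0 it decays
like exp(-2|gamma|h q)/q near the origin, as expected for selection against
the derived allele.

Numerics
--------
Exponentials are handled in log space throughout, so arbitrarily strong
selection cannot overflow; the supported range is still capped at
|s| <= 0.25 (|gamma| <= 0.5 * 2*N_anc) because the diffusion itself is a poor
approximation beyond that.  The frequency grid is a sigmoid-spaced grid
crowded near the boundaries; time integration is implicit Euler with
Chang-Cooper flux weighting, which is positivity-preserving and remains
stable at large |gamma|.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import betainc, gammaln

from .demomodel import DemographicModel
from .spectra import SFSpectrum, fold_sfs

__all__ = [
    "ScaledSelection",
    "FrequencyDensity",
    "ExpectationGrid",
    "frequency_grid",
    "quasi_stationary_density",
    "evolve_density",
    "expected_sfs_from_density",
    "equilibrium_expected_sfs",
    "demographic_expected_sfs",
    "build_expectation_grid",
]

#: hard cap of the inference convention; |s| beyond this is "not segregating"
S_MAX = 0.25


@dataclass(frozen=True)
class ScaledSelection:
    """Selection/dominance of a mutation class in the inference convention.

    ``s`` is the deleterious selection coefficient (mutant homozygote fitness
    1 - 2s, 0 <= s <= 0.5; s = 0.5 is a lethal), ``h`` the dominance
    coefficient and ``gamma = 2 * N_anc * s`` the population-scaled strength.
    """

    s: float
    h: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 0.5:
            raise ValueError(f"s must be in [0, 0.5], got {self.s}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must be in [0, 1], got {self.h}")
        if (self.s == 0.0) != (self.gamma == 0.0) or self.gamma < 0:
            raise ValueError("gamma must equal 2 * N_anc * s (deleterious, >= 0)")

    @classmethod
    def from_s(cls, s: float, h: float, N_anc: float) -> "ScaledSelection":
        return cls(s=s, h=h, gamma=2.0 * N_anc * s)

    @property
    def signed_gamma(self) -> float:
        """Signed scaled coefficient entering the diffusion (deleterious -> negative)."""
        return -self.gamma


@dataclass
class FrequencyDensity:
    """Density of segregating sites per unit frequency, per unit theta.

    ``q_grid`` spans [0, 1] inclusive; the boundary values carry no density
    (absorbed mass is discarded).
    """

    q_grid: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, float)
        self.phi = np.asarray(self.phi, float)
        if self.q_grid.shape != self.phi.shape:
            raise ValueError("q_grid and phi must have the same shape")


def frequency_grid(pts: int, crwd: float = 8.0) -> np.ndarray:
    """Sigmoid-spaced grid on [0, 1], crowded near both boundaries."""
    if pts < 20:
        raise ValueError("need at least 20 grid points")
    unif = np.linspace(-1.0, 1.0, pts)
    grid = 1.0 / (1.0 + np.exp(-crwd * unif))
    grid = (grid - grid[0]) / (grid[-1] - grid[0])
    grid[0], grid[-1] = 0.0, 1.0
    return grid


# ---------------------------------------------------------------------------
# quasi-stationary density
# ---------------------------------------------------------------------------

def _log_interval_integrals(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """log of integral of exp(g) over each interval, treating g as linear there."""
    dx = np.diff(x)
    d = np.diff(g)
    # log[(e^d - 1)/d], stable over the whole real line
    log_ratio = np.empty_like(d)
    small = np.abs(d) < 1e-8
    pos = (d >= 30) & ~small
    neg = (d <= -30) & ~small
    mid = ~(small | pos | neg)
    log_ratio[small] = d[small] / 2.0
    log_ratio[pos] = d[pos] - np.log(d[pos])
    log_ratio[neg] = -np.log(-d[neg])
    log_ratio[mid] = np.log(np.expm1(d[mid]) / d[mid])
    with np.errstate(divide="ignore"):
        return g[:-1] + np.log(dx) + log_ratio


def _suffix_logsumexp(vals: np.ndarray) -> np.ndarray:
    """S_i = log sum_{k>=i} exp(vals_k), with S_len = -inf appended."""
    rev = np.logaddexp.accumulate(vals[::-1])[::-1]
    return np.append(rev, -np.inf)


def quasi_stationary_density(
    gamma: float, h: float, q_grid: np.ndarray, n_quad: int | None = None
) -> np.ndarray:
    """Sojourn density f(q; gamma, h) at the points ``q_grid`` (interior of (0,1)).

    f(q) = [e^{4 g h q + 2 g (1-2h) q^2} / (q(1-q))]
           * int_q^1 e^{-4 g h e - 2 g (1-2h) e^2} de / int_0^1 (same) de,

    with ``gamma`` signed (positive = derived allele favored).  At gamma = 0
    this is exactly 1/q.  Evaluated by piecewise-exponential quadrature on a
    fine grid in log space; relative accuracy is ~1e-8 for |gamma| <= 1e3 at
    the default resolution.
    """
    q = np.asarray(q_grid, float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q_grid must lie strictly inside (0, 1)")
    if gamma == 0.0:
        return 1.0 / q
    if n_quad is None:
        # piecewise-exponential interval error ~ |gamma| * (1/n_quad)^2 / 4
        n_quad = int(min(1e5, max(2e4, 300.0 * np.sqrt(abs(gamma)))))
    base = np.linspace(0.0, 1.0, n_quad)
    fine = np.union1d(base, q)

    a, b = 4.0 * gamma * h, 2.0 * gamma * (1.0 - 2.0 * h)
    g = -(a * fine + b * fine * fine)
    logI = _suffix_logsumexp(_log_interval_integrals(fine, g))
    idx = np.searchsorted(fine, q)
    # prefactor exponent is -g(q)
    log_f = -g[idx] + logI[idx] - logI[0] - np.log(q) - np.log1p(-q)
    return np.exp(log_f)


def equilibrium_density(
    gamma: float, h: float, pts: int = 300, crwd: float = 8.0
) -> FrequencyDensity:
    """Quasi-stationary density on a sigmoid grid, zero at the boundaries."""
    xx = frequency_grid(pts, crwd)
    phi = np.zeros_like(xx)
    phi[1:-1] = quasi_stationary_density(gamma, h, xx[1:-1])
    return FrequencyDensity(xx, phi)


# ---------------------------------------------------------------------------
# transient integration through a demography
# ---------------------------------------------------------------------------

def _drift_sel_operator(xx: np.ndarray, nu: float, gamma: float, h: float):
    """Tridiagonal Fokker-Planck operator on grid xx (absorbing boundaries).

    The flux through each cell face is discretized in the conservative form

        F = M(x) [ (1-d) phi_j + d phi_{j+1} ] - (D_{j+1} phi_{j+1} - D_j phi_j)/dx,

    with D(x) = x(1-x)/(2 nu) evaluated at the *nodes*.  Differencing D*phi
    (smooth even where phi ~ 1/x diverges) makes the neutral equilibrium
    phi = theta/x an exact discrete steady state together with the standard
    boundary mutation influx.  The advective weight d is Chang-Cooper
    (exponential-fitting) in the face Peclet number, which upwinds
    automatically under strong selection.  Returns coefficients for interior
    nodes 1..M-1, with phi[0] = phi[M] = 0.
    """
    xm = 0.5 * (xx[:-1] + xx[1:])          # face midpoints
    dx = np.diff(xx)
    Dn = xx * (1.0 - xx) / (2.0 * nu)      # node diffusion coefficients
    Df = xm * (1.0 - xm) / (2.0 * nu)      # face diffusion (for Peclet only)
    adv = 2.0 * gamma * xm * (1.0 - xm) * (h + (1.0 - 2.0 * h) * xm)
    w = adv * dx / Df
    # Chang-Cooper weight: delta = 1/w - 1/expm1(w), -> 1/2 as w -> 0
    delta = np.empty_like(w)
    small = np.abs(w) < 1e-8
    delta[small] = 0.5
    ws = w[~small]
    with np.errstate(over="ignore"):
        delta[~small] = 1.0 / ws - 1.0 / np.expm1(ws)
    delta[w > 700] = 0.0
    delta[w < -700] = 1.0
    P = adv * (1.0 - delta) + Dn[:-1] / dx  # flux coefficient on phi_j
    Q = adv * delta - Dn[1:] / dx           # flux coefficient on phi_{j+1}

    hh = 0.5 * (xx[2:] - xx[:-2])          # cell widths of interior nodes
    lower = P[:-1] / hh                    # multiplies phi_{j-1}
    diag = -(P[1:] - Q[:-1]) / hh
    upper = -Q[1:] / hh                    # multiplies phi_{j+1}
    return lower, diag, upper, hh


def _timestep(gamma: float, dt_fac: float) -> float:
    return dt_fac / (1.0 + abs(gamma) / 25.0)


def evolve_density(
    initial: FrequencyDensity,
    demography: DemographicModel,
    gamma: float,
    h: float,
    theta_unit: float = 1.0,
    dt_fac: float = 0.02,
) -> FrequencyDensity:
    """Integrate the forward diffusion through the demography's epochs.

    ``initial`` is typically the quasi-stationary density at the ancestral
    size.  Mutation influx ``theta_unit`` feeds the q -> 0 boundary at the
    standard rate, so a neutral constant-size epoch leaves phi = theta/q
    stationary.  ``gamma`` is signed, as everywhere in this module.
    """
    xx = initial.q_grid
    phi = initial.phi.copy()
    phi[0] = phi[-1] = 0.0
    M = len(xx) - 1
    inj = np.zeros(M - 1)
    # influx of theta/2 new mutations per unit time at the first interior node
    inj[0] = theta_unit / 2.0 / xx[1] / (0.5 * (xx[2] - xx[0]))

    ab = np.zeros((3, M - 1))
    for epoch in demography.epochs:
        if epoch.relative_size_start <= 0 or epoch.relative_size_end <= 0:
            raise ValueError("non-positive relative size in epoch")
        dt = min(_timestep(gamma, dt_fac), epoch.duration / 10.0)
        nsteps = int(np.ceil(epoch.duration / dt))
        dt = epoch.duration / nsteps
        constant = epoch.growth == "constant"
        lower = diag = upper = None
        for k in range(nsteps):
            if (not constant) or lower is None:
                nu = epoch.size_at((k + 0.5) * dt)
                lower, diag, upper, _ = _drift_sel_operator(xx, nu, gamma, h)
                ab[0, 1:] = -dt * upper[:-1]
                ab[1, :] = 1.0 - dt * diag
                ab[2, :-1] = -dt * lower[1:]
            rhs = phi[1:-1] + dt * inj
            phi[1:-1] = solve_banded((1, 1), ab, rhs)
        phi[0] = phi[-1] = 0.0
    if np.any(phi < -1e-6 * max(1.0, phi.max())):
        raise RuntimeError(
            f"diffusion integration produced negative density at gamma={gamma}"
        )
    np.clip(phi, 0.0, None, out=phi)
    return FrequencyDensity(xx, phi)


# ---------------------------------------------------------------------------
# binomial sampling to an expected SFS
# ---------------------------------------------------------------------------

def expected_sfs_from_density(
    phi: FrequencyDensity, n: int, theta: float = 1.0, label: str = ""
) -> SFSpectrum:
    """Expected unfolded SFS: entry i = theta * int C(n,i) q^i (1-q)^{n-i} phi(q) dq.

    Integration is trapezoidal over the interior grid, plus analytic tail
    corrections assuming phi ~ c/q near 0 and phi ~ c'/(1-q) near 1 (the
    leading behaviors of the sojourn density).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    xx, f = phi.q_grid, phi.phi
    xi, fi = xx[1:-1], f[1:-1]
    if xx[1] > 1.0 / n:
        warnings.warn(
            f"frequency grid too coarse for n={n} (first interior point "
            f"{xx[1]:.3g} > 1/n); refine the grid",
            RuntimeWarning,
            stacklevel=2,
        )
    i = np.arange(1, n)
    log_binom = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    )[:, None]
    with np.errstate(divide="ignore"):
        log_terms = log_binom + i[:, None] * np.log(xi) + (n - i)[:, None] * np.log1p(-xi)
    integrand = np.exp(log_terms) * fi
    entries = np.trapezoid(integrand, xi, axis=1)

    # left tail: phi ~ c/q  =>  contribution c * I_x1(i, n-i+1) / i
    c_left = f[1] * xx[1]
    entries += c_left * betainc(i, n - i + 1, xx[1]) / i
    # right tail: phi ~ c'/(1-q)  =>  contribution c' * (1 - I_xM(i+1, n-i)) / (n-i)
    c_right = f[-2] * (1.0 - xx[-2])
    entries += c_right * (1.0 - betainc(i + 1, n - i, xx[-2])) / (n - i)
    return SFSpectrum(theta * entries, n=n, folded=False, label=label)


def equilibrium_expected_sfs(
    gamma: float, h: float, n: int, theta: float = 1.0, pts: int = 1000
) -> SFSpectrum:
    """Expected SFS at constant-size mutation-selection-drift equilibrium."""
    return expected_sfs_from_density(equilibrium_density(gamma, h, pts), n, theta)


def demographic_expected_sfs(
    gamma: float,
    h: float,
    demography: DemographicModel,
    n: int,
    theta: float = 1.0,
    pts: int | tuple[int, ...] = 250,
    dt_fac: float = 0.02,
) -> SFSpectrum:
    """Expected unfolded SFS after evolving through ``demography``.

    If ``pts`` is a sequence of three grid sizes, the result is Richardson-
    extrapolated (quadratically in the first grid step) toward the
    zero-spacing limit, the standard trick for making coarse diffusion grids
    accurate.
    """
    if np.ndim(pts) == 0:
        start = equilibrium_density(gamma, h, int(pts))
        final = evolve_density(start, demography, gamma, h, dt_fac=dt_fac)
        return expected_sfs_from_density(final, n, theta)
    results, steps = [], []
    for p in pts:
        start = equilibrium_density(gamma, h, int(p))
        final = evolve_density(start, demography, gamma, h, dt_fac=dt_fac)
        results.append(expected_sfs_from_density(final, n, theta).counts)
        steps.append(start.q_grid[1])
    ex = _poly_extrapolate(np.array(steps), np.vstack(results))
    return SFSpectrum(np.clip(ex, 0.0, None), n=n, folded=False)


def _poly_extrapolate(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Lagrange extrapolation of rows of ``ys`` (at abscissae xs) to x = 0."""
    out = np.zeros(ys.shape[1])
    k = len(xs)
    for j in range(k):
        w = 1.0
        for m in range(k):
            if m != j:
                w *= (0.0 - xs[m]) / (xs[j] - xs[m])
        out += w * ys[j]
    return out


# ---------------------------------------------------------------------------
# expectation grids over gamma
# ---------------------------------------------------------------------------

@dataclass
class ExpectationGrid:
    """Folded expected SFS (theta = 1) for one h over a log-spaced s grid.

    Row 0 is the neutral (gamma = 0) expectation; rows 1..n_points correspond
    to ``s_values`` mapped to gamma = 2 * N_anc * s (entered into the
    diffusion with a negative sign: deleterious).
    """

    h: float
    N_anc: float
    s_values: np.ndarray      # deleterious s, log-spaced
    expected: np.ndarray      # (n_points + 1, n//2) folded, theta=1
    n: int
    demography_id: str
    grid_meta: dict

    @property
    def gamma_values(self) -> np.ndarray:
        return 2.0 * self.N_anc * self.s_values

    @property
    def neutral_row(self) -> np.ndarray:
        return self.expected[0]

    def cache_key(self) -> str:
        meta = dict(self.grid_meta)
        desc = json.dumps(
            {
                "h": self.h,
                "N_anc": self.N_anc,
                "n": self.n,
                "demography_id": self.demography_id,
                "meta": meta,
            },
            sort_keys=True,
        )
        return hashlib.sha1(desc.encode()).hexdigest()[:16]


def build_expectation_grid(
    h: float,
    demography: DemographicModel,
    n: int,
    N_anc: float,
    s_range: tuple[float, float] = (1e-5, S_MAX),
    n_points: int = 1000,
    pts: int | tuple[int, ...] = 250,
    dt_fac: float = 0.02,
    cache_dir: str | Path | None = None,
) -> ExpectationGrid:
    """Build (or load from cache) the per-h grid of folded expected SFS.

    ``s_range`` follows the inference convention; mutations with s beyond the
    upper end are treated as not segregating and never enter the grid.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must be in [0, 1]")
    if s_range[1] > S_MAX + 1e-12:
        raise ValueError(
            f"s beyond {S_MAX} is outside the supported range of the diffusion; "
            "truncate the grid"
        )
    s_values = np.logspace(np.log10(s_range[0]), np.log10(s_range[1]), n_points)
    meta = {
        "s_range": list(s_range),
        "n_points": n_points,
        "pts": list(np.atleast_1d(pts).astype(int).tolist()),
        "dt_fac": dt_fac,
    }
    grid = ExpectationGrid(
        h=h,
        N_anc=N_anc,
        s_values=s_values,
        expected=np.empty(0),
        n=n,
        demography_id=demography.model_id,
        grid_meta=meta,
    )
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"grid_{grid.cache_key()}.npz"
        if cache_path.exists():
            with np.load(cache_path, allow_pickle=False) as z:
                grid.expected = z["expected"]
                grid.s_values = z["s_values"]
            return grid

    rows = np.empty((n_points + 1, n // 2))
    rows[0] = fold_sfs(demographic_expected_sfs(0.0, h, demography, n, 1.0, pts, dt_fac)).counts
    for j, s in enumerate(s_values):
        gamma = -2.0 * N_anc * s  # deleterious: derived allele disfavored
        sfs = demographic_expected_sfs(gamma, h, demography, n, 1.0, pts, dt_fac)
        rows[j + 1] = fold_sfs(sfs).counts
    grid.expected = rows

    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        np.savez(cache_path, expected=rows, s_values=s_values)
    return grid
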