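"""DFE and dominance inference from a folded nonsynonymous SFS.

Two families of distributions of fitness effects (DFE) over the deleterious
selection coefficient s (inference convention: mutant homozygote fitness
1 - 2s, s in [0, 0.5], s = 0.5 lethal) are fit by Poisson maximum likelihood
against precomputed per-h expectation grids:

* a gamma DFE with shape alpha and scale beta (2 free parameters), and
* a discrete DFE: a mixture of uniform distributions over five |s| bins
  (0, 1e-5], (1e-5, 1e-4], (1e-4, 1e-3], (1e-3, 1e-2], (1e-2, 0.5],
  with 4 free parameters (the proportions sum to one).

Dominance enters through which expectation grid each component integrates
over.  The dominance scan fits the discrete DFE for every combination of
per-bin h values from an allowed set (neutral bin pinned at h = 0.5),
8^4 = 4096 models in the standard configuration, and the results are
combined by Akaike-weight model averaging.

Mutations with s above the supported diffusion range (0.25) are treated as
not segregating: the part of any DFE's mass beyond 0.25 contributes nothing
to the expected SFS.  Mass below 1e-5 uses the neutral expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc

from .diffusion import ExpectationGrid, S_MAX
from .spectra import SFSpectrum, poisson_loglik

__all__ = [
    "BIN_EDGES",
    "SCAN_H_SET",
    "SINGLE_H_SET",
    "GammaDFE",
    "DiscreteDFE",
    "DominanceMap",
    "FitResult",
    "ModelAverage",
    "expected_sfs_gamma",
    "expected_sfs_discrete",
    "fit_gamma_dfe",
    "fit_discrete_dfe",
    "enumerate_and_scan",
    "compute_aic",
    "select_models",
    "akaike_model_average",
    "summarize_hs",
    "bin_mean_s",
]

#: |s| bin boundaries of the discrete DFE, inference convention
BIN_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 0.5)
BIN_NAMES = ("neutral", "nearly_neutral", "weakly_deleterious",
             "moderately_deleterious", "strongly_deleterious")

#: h values scanned per non-neutral bin in the dominance scan
SCAN_H_SET = (0.0, 0.05, 0.10, 0.15, 0.25, 0.35, 0.45, 0.50)
#: h values examined in single-dominance-coefficient analyses
SINGLE_H_SET = SCAN_H_SET + (0.75, 1.0)

#: LL drop marking the asymptotic 95% confidence set for 4 free parameters
DEFAULT_CUTOFF_LL = 4.74


def bin_mean_s(edges=BIN_EDGES) -> np.ndarray:
    """Expected |s| per bin under the within-bin uniform (arithmetic midpoint)."""
    e = np.asarray(edges)
    return (e[:-1] + e[1:]) / 2.0


@dataclass
class GammaDFE:
    """Gamma-distributed DFE over s.  ``beta`` is the scale in s units."""

    alpha: float
    beta: float
    N_anc: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma DFE parameters must be positive")

    @property
    def E_s(self) -> float:
        return self.alpha * self.beta

    @property
    def beta_scaled(self) -> float:
        """Scale in 2*N_anc units (as optimized against the gamma grid)."""
        if self.N_anc is None:
            raise ValueError("N_anc not set")
        return self.beta * 2.0 * self.N_anc

    def bin_proportions(self, edges=BIN_EDGES) -> np.ndarray:
        """Probability mass of each discrete bin under this gamma DFE."""
        cdf = gammainc(self.alpha, np.asarray(edges) / self.beta)
        return np.diff(cdf)


@dataclass
class DiscreteDFE:
    """Mixture of uniforms over the five |s| bins; proportions sum to 1."""

    proportions: np.ndarray
    edges: tuple = BIN_EDGES

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        if len(self.proportions) != len(self.edges) - 1:
            raise ValueError("need one proportion per bin")
        if np.any(self.proportions < -1e-12):
            raise ValueError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        np.clip(self.proportions, 0.0, None, out=self.proportions)


@dataclass(frozen=True)
class DominanceMap:
    """One dominance coefficient per DFE bin (neutral bin first)."""

    h_per_bin: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "h_per_bin", tuple(float(h) for h in self.h_per_bin))
        if any(not 0.0 <= h <= 1.0 for h in self.h_per_bin):
            raise ValueError("h values must lie in [0, 1]")

    @property
    def monotone(self) -> bool:
        """True iff h is non-increasing from the neutral to the strong bin."""
        h = self.h_per_bin
        return all(h[i] >= h[i + 1] for i in range(len(h) - 1))

    @classmethod
    def uniform(cls, h: float, n_bins: int = 5) -> "DominanceMap":
        return cls((h,) * n_bins)


@dataclass
class FitResult:
    """One maximized model: parameters, likelihood and AIC bookkeeping."""

    model: object                      # GammaDFE or DiscreteDFE
    dominance: DominanceMap
    LL: float
    k: int
    n_starts: int
    label: str = ""

    def __post_init__(self) -> None:
        self.AIC = compute_aic(self.LL, self.k)

    @property
    def proportions(self) -> np.ndarray:
        if isinstance(self.model, DiscreteDFE):
            return self.model.proportions
        return self.model.bin_proportions()

    @property
    def mean_h(self) -> float:
        """Proportion-weighted average dominance coefficient."""
        return float(np.dot(self.proportions, self.dominance.h_per_bin))


@dataclass
class ModelAverage:
    weights: np.ndarray
    averaged_proportions: np.ndarray
    averaged_h: np.ndarray
    n_models: int

    @property
    def average_h_overall(self) -> float:
        return float(np.dot(self.averaged_proportions, self.averaged_h))


def compute_aic(LL: float, k: int) -> float:
    """AIC = 2k - 2 LL."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * LL


# ---------------------------------------------------------------------------
# expected SFS under a DFE
# ---------------------------------------------------------------------------

def _uniform_bin_row(grid: ExpectationGrid, lo: float, hi: float) -> np.ndarray:
    """Average of grid rows over s ~ Uniform(lo, hi], as a theta=1 folded SFS.

    Mass beyond the grid's supported s range contributes zero (not
    segregating); mass below the grid's smallest s uses the neutral row.
    """
    s = grid.s_values
    rows = grid.expected[1:]
    width = hi - lo
    out = np.zeros(grid.expected.shape[1])
    # sub-neutral sliver
    lo_eff = max(lo, s[0])
    if lo < s[0]:
        out += (min(hi, s[0]) - lo) / width * grid.neutral_row
    hi_eff = min(hi, s[-1])
    if hi_eff <= lo_eff:
        return out
    # integrate rows over [lo_eff, hi_eff] by trapezoid in s, with
    # log-linear interpolation at the cut points
    inner = (s > lo_eff) & (s < hi_eff)
    s_seg = np.concatenate(([lo_eff], s[inner], [hi_eff]))
    r_lo = _interp_row(grid, lo_eff)
    r_hi = _interp_row(grid, hi_eff)
    rows_seg = np.vstack([r_lo, rows[inner], r_hi])
    out += np.trapezoid(rows_seg, s_seg, axis=0) / width
    return out


def _interp_row(grid: ExpectationGrid, s0: float) -> np.ndarray:
    """Log-linear interpolation of grid rows at selection coefficient s0."""
    s = grid.s_values
    rows = grid.expected[1:]
    j = int(np.clip(np.searchsorted(s, s0), 1, len(s) - 1))
    t = (np.log(s0) - np.log(s[j - 1])) / (np.log(s[j]) - np.log(s[j - 1]))
    return (1.0 - t) * rows[j - 1] + t * rows[j]


def expected_sfs_gamma(
    dfe: GammaDFE, h: float, grid: ExpectationGrid, theta_NS: float
) -> SFSpectrum:
    """Expected folded SFS under a gamma DFE at dominance h.

    Quadrature over the grid's log-spaced s values weighted by the gamma
    density; mass below the grid floor goes to the neutral expectation, mass
    above s = 0.25 is dropped.
    """
    if abs(grid.h - h) > 1e-9:
        raise ValueError(f"grid was built for h={grid.h}, requested h={h}")
    s = grid.s_values
    pdf = _gamma_pdf(s, dfe.alpha, dfe.beta)
    w = _trapezoid_weights(s) * pdf
    p_neut = float(gammainc(dfe.alpha, s[0] / dfe.beta))
    # renormalize the quadrature so it carries exactly the gamma mass of the
    # grid's s range; keeps sharply peaked DFEs (large alpha) exact in total
    p_grid = float(
        gammainc(dfe.alpha, s[-1] / dfe.beta) - gammainc(dfe.alpha, s[0] / dfe.beta)
    )
    tot = w.sum()
    if tot > 0 and p_grid > 0:
        w = w * (p_grid / tot)
    counts = theta_NS * (p_neut * grid.neutral_row + w @ grid.expected[1:])
    return SFSpectrum(counts, n=grid.n, folded=True, label="expected_gamma")


def _gamma_pdf(s: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    from scipy.special import gammaln as _gl

    return np.exp(
        (alpha - 1) * np.log(s) - s / beta - alpha * np.log(beta) - _gl(alpha)
    )


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2
    w[1:] += dx / 2
    return w


def discrete_bin_rows(grids: dict, dmap: DominanceMap, edges=BIN_EDGES) -> np.ndarray:
    """Per-bin folded expectation rows (theta = 1) under per-bin dominance.

    ``grids`` maps h -> ExpectationGrid.  The neutral bin always uses the
    neutral (gamma = 0) expectation, which is identical across grids.
    """
    missing = [h for h in dmap.h_per_bin if h not in grids]
    if missing:
        raise KeyError(
            f"no expectation grid built for h values {sorted(set(missing))}; "
            f"available: {sorted(grids)}"
        )
    rows = [grids[dmap.h_per_bin[0]].neutral_row]
    for b in range(1, len(edges) - 1):
        g = grids[dmap.h_per_bin[b]]
        rows.append(_uniform_bin_row(g, edges[b], edges[b + 1]))
    return np.vstack(rows)


def expected_sfs_discrete(
    dfe: DiscreteDFE, dmap: DominanceMap, grids: dict, theta_NS: float
) -> SFSpectrum:
    """Expected folded SFS under a discrete DFE with per-bin dominance."""
    rows = discrete_bin_rows(grids, dmap, dfe.edges)
    counts = theta_NS * (dfe.proportions @ rows)
    n = next(iter(grids.values())).n
    return SFSpectrum(counts, n=n, folded=True, label="expected_discrete")


# ---------------------------------------------------------------------------
# maximum-likelihood fits
# ---------------------------------------------------------------------------

def fit_gamma_dfe(
    nonsyn_sfs: SFSpectrum,
    h: float,
    grid: ExpectationGrid,
    theta_NS: float,
    n_starts: int = 25,
    seed: int = 0,
    bounds: tuple = ((1e-3, 10.0), (1e-7, 1.0)),
) -> FitResult:
    """MLE of (alpha, beta) for a gamma DFE at fixed dominance h."""
    _check_grid(nonsyn_sfs, grid)
    rng = np.random.default_rng(seed)
    (alo, ahi), (blo, bhi) = bounds
    log_bounds = [(np.log(alo), np.log(ahi)), (np.log(blo), np.log(bhi))]

    def negll(logab):
        dfe = GammaDFE(*np.exp(logab), N_anc=grid.N_anc)
        ll = poisson_loglik(nonsyn_sfs, expected_sfs_gamma(dfe, h, grid, theta_NS))
        return -ll if np.isfinite(ll) else 1e12

    best = None
    fails = []
    for k in range(n_starts):
        if k == 0:
            x0 = np.log([0.2, 1e-3])
        else:
            x0 = np.array(
                [rng.uniform(*log_bounds[0]), rng.uniform(*log_bounds[1])]
            )
        res = minimize(negll, x0, method="L-BFGS-B", bounds=log_bounds,
                       options={"maxiter": 300, "ftol": 1e-12})
        fails.append((res.fun, res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(f"all gamma-DFE starts failed: {fails}")
    alpha, beta = np.exp(best.x)
    return FitResult(
        model=GammaDFE(alpha, beta, N_anc=grid.N_anc),
        dominance=DominanceMap.uniform(h),
        LL=-best.fun,
        k=2,
        n_starts=n_starts,
        label=f"gamma_h{h:g}",
    )


def _check_grid(sfs: SFSpectrum, grid: ExpectationGrid) -> None:
    if not sfs.folded:
        raise ValueError("DFE fits expect a folded spectrum")
    if sfs.n != grid.n:
        raise ValueError(f"sample-size mismatch: sfs n={sfs.n}, grid n={grid.n}")


def _fit_proportions(
    x: np.ndarray, rows: np.ndarray, theta_NS: float, n_starts: int, rng
) -> tuple[np.ndarray, float]:
    """Concave Poisson ML over the proportion simplex (SLSQP with gradient)."""
    nb = rows.shape[0]
    R = theta_NS * rows

    def negll_grad(p):
        m = p @ R
        bad = m <= 0
        if np.any(bad & (x > 0)):
            return 1e12, np.zeros(nb)
        ok = ~bad
        ll = np.sum(x[ok] * np.log(m[ok]) - m[ok])
        g = -(R[:, ok] @ (x[ok] / m[ok] - 1.0))
        return -ll, g

    cons = {"type": "eq", "fun": lambda p: p.sum() - 1.0, "jac": lambda p: np.ones(nb)}
    best_p, best_f = None, np.inf
    for k in range(n_starts):
        p0 = np.full(nb, 1.0 / nb) if k == 0 else rng.dirichlet(np.ones(nb))
        res = minimize(
            negll_grad, p0, jac=True, method="SLSQP",
            bounds=[(0.0, 1.0)] * nb, constraints=[cons],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.fun < best_f:
            best_f, best_p = res.fun, res.x
    if best_p is None or best_f >= 1e12:
        raise RuntimeError("all discrete-DFE starts failed")
    p = np.clip(best_p, 0.0, None)
    return p / p.sum(), best_f


def fit_discrete_dfe(
    nonsyn_sfs: SFSpectrum,
    dmap: DominanceMap,
    grids: dict,
    theta_NS: float,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """MLE of the five bin proportions under a fixed per-bin dominance map.

    The likelihood is concave in the proportions (the expected SFS is linear
    in them), so a single start already finds the global optimum; extra
    starts are cheap insurance against solver stalls.
    """
    grid0 = next(iter(grids.values()))
    _check_grid(nonsyn_sfs, grid0)
    rng = np.random.default_rng(seed)
    rows = discrete_bin_rows(grids, dmap)
    p, negf = _fit_proportions(nonsyn_sfs.counts, rows, theta_NS, n_starts, rng)
    # add back the Poisson normalizing constant dropped inside the solver
    from scipy.special import gammaln

    const = float(np.sum(gammaln(nonsyn_sfs.counts + 1.0)))
    return FitResult(
        model=DiscreteDFE(p),
        dominance=dmap,
        LL=-negf - const,
        k=4,
        n_starts=n_starts,
        label="discrete_" + "_".join(f"{h:g}" for h in dmap.h_per_bin),
    )


# ---------------------------------------------------------------------------
# the dominance scan
# ---------------------------------------------------------------------------

def enumerate_dominance_maps(
    h_set=SCAN_H_SET, neutral_h: float = 0.5, n_free_bins: int = 4
):
    """All per-bin dominance maps with the neutral bin pinned, sorted."""
    for combo in itertools.product(sorted(h_set), repeat=n_free_bins):
        yield DominanceMap((neutral_h,) + combo)


def enumerate_and_scan(
    nonsyn_sfs: SFSpectrum,
    grids: dict,
    theta_NS: float,
    h_set=SCAN_H_SET,
    seed: int = 0,
    n_starts: int = 1,
    progress: bool = False,
) -> list[FitResult]:
    """Fit the discrete DFE for every dominance combination (8^4 = 4096).

    Deterministic ordering (lexicographic in the four free h values); a model
    whose optimization fails is recorded with LL = -inf and flagged via its
    label rather than aborting the scan.
    """
    from scipy.special import gammaln

    grid0 = next(iter(grids.values()))
    _check_grid(nonsyn_sfs, grid0)
    x = nonsyn_sfs.counts
    const = float(np.sum(gammaln(x + 1.0)))
    # all (h, bin) expectation rows up front: the scan then only mixes them
    bin_rows = {}
    for h in sorted(set(h_set)):
        for b in range(1, 5):
            bin_rows[(h, b)] = _uniform_bin_row(grids[h], BIN_EDGES[b], BIN_EDGES[b + 1])
    neutral_row = grid0.neutral_row
    results = []
    maps = list(enumerate_dominance_maps(h_set))
    rng = np.random.default_rng(seed)
    for idx, dmap in enumerate(maps):
        rows = np.vstack(
            [neutral_row] + [bin_rows[(dmap.h_per_bin[b], b)] for b in range(1, 5)]
        )
        try:
            p, negf = _fit_proportions(x, rows, theta_NS, n_starts, rng)
            res = FitResult(
                model=DiscreteDFE(p), dominance=dmap, LL=-negf - const,
                k=4, n_starts=n_starts,
            )
        except RuntimeError:
            res = FitResult(
                model=DiscreteDFE(np.full(5, 0.2)), dominance=dmap, LL=-np.inf,
                k=4, n_starts=n_starts, label="FAILED",
            )
        results.append(res)
        if progress and (idx + 1) % 512 == 0:
            print(f"  scan: {idx + 1}/{len(maps)} models fit")
    return results


def select_models(
    results: list[FitResult],
    cutoff_LL: float = DEFAULT_CUTOFF_LL,
    monotonic_only: bool = False,
) -> list[FitResult]:
    """Models within ``cutoff_LL`` units of the best LL (optionally monotone h).

    Ties at the maximum are broken by lower AIC, then lexicographic h order,
    so the selection is deterministic.
    """
    if not results:
        raise ValueError("empty result list")
    finite = [r for r in results if np.isfinite(r.LL)]
    best = max(finite, key=lambda r: (r.LL, -r.AIC, tuple(-h for h in r.dominance.h_per_bin)))
    kept = [r for r in finite if r.LL >= best.LL - cutoff_LL]
    if monotonic_only:
        kept = [r for r in kept if r.dominance.monotone]
    return kept


def akaike_model_average(results: list[FitResult]) -> ModelAverage:
    """Akaike-weight average of DFE proportions and per-bin h."""
    if not results:
        raise ValueError("cannot average an empty model list")
    aic = np.array([r.AIC for r in results])
    d = aic - aic.min()
    w = np.exp(-d / 2.0)
    w /= w.sum()
    props = np.array([r.proportions for r in results])
    hs = np.array([r.dominance.h_per_bin for r in results])
    return ModelAverage(
        weights=w,
        averaged_proportions=w @ props,
        averaged_h=w @ hs,
        n_models=len(results),
    )


def summarize_hs(result: FitResult, edges=BIN_EDGES) -> dict:
    """h and h*s summaries of a discrete fit.

    ``mean_h`` weights per-bin h by the inferred proportions; ``mean_hs_space``
    is the unweighted bin average of h * E[s | bin] (the location of the model
    in h*s space); ``mean_hs_inferred`` weights the same products by the
    inferred proportions.  E[s | bin] is the arithmetic bin midpoint.
    """
    if not isinstance(result.model, DiscreteDFE):
        raise ValueError("summarize_hs applies to discrete-DFE fits")
    h = np.asarray(result.dominance.h_per_bin)
    p = result.proportions
    es = bin_mean_s(edges)
    return {
        "mean_h": float(p @ h),
        "mean_hs_space": float(np.mean(h * es)),
        "mean_hs_inferred": float(p @ (h * es)),
    }
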