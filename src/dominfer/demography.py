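"""Fit the three-epoch demographic model to a folded synonymous SFS.

The model is a bottleneck (relative size N1 for time T1), a recovery epoch
(N2 for T2), and recent exponential growth from N2 to NC over TC, all sizes
relative to the ancestral population and times in 2*N_anc generations.  The
scaled synonymous mutation rate theta_S is profiled out analytically: for a
Poisson likelihood the optimal scaling of a unit-theta expectation is the
ratio of observed to expected totals.  From theta_S the ancestral size
follows as N_anc = theta_S / (4 mu L_S), and the nonsynonymous rate as
theta_NS = 2.31 * theta_S (the assumed ratio of nonsynonymous to synonymous
mutational targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .demomodel import DemographicModel, Epoch, three_epoch_model
from .diffusion import demographic_expected_sfs
from .spectra import SFSpectrum, fold_sfs, poisson_loglik

__all__ = [
    "ScalingParams",
    "DemographyFit",
    "optimal_theta",
    "three_epoch_expected_sfs",
    "fit_three_epoch",
    "derive_scaling",
    "three_epoch_model",
]

#: ratio of nonsynonymous to synonymous mutational target sizes
LNS_LS_RATIO = 2.31

_PARAM_NAMES = ("N1", "T1", "N2", "T2", "NC", "TC")
_DEFAULT_BOUNDS = {
    "N1": (1e-3, 10.0),
    "T1": (1e-3, 1.0),
    "N2": (1e-3, 10.0),
    "T2": (1e-3, 1.0),
    "NC": (1e-2, 200.0),
    "TC": (1e-3, 0.5),
}


@dataclass
class ScalingParams:
    """Mutation-rate scaling constants linking theta to census quantities."""

    theta_S: float
    theta_NS: float
    mu: float
    L_S: float
    N_anc: float

    def __post_init__(self) -> None:
        if min(self.theta_S, self.mu, self.L_S) <= 0:
            raise ValueError("scaling inputs must be positive")


@dataclass
class DemographyFit:
    model: DemographicModel
    params: dict
    theta_S: float
    loglik: float
    n_starts: int
    per_start: list


def derive_scaling(theta_S: float, mu: float, L_S: float) -> ScalingParams:
    """N_anc = theta_S / (4 mu L_S); theta_NS = 2.31 theta_S."""
    if theta_S <= 0 or mu <= 0 or L_S <= 0:
        raise ValueError("theta_S, mu and L_S must all be positive")
    return ScalingParams(
        theta_S=theta_S,
        theta_NS=LNS_LS_RATIO * theta_S,
        mu=mu,
        L_S=L_S,
        N_anc=theta_S / (4.0 * mu * L_S),
    )


def optimal_theta(observed: SFSpectrum, unit_expected: SFSpectrum) -> float:
    """Analytic Poisson-MLE scaling: sum(observed) / sum(expected at theta=1)."""
    tot = unit_expected.counts.sum()
    if tot <= 0:
        raise ValueError("unit expectation has zero total")
    return float(observed.counts.sum() / tot)


def three_epoch_expected_sfs(
    params: dict, n: int, pts=(150, 225, 300), dt_fac: float = 0.02
) -> SFSpectrum:
    """Folded neutral expected SFS (theta = 1) under a three-epoch model."""
    model = three_epoch_model(*(params[k] for k in _PARAM_NAMES))
    return fold_sfs(demographic_expected_sfs(0.0, 0.5, model, n, 1.0, pts, dt_fac))


def fit_three_epoch(
    syn_sfs: SFSpectrum,
    n_starts: int = 30,
    seed: int = 0,
    init: dict | None = None,
    bounds: dict | None = None,
    pts=(150, 225, 300),
    dt_fac: float = 0.02,
) -> DemographyFit:
    """Maximum-likelihood three-epoch fit to a folded synonymous SFS.

    Runs ``n_starts`` independent bounded quasi-Newton optimizations on
    log-parameters, each from a multiplicatively perturbed start (factors up
    to 2), and keeps the best.  theta_S is profiled out analytically at every
    evaluation.
    """
    if not syn_sfs.folded:
        raise ValueError("fit_three_epoch expects a folded spectrum")
    if syn_sfs.n < 4:
        raise ValueError("sample size too small for a demographic fit")
    rng = np.random.default_rng(seed)
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.log([b[k][0] for k in _PARAM_NAMES])
    hi = np.log([b[k][1] for k in _PARAM_NAMES])
    base = init or {"N1": 0.2, "T1": 0.05, "N2": 1.0, "T2": 0.05, "NC": 5.0, "TC": 0.02}
    x0 = np.log([base[k] for k in _PARAM_NAMES])

    def negll(logp: np.ndarray) -> float:
        params = dict(zip(_PARAM_NAMES, np.exp(logp)))
        try:
            unit = three_epoch_expected_sfs(params, syn_sfs.n, pts, dt_fac)
        except (RuntimeError, ValueError):
            return 1e12
        theta = optimal_theta(syn_sfs, unit)
        ll = poisson_loglik(syn_sfs, unit.copy(counts=theta * unit.counts))
        return -ll if np.isfinite(ll) else 1e12

    per_start = []
    best = None
    for k in range(n_starts):
        start = x0 if k == 0 else np.clip(x0 + np.log(rng.uniform(0.5, 2.0, 6)), lo, hi)
        res = minimize(
            negll,
            start,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200, "ftol": 1e-10},
        )
        per_start.append({"start": np.exp(start), "fun": res.fun, "success": res.success})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"all {n_starts} optimizer starts failed; diagnostics: {per_start}"
        )
    logp = best.x
    at_bound = np.any(np.isclose(logp, lo, atol=1e-6) | np.isclose(logp, hi, atol=1e-6))
    if at_bound:
        warnings.warn("demographic MLE pinned at a parameter bound", RuntimeWarning, stacklevel=2)
    params = dict(zip(_PARAM_NAMES, np.exp(logp)))
    unit = three_epoch_expected_sfs(params, syn_sfs.n, pts, dt_fac)
    theta = optimal_theta(syn_sfs, unit)
    model = three_epoch_model(*(params[k] for k in _PARAM_NAMES))
    return DemographyFit(
        model=model,
        params=params,
        theta_S=theta,
        loglik=-best.fun,
        n_starts=n_starts,
        per_start=per_start,
    )
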