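"""Independent oracles used by the test suite.

These deliberately share no code with the package's diffusion machinery:
expected spectra are computed by direct linear algebra on the discrete
Wright-Fisher binomial transition matrix (selection applied through exact
genotype fitnesses), sampled down hypergeometrically.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, hypergeom


def _qprime(N: int, s: float, h: float) -> np.ndarray:
    """Deterministic post-selection allele frequency, fitnesses 1 / 1-2sh / 1-2s."""
    q = np.arange(2 * N + 1) / (2 * N)
    w_bar = (1 - q) ** 2 + 2 * q * (1 - q) * (1 - 2 * s * h) + q**2 * (1 - 2 * s)
    return (q * (1 - q) * (1 - 2 * s * h) + q**2 * (1 - 2 * s)) / w_bar


def _step_matrix(N: int, s: float, h: float) -> np.ndarray:
    qp = _qprime(N, s, h)
    return binom.pmf(np.arange(2 * N + 1)[None, :], 2 * N, qp[:, None])


def wf_matrix_sfs(
    N_anc: int,
    s: float,
    h: float,
    n: int,
    epochs: list[tuple[int, int]] = (),
    theta: float = 1.0,
    folded: bool = True,
) -> np.ndarray:
    """Expected sample SFS from the discrete WF model.

    Equilibrium at diploid size ``N_anc`` (influx theta/2 singletons per
    generation), then each (N, generations) epoch with influx scaled by
    N / N_anc; finally hypergeometric down-sampling to ``n`` chromosomes.
    """
    T = _step_matrix(N_anc, s, h)
    inj = np.zeros(2 * N_anc - 1)
    inj[0] = theta / 2
    m = np.linalg.solve(np.eye(2 * N_anc - 1) - T[1:-1, 1:-1].T, inj)
    Ncur = N_anc
    for N, gens in epochs:
        if N != Ncur:
            qold = np.arange(1, 2 * Ncur) / (2 * Ncur)
            P = binom.pmf(np.arange(2 * N + 1)[None, :], 2 * N, qold[:, None])
            m = (m @ P)[1:-1]
            Ncur = N
        Tt = _step_matrix(N, s, h)[1:-1, 1:-1].T
        injN = np.zeros(2 * N - 1)
        injN[0] = theta / 2 * N / N_anc
        for _ in range(gens):
            m = Tt @ m + injN
    jj = np.arange(1, 2 * Ncur)
    E = np.array(
        [np.sum(m * hypergeom.pmf(i, 2 * Ncur, jj, n)) for i in range(1, n)]
    )
    if not folded:
        return E
    out = np.zeros(n // 2)
    for i in range(1, n // 2 + 1):
        out[i - 1] = E[i - 1] + (E[n - i - 1] if i < n - i else 0.0)
    return out


def quasi_stationary_reference(q: float, gamma: float, h: float) -> float:
    """Sojourn density by adaptive quadrature of the printed integrals.

    Only valid where exp(4|gamma|) does not overflow; the tests restrict the
    random draws accordingly.
    """
    from scipy.integrate import quad

    a, b = 4 * gamma * h, 2 * gamma * (1 - 2 * h)
    num = quad(lambda e: np.exp(-a * e - b * e * e), q, 1,
               epsabs=1e-300, epsrel=1e-12, limit=200)[0]
    den = quad(lambda e: np.exp(-a * e - b * e * e), 0, 1,
               epsabs=1e-300, epsrel=1e-12, limit=200)[0]
    return np.exp(a * q + b * q * q) / (q * (1 - q)) * num / den
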