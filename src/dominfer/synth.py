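"""Synthetic data generation: every test input the pipeline needs.

Two generators are provided:

* :func:`sample_poisson_sfs` draws folded spectra entry-wise from the Poisson
  random-field model itself (each entry Poisson with mean equal to the model's
  expected SFS) -- the exact generative mirror of the likelihood used in
  fitting, at the study's theta scale by default.
* :func:`make_validation_dataset` forward-simulates nonsynonymous sites with
  the Wright-Fisher engine (linkage, drift and selection all realized
  explicitly) under a single-population bottleneck-plus-growth history, for
  validating the dominance scan end to end against data *not* generated from
  the fitted model family.

Defaults mirror the study conditions at a reduced, workstation-scale size;
every function takes an explicit seed and regenerating with the same seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .demomodel import DemographicModel, three_epoch_model
from .dfe import DiscreteDFE, DominanceMap, expected_sfs_discrete  # noqa: F401
from .spectra import SFSpectrum, write_sfs
from .wf import GenomeModel, run_single_pop_simulation

__all__ = [
    "SyntheticDataset",
    "DESK_DEMOGRAPHY",
    "DESK_DEMOGRAPHY_PARAMS",
    "desk_truth",
    "sample_poisson_sfs",
    "make_validation_dataset",
    "make_toy_fixtures",
]

#: reduced-scale three-epoch history used across the test-suite: a 5x
#: bottleneck, partial recovery, then ~6x recent exponential growth
DESK_DEMOGRAPHY_PARAMS = {
    "N1": 0.2, "T1": 0.05, "N2": 0.7, "T2": 0.06, "NC": 4.0, "TC": 0.03,
}
DESK_DEMOGRAPHY: DemographicModel = three_epoch_model(
    **DESK_DEMOGRAPHY_PARAMS
)


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth that produced it."""

    syn_sfs: SFSpectrum | None
    nonsyn_sfs: SFSpectrum
    truth: dict
    seed: int
    provenance: str  # "prf_poisson" | "forward_sim"


def desk_truth(theta_S: float = 4000.0, n: int = 40) -> dict:
    """Study-scale truth configuration for Poisson-sampled datasets.

    theta_S = 4000 gives segregating-site totals of the same order as the
    human synonymous SFS, so the power characteristics of fits to these
    datasets resemble the real analysis.
    """
    return {
        "demography": DESK_DEMOGRAPHY,
        "demography_params": dict(DESK_DEMOGRAPHY_PARAMS),
        "theta_S": theta_S,
        "theta_NS": 2.31 * theta_S,
        "n": n,
    }


def sample_poisson_sfs(
    demography: DemographicModel,
    dfe: DiscreteDFE,
    dmap: DominanceMap,
    theta_S: float,
    n: int,
    grids: dict,
    seed: int,
) -> SyntheticDataset:
    """Poisson-sample folded synonymous and nonsynonymous spectra.

    The synonymous spectrum is drawn from the neutral expectation at
    theta_S; the nonsynonymous spectrum from the discrete-DFE expectation at
    theta_NS = 2.31 theta_S.  ``grids`` maps h -> ExpectationGrid built for
    ``demography`` and ``n``.
    """
    rng = np.random.default_rng(seed)
    theta_NS = 2.31 * theta_S
    grid0 = next(iter(grids.values()))
    syn_mean = theta_S * grid0.neutral_row
    nonsyn_mean = expected_sfs_discrete(dfe, dmap, grids, theta_NS).counts
    syn = SFSpectrum(rng.poisson(syn_mean).astype(float), n=n, folded=True,
                     label="synonymous")
    nonsyn = SFSpectrum(rng.poisson(nonsyn_mean).astype(float), n=n, folded=True,
                        label="nonsynonymous")
    return SyntheticDataset(
        syn_sfs=syn,
        nonsyn_sfs=nonsyn,
        truth={
            "demography": demography,
            "dfe": dfe,
            "dominance": dmap,
            "theta_S": theta_S,
            "theta_NS": theta_NS,
            "n": n,
        },
        seed=seed,
        provenance="prf_poisson",
    )


def make_validation_dataset(
    dfe: DiscreteDFE,
    dmap: DominanceMap,
    n: int = 40,
    N_anc: int = 350,
    genes_total: int = 8000,
    n_chromosomes: int = 11,
    seed: int = 0,
    burnin_factor: float = 5.0,
    variable_h: bool = False,
) -> SyntheticDataset:
    """Forward-simulated nonsynonymous SFS under the desk-scale demography.

    The Wright-Fisher engine runs the same relative size history as
    :data:`DESK_DEMOGRAPHY` (converted to generations at ``N_anc``), then a
    sample of ``n`` haplotypes yields the folded nonsynonymous SFS.  The
    matching theta_NS for inference is 4 * N_anc * mu_del * L.
    """
    genome = GenomeModel(n_chromosomes=n_chromosomes, genes_total=genes_total)
    p = DESK_DEMOGRAPHY_PARAMS
    two_n = 2 * N_anc
    epochs = []
    for size, dur in ((p["N1"], p["T1"]), (p["N2"], p["T2"])):
        epochs.append((max(2, round(size * N_anc)), max(1, round(dur * two_n))))
    # exponential growth realized as per-generation geometric interpolation
    g_gens = max(1, round(p["TC"] * two_n))
    ratio = p["NC"] / p["N2"]
    for t in range(1, g_gens + 1):
        epochs.append(
            (max(2, round(p["N2"] * N_anc * ratio ** (t / g_gens))), 1)
        )
    counts = run_single_pop_simulation(
        genome, N_anc, epochs, dfe, dmap, n, seed=seed,
        variable_h=variable_h, burnin_factor=burnin_factor,
    )
    unfolded = SFSpectrum(counts, n=n, folded=False, label="nonsynonymous")
    from .spectra import fold_sfs

    theta_NS = 4.0 * N_anc * genome.mu_del * genome.total_length
    return SyntheticDataset(
        syn_sfs=None,
        nonsyn_sfs=fold_sfs(unfolded),
        truth={
            "demography": DESK_DEMOGRAPHY,
            "dfe": dfe,
            "dominance": dmap,
            "theta_NS": theta_NS,
            "N_anc": N_anc,
            "n": n,
        },
        seed=seed,
        provenance="forward_sim",
    )


def make_toy_fixtures(out_dir) -> dict:
    """Write deterministic miniature SFS/config fixtures for unit tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    theta = 100.0
    n = 12
    neutral = SFSpectrum(theta / np.arange(1, n), n=n, folded=False,
                         label="neutral_expectation")
    paths["neutral_expected"] = out / "neutral_expected.txt"
    write_sfs(neutral, paths["neutral_expected"])
    rng = np.random.default_rng(12345)
    observed = SFSpectrum(
        rng.poisson(theta / np.arange(1, n)).astype(float), n=n, folded=False,
        label="toy_observed",
    )
    paths["toy_observed"] = out / "toy_observed.txt"
    write_sfs(observed, paths["toy_observed"])
    paths["toy_dadi"] = out / "toy_observed.fs"
    write_sfs(observed, paths["toy_dadi"], dialect="dadi_fs")
    return paths
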