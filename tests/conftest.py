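"""Shared fixtures.  The expensive session fixtures (expectation grids, the
forward-simulated validation dataset, and the 25-replicate load study) are
built once and reused by both the module tests and the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from dominfer.dfe import SCAN_H_SET
from dominfer.models import simulation_model
from dominfer.synth import DESK_DEMOGRAPHY, make_validation_dataset
from dominfer.wf import GenomeModel, TwoPopDemography, run_two_pop_simulation
from dominfer.workflow import load_grids

#: haploid sample size and ancestral size of the Poisson-sampled test data
DESK_N = 40
DESK_N_ANC = 5000.0
DESK_THETA_S = 4000.0

#: ancestral size of the forward-simulated validation data
VAL_N_ANC = 350

#: frozen conditions of the reduced-scale two-population load study
LOAD_GENOME = GenomeModel(n_chromosomes=11, genes_total=3000)
LOAD_RESCALE = 24
LOAD_SEED = 2026
LOAD_REPLICATES = 25


@pytest.fixture(scope="session")
def desk_grids(tmp_path_factory):
    """Expectation grids for the h values the preset models use (n=40)."""
    cache = tmp_path_factory.mktemp("grids_desk")
    return load_grids(
        [0.05, 0.15, 0.25, 0.45, 0.5], DESK_DEMOGRAPHY, DESK_N, DESK_N_ANC,
        cache, n_points=150, pts=(300, 450, 600),
    )


@pytest.fixture(scope="session")
def val_grids(tmp_path_factory):
    """Grids for the full scan h set at the forward-simulation scale."""
    cache = tmp_path_factory.mktemp("grids_val")
    return load_grids(
        SCAN_H_SET, DESK_DEMOGRAPHY, DESK_N, float(VAL_N_ANC),
        cache, n_points=200, pts=(300, 450, 600),
    )


@pytest.fixture(scope="session")
def validation_dataset():
    """Forward-simulated nonsynonymous SFS under the strongly recessive model."""
    dfe, dmap = simulation_model("strongly_recessive")
    return make_validation_dataset(
        dfe, dmap, n=DESK_N, N_anc=VAL_N_ANC, genes_total=8000, seed=42
    )


@pytest.fixture(scope="session")
def load_study():
    """25-replicate reduced-scale two-population runs for all three models."""
    demog = TwoPopDemography().rescaled(LOAD_RESCALE, size_cap=1500)
    out = {}
    for name in ("strongly_recessive", "moderately_recessive", "weakly_recessive"):
        dfe, dmap = simulation_model(name)
        out[name] = run_two_pop_simulation(
            LOAD_GENOME, demog, dfe, dmap, n_replicates=LOAD_REPLICATES,
            seed=LOAD_SEED, burnin_factor=5,
        )
    return out
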