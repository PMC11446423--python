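"""Pipeline orchestration: demography -> grids -> fits -> scan -> averages -> sims.

A single :class:`PipelineConfig` drives the full analysis.  Each stage
writes its outputs into the run directory and is skipped on rerun when its
outputs already exist, so an interrupted run resumes where it stopped (the
scan, by far the dominant cost, is the main beneficiary).  The config used
for a run is copied into the run directory alongside a log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography as demog_mod
from . import dfe as dfe_mod
from .demomodel import three_epoch_model
from .dfe import (
    SCAN_H_SET,
    DominanceMap,
    akaike_model_average,
    enumerate_and_scan,
    fit_discrete_dfe,
    fit_gamma_dfe,
    select_models,
    summarize_hs,
    bin_mean_s,
)
from .diffusion import build_expectation_grid
from .spectra import fold_sfs, read_sfs

__all__ = ["PipelineConfig", "run_full_pipeline", "scan_results_table", "load_grids"]

log = logging.getLogger("dominfer")


@dataclass
class PipelineConfig:
    """Everything a full run needs; fully serializable to YAML."""

    out_dir: str
    # inputs: either file paths...
    syn_sfs_path: str | None = None
    nonsyn_sfs_path: str | None = None
    sfs_dialect: str = "supplementary_line"
    # ...or a synthetic preset
    synthetic: dict | None = None
    # constants
    mu: float = 1.5e-8
    L_S: float | None = None
    # stage settings
    h_grid_set: tuple = SCAN_H_SET
    grid_n_points: int = 200
    grid_pts: tuple = (300, 450, 600)
    demog_n_starts: int = 30
    gamma_n_starts: int = 25
    discrete_n_starts: int = 5
    scan_n_starts: int = 1
    cutoff_LL: float = dfe_mod.DEFAULT_CUTOFF_LL
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["h_grid_set"] = tuple(d.get("h_grid_set", SCAN_H_SET))
        d["grid_pts"] = tuple(d.get("grid_pts", (300, 450, 600)))
        return cls(**d)


def load_grids(
    h_set, demography, n, N_anc, cache_dir, n_points=200, pts=(300, 450, 600)
) -> dict:
    """Build (or reload) one expectation grid per h value."""
    grids = {}
    for h in sorted(set(h_set)):
        log.info("expectation grid for h=%.2f (n=%d, %d gamma points)", h, n, n_points)
        grids[h] = build_expectation_grid(
            h, demography, n, N_anc, n_points=n_points, pts=pts, cache_dir=cache_dir
        )
    return grids


def scan_results_table(results) -> pd.DataFrame:
    """One row per scanned model: LL, proportions, h, per-bin h*E[s], summaries."""
    es = bin_mean_s()
    rows = []
    for r in results:
        h = np.asarray(r.dominance.h_per_bin)
        p = r.proportions
        row = {"LL": r.LL, "AIC": r.AIC}
        for name, v in zip(dfe_mod.BIN_NAMES, p):
            row[f"p_{name}"] = v
        for name, v in zip(dfe_mod.BIN_NAMES, h):
            row[f"h_{name}"] = v
        for name, v in zip(dfe_mod.BIN_NAMES, h * es):
            row[f"hs_{name}"] = v
        s = summarize_hs(r)
        row["average_inferred_hs"] = s["mean_hs_inferred"]
        row["mean_h_bins"] = float(np.mean(h))
        row["mean_hs"] = s["mean_hs_space"]
        row["mean_h_weighted"] = s["mean_h"]
        rows.append(row)
    return pd.DataFrame(rows)


def _average_table(results, cutoff_LL) -> pd.DataFrame:
    rows = []
    for subset, kwargs in (
        ("all_models", {}),
        ("high_ll", {"cutoff_LL": cutoff_LL}),
        ("monotonic_decay", {"cutoff_LL": cutoff_LL, "monotonic_only": True}),
    ):
        kept = select_models(results, **kwargs) if kwargs else [
            r for r in results if np.isfinite(r.LL)
        ]
        avg = akaike_model_average(kept)
        row = {"subset": subset, "n_models": avg.n_models,
               "average_h": avg.average_h_overall}
        for name, v in zip(dfe_mod.BIN_NAMES, avg.averaged_proportions):
            row[f"p_{name}"] = v
        for name, v in zip(dfe_mod.BIN_NAMES, avg.averaged_h):
            row[f"h_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run (or resume) the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)


def _run(config: PipelineConfig, out: Path) -> Path:
    config.to_yaml(out / "config.yaml")

    # ---- stage: inputs -------------------------------------------------
    if config.synthetic is not None:
        syn, nonsyn, truth_n = _synthetic_inputs(config, out)
    else:
        if not config.syn_sfs_path or not config.nonsyn_sfs_path:
            raise ValueError("config needs SFS paths or a synthetic preset")
        syn_raw = read_sfs(config.syn_sfs_path, config.sfs_dialect, "synonymous")
        nonsyn_raw = read_sfs(config.nonsyn_sfs_path, config.sfs_dialect, "nonsynonymous")
        syn = fold_sfs(syn_raw) if not syn_raw.folded else syn_raw
        nonsyn = fold_sfs(nonsyn_raw) if not nonsyn_raw.folded else nonsyn_raw
        truth_n = syn.n
    if config.L_S is None:
        # a mutational-target size must be supplied to convert theta to N_anc
        raise ValueError("config.L_S is required")

    # ---- stage: demography --------------------------------------------
    demog_path = out / "demog.yaml"
    if demog_path.exists():
        log.info("demography: reusing %s", demog_path)
        with open(demog_path) as fhh:
            dd = yaml.safe_load(fhh)
        params, theta_S = dd["params"], dd["theta_S"]
    else:
        log.info("demography: fitting three-epoch model (%d starts)", config.demog_n_starts)
        fit = demog_mod.fit_three_epoch(
            syn, n_starts=config.demog_n_starts, seed=config.seed
        )
        params, theta_S = fit.params, fit.theta_S
        with open(demog_path, "w") as fhh:
            yaml.safe_dump(
                {"params": {k: float(v) for k, v in params.items()},
                 "theta_S": float(theta_S), "LL": float(fit.loglik)}, fhh
            )
    scaling = demog_mod.derive_scaling(theta_S, config.mu, config.L_S)
    model = three_epoch_model(*(params[k] for k in ("N1", "T1", "N2", "T2", "NC", "TC")))
    log.info("theta_S=%.1f N_anc=%.0f theta_NS=%.1f",
             scaling.theta_S, scaling.N_anc, scaling.theta_NS)

    # ---- stage: grids --------------------------------------------------
    grids = load_grids(
        config.h_grid_set, model, truth_n, scaling.N_anc, out / "grids",
        n_points=config.grid_n_points, pts=config.grid_pts,
    )

    # ---- stage: reference fits ----------------------------------------
    fits_path = out / "fits.tsv"
    if not fits_path.exists():
        log.info("reference fits: gamma and discrete at h=0.5")
        gamma_fit = fit_gamma_dfe(
            nonsyn, 0.5, grids[0.5], scaling.theta_NS,
            n_starts=config.gamma_n_starts, seed=config.seed,
        )
        add_fit = fit_discrete_dfe(
            nonsyn, DominanceMap.uniform(0.5), grids, scaling.theta_NS,
            n_starts=config.discrete_n_starts, seed=config.seed,
        )
        pd.DataFrame(
            [
                {"model": "gamma_h0.5", "LL": gamma_fit.LL, "k": 2,
                 "AIC": gamma_fit.AIC, "alpha": gamma_fit.model.alpha,
                 "beta": gamma_fit.model.beta, "E_s": gamma_fit.model.E_s},
                {"model": "discrete_additive", "LL": add_fit.LL, "k": 4,
                 "AIC": add_fit.AIC,
                 **{f"p{i}": v for i, v in enumerate(add_fit.model.proportions)}},
            ]
        ).to_csv(fits_path, sep="\t", index=False)

    # ---- stage: dominance scan ----------------------------------------
    scan_path = out / "scan.tsv"
    if scan_path.exists():
        log.info("scan: reusing %s", scan_path)
        results = _results_from_table(pd.read_csv(scan_path, sep="\t"))
    else:
        log.info("scan: fitting %d dominance models", len(config.h_grid_set) ** 4)
        results = enumerate_and_scan(
            nonsyn, grids, scaling.theta_NS, h_set=config.h_grid_set,
            seed=config.seed, n_starts=config.scan_n_starts, progress=True,
        )
        scan_results_table(results).to_csv(scan_path, sep="\t", index=False)

    # ---- stage: model averaging ---------------------------------------
    avg_path = out / "averages.tsv"
    if not avg_path.exists():
        _average_table(results, config.cutoff_LL).to_csv(avg_path, sep="\t", index=False)
    log.info("pipeline complete: %s", out)
    return out


def _results_from_table(df: pd.DataFrame) -> list:
    from .dfe import DiscreteDFE, FitResult

    results = []
    for _, row in df.iterrows():
        p = np.array([row[f"p_{n}"] for n in dfe_mod.BIN_NAMES])
        h = tuple(row[f"h_{n}"] for n in dfe_mod.BIN_NAMES)
        results.append(
            FitResult(
                model=DiscreteDFE(p / p.sum()),
                dominance=DominanceMap(h),
                LL=row["LL"], k=4, n_starts=0,
            )
        )
    return results


def _synthetic_inputs(config: PipelineConfig, out: Path):
    from .models import simulation_model
    from .synth import DESK_DEMOGRAPHY, desk_truth, sample_poisson_sfs

    preset = dict(config.synthetic)
    name = preset.get("model", "strongly_recessive")
    theta_S = float(preset.get("theta_S", 4000.0))
    n = int(preset.get("n", 40))
    truth = desk_truth(theta_S, n)
    dfe, dmap = simulation_model(name)
    # truth grids only need the h values the generating model uses
    N_anc_truth = float(preset.get("N_anc", 5000.0))
    grids = load_grids(
        set(dmap.h_per_bin), DESK_DEMOGRAPHY, n, N_anc_truth, out / "grids_truth",
        n_points=config.grid_n_points, pts=config.grid_pts,
    )
    ds = sample_poisson_sfs(
        DESK_DEMOGRAPHY, dfe, dmap, theta_S, n, grids, seed=config.seed
    )
    truth_path = out / "truth.yaml"
    if not truth_path.exists():
        with open(truth_path, "w") as fhh:
            yaml.safe_dump(
                {"model": name, "theta_S": theta_S, "n": n, "N_anc": N_anc_truth,
                 "demography": truth["demography_params"], "seed": config.seed}, fhh
            )
    return ds.syn_sfs, ds.nonsyn_sfs, n
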