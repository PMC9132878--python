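"""End-to-end drivers for the two studies.

``run_full_sa`` reproduces the forward-sensitivity workflow: design ->
surrogate simulations -> GP emulators -> Q^2 validation gate -> Sobol-index
ensembles under two priors (full 11-input study) and over an EDP grid
(reduced study).  ``run_full_iuq`` reproduces the inverse workflow: joint
(log-material, pressure) emulator bank -> synthetic test battery -> NUTS
posterior battery -> I-IQR, LVV-binned and stress-stretch reports.

Each stage logs timing and failure counts; outputs are CSV/JSON plus an
archived copy of the config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .design import DESIGN_BOUNDS, two_block_design, sobol_design
from .emulator import MultiOutputEmulator, q2
from .forward import (SegmentLayout, STAR_SEGMENT, generate_test_battery,
                      generate_training_set)
from .inference import IUQ_OUTPUT_NAMES, MCMCConfig, NoiseModel, run_iuq_battery
from .sensitivity import run_sa1, run_sa2
from .stress_stretch import battery_stress_summary

logger = logging.getLogger(__name__)

__all__ = ["run_full_sa", "run_full_iuq", "fit_sa_emulators",
           "fit_iuq_emulators", "SA_OUTPUT_NAMES", "REDUCED_INPUT_NAMES"]

#: SA outputs: volume plus the pre-selected segmental strains.
SA_OUTPUT_NAMES = ("LVV", "eps_cc_star", "eps_ll_star", "eps_rr_star")
REDUCED_INPUT_NAMES = ("a", "b", "a_f", "b_f", "EDP")


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def _done(name, t0, **counts):
    logger.info("stage %s done in %.1fs %s", name, time.time() - t0,
                counts or "")


def _sa_outputs(Y: np.ndarray) -> np.ndarray:
    """Map a (n, 73) QoI matrix to the 4 SA outputs."""
    cols = [0, 1 + STAR_SEGMENT, 1 + 24 + STAR_SEGMENT, 1 + 48 + STAR_SEGMENT]
    return Y[:, cols]


def fit_sa_emulators(cfg: RunConfig):
    """Train the 11-input SA emulator bank on a two-block design and
    validate it on held-out simulations (returns bank, Q^2 dict)."""
    t0 = _stage("sa-train")
    layout = SegmentLayout(seed=cfg.seed_layout)
    design = two_block_design(cfg.n_train + cfg.n_test, seed=cfg.seed_design)
    train, test = design[:cfg.n_train], design[cfg.n_train:]
    X, Y, ok = generate_training_set(train, spec=cfg.geometry_spec,
                                     layout=layout)
    Xt, Yt, _ = generate_training_set(test, spec=cfg.geometry_spec,
                                      layout=layout)
    bank = MultiOutputEmulator(
        SA_OUTPUT_NAMES, log_dims=list(range(8)), n_restarts=cfg.gp_restarts,
        max_opt_subset=cfg.gp_max_opt_subset,
        nugget_floor=cfg.gp_nugget_floor)
    bank.fit(X, _sa_outputs(Y), random_state=cfg.seed_gp)
    pred = bank.predict(Xt)
    truth = _sa_outputs(Yt)
    scores = {name: q2(truth[:, j], pred[:, j])
              for j, name in enumerate(SA_OUTPUT_NAMES)}
    _done("sa-train", t0, n_ok=int(ok.sum()), q2=scores)
    return bank, scores


def fit_iuq_emulators(cfg: RunConfig, n_outputs: str = "iuq"):
    """Train the reduced-space bank over (a, b, a_f, b_f, EDP): material
    parameters Sobol-sampled in log space, pressure linear.  ``n_outputs``
    selects the 25 inverse-UQ outputs or the 2 SA2 outputs."""
    t0 = _stage("iuq-train")
    layout = SegmentLayout(seed=cfg.seed_layout)
    bounds = [DESIGN_BOUNDS[k] for k in REDUCED_INPUT_NAMES]
    design = sobol_design(cfg.n_train + cfg.n_test, bounds,
                          space=["log"] * 4 + ["linear"],
                          seed=cfg.seed_design + 1)
    train, test = design[:cfg.n_train], design[cfg.n_train:]
    X, Y, ok = generate_training_set(train, spec=cfg.geometry_spec,
                                     layout=layout,
                                     input_names=REDUCED_INPUT_NAMES)
    Xt, Yt, _ = generate_training_set(test, spec=cfg.geometry_spec,
                                      layout=layout,
                                      input_names=REDUCED_INPUT_NAMES)
    if n_outputs == "iuq":
        names = IUQ_OUTPUT_NAMES
        cols = list(range(25))
    else:  # volume + pre-selected circumferential strain
        names = ("LVV", "eps_cc_star")
        cols = [0, 1 + STAR_SEGMENT]
    bank = MultiOutputEmulator(
        names, log_dims=list(range(4)), n_restarts=cfg.gp_restarts,
        max_opt_subset=cfg.gp_max_opt_subset,
        nugget_floor=cfg.gp_nugget_floor)
    bank.fit(X, Y[:, cols], random_state=cfg.seed_gp)
    pred = bank.predict(Xt)
    scores = {name: q2(Yt[:, c], pred[:, j])
              for j, (name, c) in enumerate(zip(names, cols))}
    _done("iuq-train", t0, n_ok=int(ok.sum()), q2_lvv=scores["LVV"])
    return bank, scores


def _check_q2_gate(scores: dict, gate: float, targets=("LVV",)):
    bad = {k: v for k, v in scores.items() if k in targets and v < gate}
    if bad:
        raise RuntimeError(
            f"emulator validation failed the Q^2 gate ({gate}): {bad}; "
            "refusing to run the analysis on an unvalidated surrogate")


def run_full_sa(cfg: RunConfig) -> dict:
    """Design -> simulations -> emulators -> Q^2 gate -> SA1 + SA2 reports."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    bank11, scores11 = fit_sa_emulators(cfg)
    _check_q2_gate(scores11, cfg.q2_gate,
                   targets=("LVV", "eps_cc_star", "eps_ll_star"))

    t0 = _stage("sa1")
    sa1 = run_sa1(bank11, n_base=cfg.sa_n_base, n_gp_samples=cfg.sa_gp_samples,
                  seed=cfg.seed_gp)
    sa1_frames = []
    for prior, ens in sa1.items():
        s = ens.summary()
        s["prior"] = prior
        sa1_frames.append(s)
    sa1_df = pd.concat(sa1_frames, ignore_index=True)
    sa1_df.to_csv(out / "sa1_indices.csv", index=False)
    _done("sa1", t0)

    bank5, scores5 = fit_iuq_emulators(cfg, n_outputs="sa2")
    _check_q2_gate(scores5, cfg.q2_gate, targets=("LVV", "eps_cc_star"))

    t0 = _stage("sa2")
    sa2_df = run_sa2(bank5, n_base=cfg.sa_n_base,
                     n_gp_samples=cfg.sa_gp_samples, seed=cfg.seed_gp + 1)
    sa2_df.to_csv(out / "sa2_total_effects.csv", index=False)
    _done("sa2")
    with open(out / "emulator_validation.json", "w") as fh:
        json.dump({"sa1_q2": scores11, "sa2_q2": scores5,
                   "gate": cfg.q2_gate}, fh, indent=2)
    return {"sa1": sa1, "sa2": sa2_df, "q2": {**scores11, **scores5}}


def run_full_iuq(cfg: RunConfig) -> dict:
    """Emulator bank -> synthetic battery -> posterior battery -> reports."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    bank, scores = fit_iuq_emulators(cfg, n_outputs="iuq")
    _check_q2_gate(scores, cfg.q2_gate, targets=("LVV", "eps_cc_0"))

    t0 = _stage("battery")
    layout = SegmentLayout(seed=cfg.seed_layout)
    battery = generate_test_battery(
        n_cases=cfg.battery_cases, edp_list=cfg.battery_edps,
        seed=cfg.seed_noise, sigma0=cfg.sigma0,
        sigma_strain=cfg.sigma_strain, spec=cfg.geometry_spec, layout=layout)
    _done("battery", t0, n_cases=len(battery))

    t0 = _stage("mcmc-battery")
    noise = NoiseModel(sigma0_sq=max(cfg.sigma0, 1e-3) ** 2)
    mcmc_cfg = MCMCConfig(n_chains=cfg.mcmc_chains, n_warmup=cfg.mcmc_warmup,
                          n_draws=cfg.mcmc_draws,
                          max_treedepth=cfg.mcmc_max_treedepth,
                          seed=cfg.seed_mcmc)
    table = run_iuq_battery(battery, bank, noise=noise, config=mcmc_cfg,
                            keep_samples=True)
    table.to_csv(out / "iiqr_table.csv", index=False)
    _done("mcmc-battery", t0, n_rows=len(table))

    t0 = _stage("stress-stretch")
    stress = battery_stress_summary(table.attrs.get("samples", {}), battery)
    stress.to_csv(out / "stress_stretch.csv", index=False)
    _done("stress-stretch", t0)

    with open(out / "emulator_validation.json", "w") as fh:
        json.dump({"iuq_q2": scores, "gate": cfg.q2_gate}, fh, indent=2)
    return {"battery": battery, "iiqr": table, "stress": stress,
            "q2": scores, "emulators": bank}
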