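"""Shared fixtures.

The expensive artefacts (surrogate training sets, GP emulator banks, MCMC
batteries) are session-scoped and generated programmatically at fixed seeds;
acceptance tests and module tests share them.  Battery MCMC settings are
the scaled-battery defaults (2 short chains per case) so the full posterior
battery stays desk-scale.
"""

import numpy as np
import pytest

from lvuq.design import DESIGN_BOUNDS, sobol_design, two_block_design
from lvuq.emulator import MultiOutputEmulator
from lvuq.forward import (STAR_SEGMENT, SegmentLayout, generate_test_battery,
                          generate_training_set)
from lvuq.inference import IUQ_OUTPUT_NAMES, MCMCConfig, run_iuq_battery
from lvuq.pipeline import REDUCED_INPUT_NAMES, SA_OUTPUT_NAMES, _sa_outputs

GP_KW = dict(n_restarts=2, max_opt_subset=400)


def subset_bank(bank: MultiOutputEmulator, names) -> MultiOutputEmulator:
    """View of a fitted bank restricted to some outputs."""
    mo = MultiOutputEmulator(list(names))
    mo.emulators_ = [bank[n] for n in names]
    mo._build_stack()
    return mo


@pytest.fixture(scope="session")
def segment_layout():
    return SegmentLayout(seed=0)


@pytest.fixture(scope="session")
def sa_dataset(segment_layout):
    """Two-block 11-input design: 2000 training + 100 held-out test
    simulations (the full-study design sizes)."""
    design = two_block_design(2100, seed=101)
    X, Y, ok = generate_training_set(design[:2000], layout=segment_layout)
    Xt, Yt, _ = generate_training_set(design[2000:], layout=segment_layout)
    return {"X": X, "Y": Y, "X_test": Xt, "Y_test": Yt, "ok": ok}


@pytest.fixture(scope="session")
def sa_bank(sa_dataset):
    """11-input emulator bank for the four SA outputs.  The volume response
    is the hardest target (heavy soft-corner tail), so this bank uses a
    larger hyperparameter-optimization subset than the default."""
    bank = MultiOutputEmulator(SA_OUTPUT_NAMES, log_dims=list(range(8)),
                               n_restarts=2, max_opt_subset=800)
    bank.fit(sa_dataset["X"], _sa_outputs(sa_dataset["Y"]), random_state=7)
    return bank


@pytest.fixture(scope="session")
def iuq_dataset(segment_layout):
    """Reduced-space design (log-material x linear pressure): 2000 training
    + 48 held-out simulations (the full-study training size)."""
    bounds = [DESIGN_BOUNDS[k] for k in REDUCED_INPUT_NAMES]
    design = sobol_design(2048, bounds, space=["log"] * 4 + ["linear"],
                          seed=202)
    X, Y, ok = generate_training_set(design[:2000], layout=segment_layout,
                                     input_names=REDUCED_INPUT_NAMES)
    Xt, Yt, _ = generate_training_set(design[2000:], layout=segment_layout,
                                      input_names=REDUCED_INPUT_NAMES)
    return {"X": X, "Y": Y, "X_test": Xt, "Y_test": Yt, "ok": ok}


@pytest.fixture(scope="session")
def iuq_bank(iuq_dataset):
    """25-output (volume + 24 circumferential strains) emulator bank over
    (a, b, a_f, b_f, EDP).  The volume output carries the likelihood's
    single-measurement term, so its emulator gets a larger hyperparameter-
    optimization subset than the strain outputs."""
    from lvuq.emulator import GPEmulator
    bank = MultiOutputEmulator(IUQ_OUTPUT_NAMES, log_dims=[0, 1, 2, 3],
                               **GP_KW)
    bank.fit(iuq_dataset["X"], iuq_dataset["Y"][:, :25], random_state=11)
    bank.emulators_[0] = GPEmulator(log_dims=[0, 1, 2, 3], n_restarts=3,
                                    max_opt_subset=800, random_state=11
                                    ).fit(iuq_dataset["X"],
                                          iuq_dataset["Y"][:, 0])
    bank._build_stack()
    return bank


@pytest.fixture(scope="session")
def sa2_bank(iuq_bank):
    """Reduced-space bank restricted to the SA2 outputs."""
    mo = subset_bank(iuq_bank, ["LVV", f"eps_cc_{STAR_SEGMENT}"])
    mo.output_names = ["LVV", "eps_cc_star"]
    return mo


@pytest.fixture(scope="session")
def battery(segment_layout):
    """Scaled synthetic test battery: 32 log-uniform cases at the five
    study pressures, observation noise 5 ml / 0.03."""
    return generate_test_battery(n_cases=32, seed=303, spec=None,
                                 layout=segment_layout)


@pytest.fixture(scope="session")
def battery_mcmc_cfg():
    """Coverage-grade scaled battery sampler settings."""
    return MCMCConfig(n_chains=2, n_warmup=200, n_draws=300,
                      max_treedepth=6, target_accept=0.7, seed=404)


@pytest.fixture(scope="session")
def trend_mcmc_cfg():
    """Lighter settings for the qualitative per-pressure trend sweeps."""
    return MCMCConfig(n_chains=2, n_warmup=150, n_draws=200,
                      max_treedepth=6, target_accept=0.7, seed=404)


@pytest.fixture(scope="session")
def battery_results(battery, iuq_bank, battery_mcmc_cfg):
    """Posterior battery at EDP = 10 mmHg for the first 21 cases
    (samples kept)."""
    return run_iuq_battery(battery[:21], iuq_bank, config=battery_mcmc_cfg,
                           edp_list=[10.0], keep_samples=True)


@pytest.fixture(scope="session")
def battery_results_halfnoise(segment_layout, iuq_bank, battery_mcmc_cfg):
    """First 8 cases re-observed with both noise SDs halved."""
    from lvuq.inference import NoiseModel
    half = generate_test_battery(n_cases=32, seed=303, sigma0=2.5,
                                 sigma_strain=0.015, layout=segment_layout)
    return run_iuq_battery(half[:8], iuq_bank,
                           noise=NoiseModel(sigma0_sq=2.5 ** 2),
                           config=battery_mcmc_cfg, edp_list=[10.0])


@pytest.fixture(scope="session")
def edp_battery_results(battery, iuq_bank, battery_results, trend_mcmc_cfg):
    """Posterior battery for the first 5 cases at all five pressures
    (EDP-10 runs re-used from ``battery_results``), samples retained for
    the stress push-forward."""
    import pandas as pd
    extra = run_iuq_battery(battery[:5], iuq_bank, config=trend_mcmc_cfg,
                            edp_list=[5.0, 15.0, 20.0, 25.0],
                            keep_samples=True)
    case_ids = {c["case_id"] for c in battery[:5]}
    base = battery_results[battery_results.case_id.isin(case_ids)]
    df = pd.concat([base, extra], ignore_index=True)
    df.attrs["samples"] = {
        **{k: v for k, v in battery_results.attrs["samples"].items()
           if k[0] in case_ids},
        **extra.attrs["samples"]}
    return df
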