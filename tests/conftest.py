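"""Shared fixtures: the default synthetic study and a 25-seed population run.

The expensive Monte-Carlo fixtures are session-scoped so the recovery-quality
tests (filter cosine, threshold error, electrode flags, ERF correlation,
validation error, G) all reuse one set of simulated experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import elstim as el
from elstim.synthetic_rgc import calibration_run

# Study conditions: default cell on the standard array, noise amplitude from
# the half-max calibration rule, 2000 distinct stimuli x 3 repeats.
CELL_POSITION = np.array([1.75, 1.75])
N_DISTINCT = 2000
REPEATS = 3
N_SEEDS = 25
N_SHUFFLES = 300
SIGMA_GRID = np.array([50.0, 100.0, 150.0, 200.0, 250.0])


@pytest.fixture(scope="session")
def array():
    return el.default_array()


@pytest.fixture(scope="session")
def calibrated_sigma(array):
    """Noise SD chosen by the half-of-fitted-saturation rule on the sigma grid."""
    cell = el.make_cell(array, CELL_POSITION, n_significant=3, seed=0)
    probs = calibration_run(cell, SIGMA_GRID, n_pulses=1500, seed=0)
    cal = el.calibrate_sigma(SIGMA_GRID, probs)
    assert not cal.extrapolated
    return float(cal.chosen_sigma)


@dataclass
class SeedRun:
    """Everything the recovery tests need from one simulated experiment."""

    cell: object
    ensemble: object
    sens: object
    sig: object
    v1: np.ndarray
    erf: object  # full-data ERFs with electrode significance
    model_full: object  # LN model fitted on all presentations
    model_train: object  # LN model fitted on the 80% training split
    e_rms: float  # held-out validation error of model_train


def _one_run(seed: int, array, sigma: float) -> SeedRun:
    cell = el.make_cell(array, CELL_POSITION, n_significant=3, seed=seed)
    ens = el.sample_white_noise(
        N_DISTINCT, array.n_electrodes, sigma, repeats=REPEATS, seed=1000 + seed
    )
    rec = el.simulate_responses(cell, ens, seed=2000 + seed)
    sens = el.SpikeTriggeredEnsemble(
        ens.amplitudes, rec.responses.short, mask=ens.mask, stimulus_ids=ens.stimulus_ids
    )
    sig = el.significance_test(sens, n_shuffles=N_SHUFFLES, seed=3000 + seed)
    spectrum = el.spike_triggered_cov(sens)
    v1 = sig.significant[0][0] if sig.significant else spectrum.eigenvectors[:, 0]
    erf = el.electrode_significance(sens, sig, el.estimate_erfs(sens, v1))
    _, model_full = el.fit_ln_model(sens, v1, fit_seed=seed)
    train, test = el.split_data(sens, 0.8, seed=4000 + seed)
    _, model_train = el.fit_ln_model(train, v1, fit_seed=seed)
    report = el.validation_error(model_train, test, B=10)
    return SeedRun(
        cell=cell,
        ensemble=ens,
        sens=sens,
        sig=sig,
        v1=v1,
        erf=erf,
        model_full=model_full,
        model_train=model_train,
        e_rms=report.e_rms,
    )


@pytest.fixture(scope="session")
def population_runs(array, calibrated_sigma):
    """25 independent simulated experiments under the default study conditions."""
    return [_one_run(seed, array, calibrated_sigma) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def single_run(array, calibrated_sigma):
    """One simulated experiment, for tests that need a realistic dataset."""
    return _one_run(7, array, calibrated_sigma)
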