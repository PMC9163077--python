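"""Shared fixtures: packaged genotype parameter sets and common variants."""

from dataclasses import replace

import pytest

import cavclamp as cc


@pytest.fixture(scope="session")
def wt_cell():
    return cc.load_genotype("wt")


@pytest.fixture(scope="session")
def r1667p_cell():
    return cc.load_genotype("r1667p")


@pytest.fixture(scope="session")
def ideal_wt(wt_cell):
    """Noiseless wild type under an ideal clamp (no access resistance)."""
    return replace(wt_cell, noise_sd=0.0, ra=0.0)


@pytest.fixture(scope="session")
def quiet_wt(wt_cell):
    """Noiseless wild type with the realistic access resistance."""
    return replace(wt_cell, noise_sd=0.0)


@pytest.fixture(scope="session")
def leak_only_wt(wt_cell):
    """Pure-leak cell: no channels, no noise; current affine in command."""
    return replace(wt_cell, gmax_density=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def step_iv():
    return cc.build_protocol("step_iv")


@pytest.fixture(scope="session")
def corrected_quiet_iv(quiet_wt, step_iv):
    rec = cc.simulate_recording(step_iv, quiet_wt, seed=11)
    return cc.correct_recording(rec)
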