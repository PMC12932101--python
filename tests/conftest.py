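"""Shared fixtures: small synthetic truths and curves built at test time."""

from fractions import Fraction

import pytest
from hypothesis import settings

import nabtiter as nt

# derandomized hypothesis profile so CI runs are reproducible
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def seroneg_profile():
    return nt.SampleProfile("neg")


@pytest.fixture
def seropos_profile():
    return nt.SampleProfile("pos", true_nd50=Fraction(1, 16), hill_slope=2.0)


@pytest.fixture
def csc_design():
    return nt.AssayDesign(format="CSC", noise_sigma=0.0, seed=0)


@pytest.fixture
def vsc_design():
    return nt.AssayDesign(format="VSC", noise_sigma=0.0, seed=0)


@pytest.fixture
def noisefree_csc_curves(seroneg_profile, seropos_profile, csc_design):
    truth = nt.SimulationTruth(
        profiles=(seroneg_profile, seropos_profile), design=csc_design
    )
    return nt.normalize_plate(nt.simulate_plate(truth))


def curve_by_sample(curves, sample_id):
    return next(c for c in curves if c.sample_id == sample_id)
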