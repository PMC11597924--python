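"""Shared fixtures: scenario bundles and cached transport runs.

Session-scoped so that expensive Monte Carlo runs are shared between the
tests that inspect different aspects of the same field.
"""

import numpy as np
import pytest

import paws_sim as ps


@pytest.fixture(scope="session")
def default_bundle():
    """Curved four-layer phantom, constant baseline properties, tilt 0."""
    return ps.make_fixture(ps.FixtureSpec(scenario="table1-default", grid_resolution_mm=0.1))


@pytest.fixture(scope="session")
def peaked_bundle():
    """Wavelength-resolved properties anchored on the baseline table."""
    return ps.make_fixture(ps.FixtureSpec(scenario="peaked-curves", grid_resolution_mm=0.1))


@pytest.fixture(scope="session")
def literature_bundle():
    """Wavelength-resolved properties at realistic tissue-optics magnitudes."""
    return ps.make_fixture(ps.FixtureSpec(scenario="literature-curves", grid_resolution_mm=0.1))


@pytest.fixture(scope="session")
def literature_field(literature_bundle):
    """One well-converged MC field on the realistic phantom (3 mW/diode)."""
    phantom, props, source = literature_bundle
    return ps.run_transport(phantom, source, props, n_photons=400_000, seed=11)


@pytest.fixture(scope="session")
def slab_case():
    return ps.make_analytic_case("single-slab-beer-lambert")


@pytest.fixture(scope="session")
def fresnel_case():
    return ps.make_analytic_case("two-layer-fresnel-normal")
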