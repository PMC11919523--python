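"""Shared fixtures: default specimen, detector geometry and reduced phantoms."""

import numpy as np
import pytest

from cuticleflex import beam, phantom, waxd


@pytest.fixture(scope="session")
def arc():
    return phantom.default_arc()


@pytest.fixture(scope="session")
def section(arc):
    return beam.section_properties(arc, 7.0 / 24.0)


@pytest.fixture(scope="session")
def mini_geo():
    return waxd.mini_geometry()


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def noiseless_spec():
    return phantom.PhantomSpec(
        seed=11,
        noise=phantom.NoiseModel(poisson=False, read_sigma=0.0),
        relax_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def phantom_dataset(default_spec, tmp_path_factory):
    """Default-noise phantom written to disk and reduced once per session."""
    outdir = tmp_path_factory.mktemp("phantom")
    paths = phantom.write_dataset(default_spec, outdir)
    truth, manifest = phantom.make_phantom(default_spec)
    scans = waxd.reduce_manifest(
        paths["manifest"],
        default_spec.geometry,
        t1_fraction=default_spec.arc.t1_mm / default_spec.arc.h_mm,
    )
    return dict(spec=default_spec, paths=paths, truth=truth, scans=scans)


@pytest.fixture(scope="session")
def true_load_steps(arc, section):
    """Noise-free forward loads at the stepwise compression levels."""
    steps = np.array([0.5, 1.0, 1.5, 2.0])
    deltas = -steps / 100.0 * arc.chord_mm
    guess = None
    loads = []
    for d in deltas:
        sol = beam.shoot(arc, section, float(d), initial_guess=guess)
        guess = (sol.H_bar, sol.M_apex_bar)
        loads.append(sol.physical_load_N(24.0))
    return deltas, np.array(loads)
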