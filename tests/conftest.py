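"""Shared fixtures: phantom studies processed once per session.

All synthetic data is generated programmatically; the expensive end-to-end
pipeline runs (encoded dual-acquisition studies) are session-scoped and
shared between unit and acceptance tests.
"""

from __future__ import annotations

import pytest

from tpm.phantom import (
    PhantomSpec,
    delay_spec,
    make_motion_model,
    mi_like_spec,
    simulate,
)
from tpm.pipeline import combine_runs, process_acquisition


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return make_motion_model(default_spec)


@pytest.fixture(scope="session")
def vel_bundle(default_spec):
    """Default phantom, velocity cines only (no encoding), both rotations."""
    return simulate(default_spec, dual_acquisition=True, encode=False)


@pytest.fixture(scope="session")
def vel_run(vel_bundle):
    """Single-acquisition processing of the default velocity-path phantom."""
    return process_acquisition(vel_bundle.cines[0], vel_bundle.annotations[0])


@pytest.fixture(scope="session")
def dual_encoded(default_spec):
    """Full protocol: encode both rotated acquisitions, process, combine."""
    bundle = simulate(default_spec, dual_acquisition=True, encode=True)
    runs = [
        process_acquisition(acq, ann)
        for acq, ann in zip(bundle.acquisitions, bundle.annotations)
    ]
    waveforms, strain, key, alignment = combine_runs(runs[0], runs[1])
    return {
        "bundle": bundle,
        "runs": runs,
        "waveforms": waveforms,
        "strain": strain,
        "key": key,
        "alignment": alignment,
    }


@pytest.fixture(scope="session")
def ghost_dual():
    """Dual rotated acquisitions with independent phase-encode ghosts."""
    spec = PhantomSpec(ghost_amplitude=0.1)
    bundle = simulate(spec, dual_acquisition=True, encode=True)
    runs = [
        process_acquisition(acq, ann)
        for acq, ann in zip(bundle.acquisitions, bundle.annotations)
    ]
    waveforms, strain, key, alignment = combine_runs(runs[0], runs[1])
    return {"bundle": bundle, "runs": runs, "waveforms": waveforms}


@pytest.fixture(scope="session")
def delay_recovery():
    """Dyssynchrony index recovered for imposed delay SDs 0/3.2/6.4/12.8 ms."""
    from tpm.metrics import dyssynchrony_index

    out = {}
    for sd in (0.0, 3.2, 6.4, 12.8):
        bundle = simulate(delay_spec(sd), dual_acquisition=False, encode=False)
        run = process_acquisition(bundle.cines[0], bundle.annotations[0])
        out[sd] = dyssynchrony_index(run.waveforms["radial"])
    return out


@pytest.fixture(scope="session")
def sham_and_mi():
    """Regional indices for a normal and an infarct-like phantom."""
    from tpm.metrics import compute_indices

    out = {}
    for name, spec in (("sham", PhantomSpec()), ("mi", mi_like_spec())):
        bundle = simulate(spec, dual_acquisition=False, encode=False)
        run = process_acquisition(bundle.cines[0], bundle.annotations[0])
        out[name] = compute_indices(run.waveforms["radial"], run.strain, run.key)
    return out


@pytest.fixture()
def small_spec():
    """Cheap plumbing-test phantom: coarse grid, short cycle, thick wall."""
    return PhantomSpec(
        grid_size=64,
        n_frames=20,
        r_endo_mm=5.0,
        r_epi_mm=8.0,
        contraction_amplitude=0.1,
        rotation_amplitude_rad=0.06,
        n_coils=2,
        fov_rotation_deg=30.0,
    )
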