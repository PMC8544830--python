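import numpy as np
import pytest

from mechanonps import get_preset, process_trace
from mechanonps.simulate import (AcquisitionConfig, PopulationParams,
                                 sample_cells, synthesize_trace)


@pytest.fixture(scope="session")
def ap_geometry():
    return get_preset("AP-1060")


@pytest.fixture(scope="session")
def mcf_geometry():
    return get_preset("MCF-10A")


@pytest.fixture(scope="session")
def noiseless_recording(ap_geometry):
    """Six noiseless cells with drift: shared ground-truth round-trip input."""
    cells = sample_cells(ap_geometry, 6, PopulationParams(), seed=101)
    trace, manifest = synthesize_trace(
        cells, ap_geometry, AcquisitionConfig(noise_sd_rel=0.0, seed=102))
    return trace, manifest


@pytest.fixture(scope="session")
def noiseless_processed(noiseless_recording, ap_geometry):
    trace, manifest = noiseless_recording
    records, detection = process_trace(trace, ap_geometry)
    return records, detection, manifest


@pytest.fixture(scope="session")
def noisy_recording(ap_geometry):
    """Twelve cells at the default acquisition noise level."""
    cells = sample_cells(ap_geometry, 12,
                         PopulationParams(frac_instantaneous=0.0), seed=201)
    trace, manifest = synthesize_trace(cells, ap_geometry,
                                       AcquisitionConfig(seed=202))
    return trace, manifest
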