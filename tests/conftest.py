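"""Shared fixtures.

The conductance-based cell is deterministic, so expensive artifacts
(drive calibration, the AP waveform, protocol runs) are computed once per
session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from sprf.fs_model import (FSModelParams, detect_spikes, find_drive_for_rate,
                           generate_ap_waveform, simulate)
from sprf.pipeline import run_perturbation_protocol
from sprf.stimuli import ConductanceEvent, StimulusProgram


@pytest.fixture(scope="session")
def params():
    return FSModelParams()


@pytest.fixture(scope="session")
def drive40(params):
    return find_drive_for_rate(params, 40.0, 0.5)


@pytest.fixture(scope="session")
def waveform(params):
    return generate_ap_waveform(params)


@pytest.fixture(scope="session")
def steady40(params, drive40):
    """A 1.2 s steady 40 Hz run: (trace, spike train)."""
    prog = StimulusProgram(
        events=[ConductanceEvent("drive_step", 0.0, drive40)],
        duration_ms=1200.0)
    trace = simulate(params, prog)
    return trace, detect_spikes(trace)


@pytest.fixture(scope="session")
def sprf_grid_curves(params, waveform):
    """Measured SPRFs at F = 40 Hz, g_i = 1.5 nS over the four g_e values,
    100 perturbation phases each."""
    out = {}
    for g_e in (0.1, 0.25, 0.5, 0.75):
        out[g_e] = run_perturbation_protocol(
            params, 40.0, g_e, 1.5, phases=100, waveform=waveform)
    return out


@pytest.fixture(scope="session")
def strong_perturbation_curve(params, waveform):
    """The strong-perturbation condition (g_e = 0.4, g_i = 2 nS) used for
    the second-order resetting check."""
    return run_perturbation_protocol(params, 40.0, 0.4, 2.0, phases=40,
                                     waveform=waveform)
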