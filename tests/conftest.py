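"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

import vclamp
from vclamp.protocol import Protocol, Segment

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_protocols():
    return vclamp.fixtures(dt=1.0)


@pytest.fixture(scope="session")
def staircase(fixture_protocols):
    return fixture_protocols["staircase_like"]


@pytest.fixture()
def hold_protocol():
    """Single 300 ms holding step at an arbitrary voltage, holding 0 mV."""

    def make(v, duration=300.0, dt=1.0):
        return Protocol((Segment(duration, v, v),), dt=dt, holding=0.0)

    return make


def dc_circuit_solution(v_cmd, R_m, R_s, alpha=0.0, R_s_star=0.0,
                        V_off=0.0, V_off_star=0.0, g_leak=0.0, E_leak=0.0):
    """Independent DC solution of the clamp circuit by Kirchhoff's laws.

    At DC the capacitors carry no current and the Type II branch is open,
    so the circuit is two linear equations in (V_m, I):

        access loop:  (R_s - alpha R_s*) I + V_m = v_cmd - V_off* + V_off
        membrane:     I = V_m / R_m + g_leak (V_m - E_leak)

    Solved as an explicit 2x2 linear system (no clamp-model code involved).
    """
    A = np.array([
        [1.0, R_s - alpha * R_s_star],
        [-(1.0 / R_m + g_leak), 1.0],
    ])
    b = np.array([v_cmd - V_off_star + V_off, -g_leak * E_leak])
    V_m, I = np.linalg.solve(A, b)
    return V_m, I


@pytest.fixture(scope="session")
def ikr_default():
    return vclamp.default_ikr_parameters()
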