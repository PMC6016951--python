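"""Steady-state algebra of a passive isopotential membrane patch.

A single electrical compartment with a leak conductance and up to two
synaptic conductances (batteries at the excitatory and inhibitory
reversal potentials) is the biophysical core of the motion detector.
Two input configurations are analysed in closed form:

``exc_exc``
    Both inputs open excitatory conductances.  The combined response is
    always *sublinear*: the response to both inputs together is smaller
    than the sum of the individual responses, because each conductance
    shunts the other.

``exc_inh``
    One input opens an excitatory conductance ``g_exc = x`` while the
    other *closes* a tonically active inhibitory conductance,
    ``g_inh = 1 - y`` with ``0 <= y <= 1``.  Relieving the inhibition
    raises the input resistance of the compartment, so the combined
    response is *supralinear* whenever ``|E_exc| > |E_inh|`` — signal
    amplification without any voltage-gated channel.  This is the
    release-from-inhibition mechanism for preferred-direction
    enhancement.

All conductances are expressed relative to the leak conductance and all
voltages relative to the leak reversal potential (taken as 0 mV); the
``exc_inh`` configuration additionally reports responses relative to its
resting potential ``V_rest = E_inh / 2`` (the voltage with the tonic
inhibition active and no input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "InputDrive",
    "CircuitResponse",
    "steady_state_voltage",
    "response_exc_exc",
    "response_exc_inh",
    "nonlinearity_sweep",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class CircuitParams:
    """Reversal potentials and leak conductance of the membrane patch.

    Parameters
    ----------
    e_exc : float
        Excitatory reversal potential in mV (positive).
    e_inh : float
        Inhibitory reversal potential in mV (negative).
    e_leak : float
        Leak reversal potential in mV; voltages are reported relative to
        it, so it is 0 by convention.
    g_leak : float
        Leak conductance.  All synaptic conductances are expressed in
        units of ``g_leak``; it is kept explicit so non-unit leaks stay
        expressible.
    """

    e_exc: float = 50.0
    e_inh: float = -20.0
    e_leak: float = 0.0
    g_leak: float = 1.0

    def __post_init__(self) -> None:
        if self.g_leak <= 0:
            raise ValueError(f"g_leak must be positive, got {self.g_leak}")


@dataclass(frozen=True)
class InputDrive:
    """Dimensionless drives of the two synaptic inputs.

    ``x`` drives the first (excitatory) conductance directly.  In the
    ``exc_inh`` configuration ``y`` controls the inhibitory conductance
    through ``g_inh = 1 - y``, which restricts ``y`` to [0, 1].
    """

    x: float
    y: float

    def validate(self, mode: Literal["exc_exc", "exc_inh"]) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("input drives must be non-negative")
        if mode == "exc_inh" and self.y > 1:
            raise ValueError("exc_inh mode requires y <= 1 (g_inh = 1 - y)")


@dataclass(frozen=True)
class CircuitResponse:
    """Individual, combined and nonlinear response components (mV).

    ``r_nonlin = r12 - (r1 + r2)`` by construction; its sign diagnoses
    sub- vs supralinearity.  All entries are relative to ``v_rest``.
    """

    r1: np.ndarray
    r2: np.ndarray
    r12: np.ndarray
    v_rest: float
    linear_expectation: np.ndarray = field(init=False)
    r_nonlin: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear_expectation", self.r1 + self.r2)
        object.__setattr__(self, "r_nonlin", self.r12 - self.linear_expectation)


def steady_state_voltage(
    g_exc: ArrayLike, g_inh: ArrayLike, params: CircuitParams = CircuitParams()
) -> ArrayLike:
    """Membrane voltage of the passive patch, relative to the leak reversal.

    Solves the steady-state current balance

        Vm = (E_exc * g_exc + E_inh * g_inh) / (g_exc + g_inh + g_leak)

    with reversal potentials measured from ``e_leak``.  Capacitance is
    ignored: the synaptic dynamics are slow against the membrane time
    constant, so every time step is at steady state.

    Parameters
    ----------
    g_exc, g_inh : float or ndarray
        Synaptic conductances in units of the leak conductance; must be
        non-negative.  Broadcast against each other.
    params : CircuitParams
        Battery voltages and leak conductance.

    Returns
    -------
    float or ndarray
        Voltage in mV relative to ``e_leak``.
    """
    g_exc = np.asarray(g_exc, dtype=float)
    g_inh = np.asarray(g_inh, dtype=float)
    if np.any(g_exc < 0) or np.any(g_inh < 0):
        raise ValueError("conductances must be non-negative")
    num = (params.e_exc - params.e_leak) * g_exc + (params.e_inh - params.e_leak) * g_inh
    vm = num / (g_exc + g_inh + params.g_leak)
    return vm if vm.ndim else float(vm)


def response_exc_exc(
    x: ArrayLike, params: CircuitParams = CircuitParams()
) -> CircuitResponse:
    """Responses of a patch driven by two equal excitatory inputs ``x``.

    With ``g_exc1 = g_exc2 = x`` the closed forms are

        R1 = R2 = E_exc * x / (x + 1)
        R12     = E_exc * 2x / (2x + 1)
        R_nonlin = -2 E_exc x**2 / (2x**2 + 3x + 1)

    so the nonlinear component is never positive: mutual shunting makes
    two excitatory conductances interact sublinearly.  Conductances are
    in units of ``g_leak``; the formulas above assume ``g_leak = 1``,
    the general case rescales ``x`` by ``g_leak`` internally.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("drive x must be non-negative")
    u = x / params.g_leak  # conductance in leak units
    e = params.e_exc - params.e_leak
    r1 = e * u / (u + 1.0)
    r12 = e * 2.0 * u / (2.0 * u + 1.0)
    return CircuitResponse(r1=r1, r2=r1.copy(), r12=r12, v_rest=0.0)


def response_exc_inh(
    x: ArrayLike, params: CircuitParams = CircuitParams()
) -> CircuitResponse:
    """Responses of a patch with excitation plus release from inhibition.

    The excitatory conductance follows the drive (``g_exc = x``) while
    the inhibitory conductance is tonically open and closed by the drive
    (``g_inh = 1 - x``, requiring ``0 <= x <= 1``).  At rest the patch
    sits at ``V_rest = E_inh / 2``; responses are reported relative to
    it.  Closed forms for equal drives:

        R1  = (2 E_exc - E_inh) x / (2 (2 + x))
        R2  = -E_inh x / (2 (2 - x))
        R12 = (E_exc - E_inh) x / 2
        R_nonlin = (E_exc (2 - x) + E_inh x) x**2 / (2 (4 - x**2))

    For ``0 < x <= 1`` and ``|E_exc| > |E_inh|`` the nonlinear component
    is strictly positive: closing the inhibition raises the input
    resistance and amplifies the concurrent excitation.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("exc_inh mode requires drive x in [0, 1]")
    e_exc = params.e_exc - params.e_leak
    e_inh = params.e_inh - params.e_leak
    v_rest = e_inh / 2.0
    r1 = (2.0 * e_exc - e_inh) * x / (2.0 * (2.0 + x))
    r2 = -e_inh * x / (2.0 * (2.0 - x))
    r12 = (e_exc - e_inh) * x / 2.0
    return CircuitResponse(r1=r1, r2=r2, r12=r12, v_rest=v_rest)


def nonlinearity_sweep(
    x_grid: ArrayLike,
    params: CircuitParams = CircuitParams(),
    mode: Literal["exc_exc", "exc_inh"] = "exc_inh",
) -> pd.DataFrame:
    """Tabulate response components over a grid of input drives.

    Returns a DataFrame with columns ``x, R1, R2, R12,
    linear_expectation, R_nonlin`` suitable for plotting or CSV export.
    """
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if mode == "exc_exc":
        resp = response_exc_exc(x, params)
    elif mode == "exc_inh":
        resp = response_exc_inh(x, params)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "x": x,
            "R1": resp.r1,
            "R2": resp.r2,
            "R12": resp.r12,
            "linear_expectation": resp.linear_expectation,
            "R_nonlin": resp.r_nonlin,
        }
    )
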