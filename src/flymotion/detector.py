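"""The 38 x 40 array of rightward-preferring motion-detecting units.

Each unit stands for a T4 cell and reads three horizontally adjacent
photoreceptor columns: the *left* input (OFF sustained, Mi9-like) and
the *right* input (ON sustained, Mi4-like) drive the inhibitory
conductance, the *central* input (ON transient, Mi1-like) drives the
excitatory conductance.  The leading-side OFF input implements
preferred-direction enhancement by release from inhibition; the
trailing-side ON input implements null-direction suppression.  The
membrane is the passive patch of :mod:`flymotion.circuit`, solved at
steady state for every frame.  As a stand-in for the tangential cell
that pools many T4 outputs, the population signal is the spatial mean
of the voltages rectified at 0 mV.

Three wiring variants isolate the mechanisms: ``full`` uses both
inhibitory arms, ``nds_only`` silences the left (enhancing) arm and
``pde_only`` silences the right (suppressing) arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple, get_args

import numpy as np

from . import circuit, periphery
from .periphery import FilterParams, PathwaySignals
from .stimuli import StimulusMovie

__all__ = [
    "DetectorParams",
    "DetectorVariant",
    "VARIANTS",
    "DetectorArrayOutput",
    "conductances",
    "membrane_voltage",
    "population_output",
    "run_detector",
    "run_variants",
]

DetectorVariant = Literal["full", "nds_only", "pde_only"]
VARIANTS: Tuple[DetectorVariant, ...] = get_args(DetectorVariant)


@dataclass(frozen=True)
class DetectorParams:
    """Membrane parameters of each detector unit.

    E_exc = +50 mV, E_inh = -20 mV, g_leak = 1 (conductances relative to
    leak); the population rectification threshold is 0 mV.
    """

    e_exc: float = 50.0
    e_inh: float = -20.0
    g_leak: float = 1.0
    threshold: float = 0.0

    def as_circuit_params(self) -> circuit.CircuitParams:
        return circuit.CircuitParams(
            e_exc=self.e_exc, e_inh=self.e_inh, e_leak=0.0, g_leak=self.g_leak
        )


@dataclass
class DetectorArrayOutput:
    """Voltages of every unit plus the rectified population mean.

    ``vm`` has shape (columns, rows, frames) in mV relative to the leak
    reversal (0 mV); ``population`` is the rectified spatial mean per
    frame.
    """

    vm: np.ndarray
    population: np.ndarray
    dt: float
    variant: DetectorVariant
    params: DetectorParams


def conductances(
    pathways: PathwaySignals, variant: DetectorVariant = "full"
) -> Tuple[np.ndarray, np.ndarray]:
    """Map pathway signals onto each unit's synaptic conductances.

    The unit in column ``i`` (0-based, 38 columns from 40 receptor
    columns) receives: excitation from the central receptor's ON
    transient (``on_hp[i+1]``); inhibition from the left receptor's OFF
    sustained signal (``off_lp[i]``, silenced in ``nds_only``) plus the
    right receptor's ON sustained signal (``on_lp[i+2]``, silenced in
    ``pde_only``).  Rightward motion (left -> central) is the preferred
    direction.

    Conductances are rectified at zero: for luminance in [0, 1] the
    pathway signals are non-negative anyway, but renormalized noisy
    stimuli can push luminance above 1, driving the OFF sustained signal
    slightly negative, and a synaptic conductance cannot be.
    """
    g_exc = pathways.on_hp[1:-1]
    if variant == "full":
        g_inh = np.maximum(pathways.off_lp[:-2], 0.0) + np.maximum(
            pathways.on_lp[2:], 0.0
        )
    elif variant == "nds_only":
        g_inh = np.maximum(pathways.on_lp[2:], 0.0)
    elif variant == "pde_only":
        g_inh = np.maximum(pathways.off_lp[:-2], 0.0)
    else:
        raise ValueError(f"unknown detector variant {variant!r}")
    if g_exc.shape != g_inh.shape:
        raise ValueError("pathway grids do not align; expected a common receptor grid")
    return g_exc, g_inh


def membrane_voltage(
    g_exc: np.ndarray, g_inh: np.ndarray, params: DetectorParams = DetectorParams()
) -> np.ndarray:
    """Steady-state membrane voltage of every unit at every frame."""
    return circuit.steady_state_voltage(g_exc, g_inh, params.as_circuit_params())


def population_output(vm: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Spatial mean over units of the voltage rectified at ``threshold``."""
    return np.maximum(vm - threshold, 0.0).mean(axis=(0, 1))


def run_detector(
    movie: StimulusMovie,
    variant: DetectorVariant = "full",
    filter_params: Optional[FilterParams] = None,
    detector_params: DetectorParams = DetectorParams(),
    pathways: Optional[PathwaySignals] = None,
) -> DetectorArrayOutput:
    """Run the whole pipeline: movie -> receptors -> pathways -> array.

    Passing precomputed ``pathways`` (from the same movie) skips the
    peripheral stages, which is how several wiring variants are
    evaluated cheaply on one stimulus.
    """
    if filter_params is None:
        filter_params = FilterParams(dt=movie.dt)
    if pathways is None:
        receptors = periphery.downsample(movie)
        pathways = periphery.pathway_signals(receptors, filter_params)
    g_exc, g_inh = conductances(pathways, variant)
    vm = membrane_voltage(g_exc, g_inh, detector_params)
    pop = population_output(vm, detector_params.threshold)
    return DetectorArrayOutput(
        vm=vm, population=pop, dt=movie.dt, variant=variant, params=detector_params
    )


def run_variants(
    movie: StimulusMovie,
    variants: Tuple[DetectorVariant, ...] = VARIANTS,
    filter_params: Optional[FilterParams] = None,
    detector_params: DetectorParams = DetectorParams(),
) -> dict:
    """Run several wiring variants on one movie, sharing the periphery."""
    if filter_params is None:
        filter_params = FilterParams(dt=movie.dt)
    receptors = periphery.downsample(movie)
    pathways = periphery.pathway_signals(receptors, filter_params)
    return {
        v: run_detector(movie, v, filter_params, detector_params, pathways=pathways)
        for v in variants
    }
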