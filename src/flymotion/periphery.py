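"""Photoreceptor sampling and the temporal-filter / rectification stages.

The stimulus movie is spatially averaged onto a 40 x 40 photoreceptor
grid (4.5 x 4.5 deg per receptor) and split into the three filtered,
rectified signals that mimic the medulla interneurons presynaptic to the
T4 cell:

* ``on_hp``  — Mi1/Tm3 role: first-order high-pass (tau 250 ms) plus a
  10% DC fraction of the raw receptor signal, rectified at 0 (ON,
  band-pass, fast).
* ``on_lp``  — Mi4 role: first-order low-pass of the receptor signal
  (tau 50 ms; ON, sustained).
* ``off_lp`` — Mi9 role: first-order low-pass of ``1 - luminance``
  (OFF, sustained) — tonically active in darkness.
* ``off_hp`` — sign-inverted, rectified high-pass (the OFF-pathway
  transient signal).  Computed for completeness; the rightward-tuned
  ON detector modelled here does not use it.

Filters use the exact exponential update for piecewise-constant input,
``y[t] = y[t-1] + (1 - exp(-dt/tau)) (x[t] - y[t-1])``, with the state
initialized to the first sample so that static scenes produce no onset
transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal as _signal

from .stimuli import StimulusMovie

__all__ = [
    "FilterParams",
    "PathwaySignals",
    "downsample",
    "lowpass",
    "highpass",
    "pathway_signals",
]

#: photoreceptor grid (rows of detectors use the x axis = axis 0)
RECEPTOR_GRID: Tuple[int, int] = (40, 40)


@dataclass(frozen=True)
class FilterParams:
    """Time constants (s) of the peripheral filters.

    tau_lp : low-pass time constant, 50 ms (slow, sustained inputs).
    tau_hp : high-pass time constant, 250 ms (fast, transient input).
    dc_fraction : fraction (0.1) of the raw receptor signal added to the
        high-pass output before rectification.
    dt : simulation step, 10 ms.
    """

    tau_lp: float = 0.05
    tau_hp: float = 0.25
    dc_fraction: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        if min(self.tau_lp, self.tau_hp, self.dt) <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.dt >= min(self.tau_lp, self.tau_hp):
            raise ValueError("dt must be smaller than the filter time constants")


@dataclass
class PathwaySignals:
    """The filtered interneuron-like signals on the receptor grid."""

    on_hp: np.ndarray
    on_lp: np.ndarray
    off_lp: np.ndarray
    off_hp: np.ndarray


def downsample(movie: StimulusMovie, grid: Tuple[int, int] = RECEPTOR_GRID) -> np.ndarray:
    """Average the movie onto the photoreceptor grid.

    Each receptor takes the mean over its non-overlapping pixel block
    (5 x 5 pixels for the default 200-pixel movie on a 40-receptor
    grid), per frame.  Returns an ``(n_rx, n_ry, n_frames)`` array.
    """
    n_rx, n_ry = grid
    n_x, n_y, n_t = movie.luminance.shape
    if n_x % n_rx or n_y % n_ry:
        raise ValueError(
            f"movie dims ({n_x}, {n_y}) not divisible by receptor grid {grid}"
        )
    bx, by = n_x // n_rx, n_y // n_ry
    blocks = movie.luminance.reshape(n_rx, bx, n_ry, by, n_t)
    return blocks.mean(axis=(1, 3))


def _alpha(tau: float, dt: float) -> float:
    return 1.0 - np.exp(-dt / tau)


def lowpass(x: np.ndarray, tau: float, dt: float, axis: int = -1) -> np.ndarray:
    """First-order low-pass along ``axis``, state initialized to x[0]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = _alpha(tau, dt)
    x = np.asarray(x, dtype=np.float64)
    x0 = np.take(x, [0], axis=axis)
    # unit-DC-gain recursion applied to the deviation from the first
    # sample, so y starts exactly at x[0]
    y = _signal.lfilter([a], [1.0, -(1.0 - a)], x - x0, axis=axis)
    return y + x0


def highpass(x: np.ndarray, tau: float, dt: float, axis: int = -1) -> np.ndarray:
    """First-order high-pass: the input minus its low-pass."""
    return np.asarray(x, dtype=np.float64) - lowpass(x, tau, dt, axis=axis)


def pathway_signals(
    receptors: np.ndarray, params: FilterParams = FilterParams()
) -> PathwaySignals:
    """Filter and rectify the receptor signals into the four pathways.

    ``h = highpass(I, tau_hp) + dc_fraction * I``; the ON transient is
    ``max(h, 0)`` and the OFF transient ``max(-h, 0)``.  The sustained
    signals are ``lowpass(I, tau_lp)`` (ON) and ``lowpass(1 - I,
    tau_lp)`` (OFF).  All outputs are non-negative for luminance in
    [0, 1].
    """
    receptors = np.asarray(receptors, dtype=np.float64)
    h = highpass(receptors, params.tau_hp, params.dt) + params.dc_fraction * receptors
    return PathwaySignals(
        on_hp=np.maximum(h, 0.0),
        on_lp=lowpass(receptors, params.tau_lp, params.dt),
        off_lp=lowpass(1.0 - receptors, params.tau_lp, params.dt),
        off_hp=np.maximum(-h, 0.0),
    )
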