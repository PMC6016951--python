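"""Experiment battery characterizing the detector array.

Four experiments, each run for any subset of the three wiring variants:

* temporal-frequency tuning (drifting gratings, 0.1-10 Hz, preferred
  and null direction),
* direction tuning (1 Hz gratings, 30-deg steps),
* photon-noise sensitivity (Poisson-corrupted gratings at mean
  luminance factors 1-32, quantified as a signal-to-noise ratio),
* motion-coherence sensitivity (random-dot kinematograms).

The scalar "response" of a run is the time mean of the rectified
population output with the first second discarded (onset transient).
The signal-to-noise ratio of a noise run is the difference of the mean
outputs during the preferred-direction window (0.5-4.5 s) and the
null-direction window (5.5-9.5 s), divided by the square root of the
response variance pooled over both windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stimuli
from .detector import DetectorParams, VARIANTS, DetectorVariant, run_variants
from .periphery import FilterParams
from .stimuli import (
    DEFAULT_DIMS,
    PD_ND_SCHEDULE,
    DotSpec,
    GratingSpec,
    NoiseSpec,
    make_dots,
    make_grating,
    apply_photon_noise,
)

__all__ = [
    "FREQUENCY_GRID",
    "DIRECTION_GRID",
    "NOISE_FACTORS",
    "COHERENCE_GRID",
    "PD_WINDOW",
    "ND_WINDOW",
    "SNRResult",
    "mean_response",
    "snr",
    "response_histogram",
    "temporal_frequency_tuning",
    "direction_tuning",
    "photon_noise_experiment",
    "coherence_experiment",
    "summarize_snr",
]

#: log-spaced drift frequencies (Hz) of the tuning experiment
FREQUENCY_GRID: Tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
#: motion directions (deg) of the direction-tuning experiment
DIRECTION_GRID: Tuple[float, ...] = tuple(range(0, 360, 30))
#: mean-luminance factors of the photon-noise experiment
NOISE_FACTORS: Tuple[float, ...] = (1, 2, 4, 8, 16, 32)
#: coherent-dot fractions of the motion-noise experiment
COHERENCE_GRID: Tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

PD_WINDOW: Tuple[float, float] = (0.5, 4.5)
ND_WINDOW: Tuple[float, float] = (5.5, 9.5)

#: onset-transient exclusion for tuning responses (s)
RESPONSE_T_MIN = 1.0


@dataclass
class SNRResult:
    """Mean window responses, pooled variance, and their ratio.

    ``snr = (mean_pd - mean_nd) / sqrt(variance)``.  A noiseless run can
    have zero variance; it is flagged ``degenerate`` and reported as
    infinite (or zero if the means coincide).
    """

    mean_pd: float
    mean_nd: float
    variance: float
    snr: float
    windows: Tuple[Tuple[float, float], Tuple[float, float]]
    var_pd: float = 0.0
    var_nd: float = 0.0
    degenerate: bool = False


def mean_response(
    population: np.ndarray, dt: float, t_min: float = RESPONSE_T_MIN
) -> float:
    """Time mean of the population output after the onset transient."""
    start = int(round(t_min / dt))
    return float(np.mean(population[start:]))


def _window_slice(window: Tuple[float, float], dt: float) -> slice:
    return slice(int(round(window[0] / dt)), int(round(window[1] / dt)))


def snr(
    population: np.ndarray,
    dt: float,
    windows: Tuple[Tuple[float, float], Tuple[float, float]] = (PD_WINDOW, ND_WINDOW),
    variance: Literal["pooled", "pd", "nd"] = "pooled",
) -> SNRResult:
    """Signal-to-noise ratio of a preferred/null stimulation run.

    The response variance is computed within each window about that
    window's own mean; by default the two windows are pooled so every
    noisy sample contributes symmetrically.
    """
    pd_win, nd_win = windows
    x_pd = population[_window_slice(pd_win, dt)]
    x_nd = population[_window_slice(nd_win, dt)]
    if x_pd.size == 0 or x_nd.size == 0:
        raise ValueError("population trace does not cover the analysis windows")
    mean_pd = float(x_pd.mean())
    mean_nd = float(x_nd.mean())
    var_pd = float(np.mean((x_pd - mean_pd) ** 2))
    var_nd = float(np.mean((x_nd - mean_nd) ** 2))
    if variance == "pooled":
        var = (var_pd * x_pd.size + var_nd * x_nd.size) / (x_pd.size + x_nd.size)
    elif variance == "pd":
        var = var_pd
    elif variance == "nd":
        var = var_nd
    else:
        raise ValueError(f"unknown variance mode {variance!r}")

    diff = mean_pd - mean_nd
    if var <= 0.0:
        value = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        return SNRResult(mean_pd, mean_nd, var, value, windows, var_pd, var_nd,
                         degenerate=True)
    return SNRResult(mean_pd, mean_nd, var, diff / math.sqrt(var), windows,
                     var_pd, var_nd)


def response_histogram(
    population: np.ndarray,
    dt: float,
    window: Tuple[float, float],
    bins: int | np.ndarray = 50,
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of the population output within a time window."""
    x = population[_window_slice(window, dt)]
    if x.size == 0:
        raise ValueError("window contains no samples")
    return np.histogram(x, bins=bins)


# ---------------------------------------------------------------------------
# experiment drivers


def _seed_table(seed: int, n: int) -> np.ndarray:
    """Independent sub-seeds for replicate stimulus realizations."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def temporal_frequency_tuning(
    variants: Sequence[DetectorVariant] = VARIANTS,
    freqs: Sequence[float] = FREQUENCY_GRID,
    dims: Tuple[int, int, int] = DEFAULT_DIMS,
    detector_params: DetectorParams = DetectorParams(),
    filter_params: Optional[FilterParams] = None,
) -> pd.DataFrame:
    """Response vs. grating drift frequency, preferred and null direction.

    One full-duration drifting grating per (frequency, direction); the
    normalized column scales each variant's responses to that variant's
    own preferred-direction peak, so the reference curve peaks at 1 and
    the null-direction curve is directly comparable to it.
    """
    rows = []
    for f in freqs:
        for direction, label in ((0.0, "PD"), (180.0, "ND")):
            movie = make_grating(
                GratingSpec(temporal_frequency=f, direction=direction), dims=dims
            )
            outs = run_variants(movie, tuple(variants), filter_params, detector_params)
            for v, out in outs.items():
                rows.append(
                    {
                        "variant": v,
                        "frequency": f,
                        "direction": label,
                        "response": mean_response(out.population, movie.dt),
                    }
                )
    df = pd.DataFrame(rows)
    if "full" in df["variant"].values:
        # common reference: the full model's preferred-direction peak
        ref = df[(df.variant == "full") & (df.direction == "PD")]["response"].max()
        df["response_norm"] = df["response"] / ref
    else:
        peaks = (
            df[df.direction == "PD"].groupby("variant")["response"].max().rename("peak")
        )
        df = df.join(peaks, on="variant")
        df["response_norm"] = df["response"] / df["peak"]
        df = df.drop(columns="peak")
    return df


def direction_tuning(
    variants: Sequence[DetectorVariant] = VARIANTS,
    directions: Sequence[float] = DIRECTION_GRID,
    temporal_frequency: float = 1.0,
    dims: Tuple[int, int, int] = DEFAULT_DIMS,
    detector_params: DetectorParams = DetectorParams(),
    filter_params: Optional[FilterParams] = None,
) -> pd.DataFrame:
    """Response vs. grating motion direction at a fixed drift frequency.

    Each variant's curve is normalized to its own peak.
    """
    rows = []
    for direction in directions:
        movie = make_grating(
            GratingSpec(temporal_frequency=temporal_frequency, direction=direction),
            dims=dims,
        )
        outs = run_variants(movie, tuple(variants), filter_params, detector_params)
        for v, out in outs.items():
            rows.append(
                {
                    "variant": v,
                    "direction": direction,
                    "response": mean_response(out.population, movie.dt),
                }
            )
    df = pd.DataFrame(rows)
    peaks = df.groupby("variant")["response"].max().rename("peak")
    df = df.join(peaks, on="variant")
    df["response_norm"] = df["response"] / df["peak"]
    return df.drop(columns="peak")


def photon_noise_experiment(
    variants: Sequence[DetectorVariant] = VARIANTS,
    factors: Sequence[float] = NOISE_FACTORS,
    n_replicates: int = 10,
    seed: int = 0,
    temporal_frequency: float = 1.0,
    dims: Tuple[int, int, int] = DEFAULT_DIMS,
    detector_params: DetectorParams = DetectorParams(),
    filter_params: Optional[FilterParams] = None,
) -> pd.DataFrame:
    """Signal-to-noise ratio under photon shot noise.

    A 1 Hz grating follows the preferred/null motion schedule
    (stationary, preferred 0.5-4.5 s, stationary, null 5.5-9.5 s); each
    (factor, replicate) applies an independent Poisson corruption before
    the detector runs.  Returns one row per (variant, factor, replicate)
    with the window means, pooled variance and SNR.
    """
    clean = make_grating(
        GratingSpec(temporal_frequency=temporal_frequency, schedule=PD_ND_SCHEDULE),
        dims=dims,
    )
    seeds = _seed_table(seed, len(factors) * n_replicates)
    rows = []
    for i, factor in enumerate(factors):
        for rep in range(n_replicates):
            s = int(seeds[i * n_replicates + rep])
            noisy = apply_photon_noise(clean, NoiseSpec(factor, seed=s))
            outs = run_variants(noisy, tuple(variants), filter_params, detector_params)
            for v, out in outs.items():
                r = snr(out.population, noisy.dt)
                rows.append(
                    {
                        "variant": v,
                        "factor": factor,
                        "replicate": rep,
                        "seed": s,
                        "mean_pd": r.mean_pd,
                        "mean_nd": r.mean_nd,
                        "variance": r.variance,
                        "var_pd": r.var_pd,
                        "var_nd": r.var_nd,
                        "snr": r.snr,
                    }
                )
    return pd.DataFrame(rows)


def coherence_experiment(
    variants: Sequence[DetectorVariant] = VARIANTS,
    coherences: Sequence[float] = COHERENCE_GRID,
    n_replicates: int = 10,
    seed: int = 0,
    dot_spec: DotSpec = DotSpec(),
    dims: Tuple[int, int, int] = DEFAULT_DIMS,
    detector_params: DetectorParams = DetectorParams(),
    filter_params: Optional[FilterParams] = None,
) -> pd.DataFrame:
    """Signal-to-noise ratio vs. fraction of coherently moving dots.

    The coherent dots move rightward during the preferred window and
    leftward during the null window; incoherent dots random-walk
    throughout.  ``dot_spec`` carries all other kinematogram parameters
    (its own coherence/seed fields are overridden per condition).
    """
    seeds = _seed_table(seed, len(coherences) * n_replicates)
    rows = []
    for i, coh in enumerate(coherences):
        for rep in range(n_replicates):
            s = int(seeds[i * n_replicates + rep])
            spec = DotSpec(
                n_dots=dot_spec.n_dots,
                coherence=coh,
                coherent_direction=dot_spec.coherent_direction,
                speed=dot_spec.speed,
                redirection_interval=dot_spec.redirection_interval,
                blur_half_width=dot_spec.blur_half_width,
                seed=s,
            )
            movie = make_dots(spec, dims=dims, motion_schedule=PD_ND_SCHEDULE)
            outs = run_variants(movie, tuple(variants), filter_params, detector_params)
            for v, out in outs.items():
                r = snr(out.population, movie.dt)
                rows.append(
                    {
                        "variant": v,
                        "coherence": coh,
                        "replicate": rep,
                        "seed": s,
                        "mean_pd": r.mean_pd,
                        "mean_nd": r.mean_nd,
                        "variance": r.variance,
                        "var_pd": r.var_pd,
                        "var_nd": r.var_nd,
                        "snr": r.snr,
                    }
                )
    return pd.DataFrame(rows)


def summarize_snr(df: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Mean and standard deviation of SNR across replicates."""
    g = df.groupby(list(by))["snr"]
    out = g.agg(snr_mean="mean", snr_sd="std", n="count").reset_index()
    return out
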