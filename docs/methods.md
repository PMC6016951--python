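# Model and methods

## The biophysical question

Elementary motion detectors must respond to visual motion in one
direction (the preferred direction, PD) and not the opposite (null
direction, ND).  Two algorithmic routes exist: amplify PD signals
(preferred-direction enhancement, PDE) or suppress ND signals
(null-direction suppression, NDS).  Suppression maps naturally onto
inhibition, but amplification is biophysically puzzling — a passive
dendrite cannot multiply.  `flymotion` implements, as tested code, a
mechanism in which amplification emerges from *release from
inhibition*: an OFF-type inhibitory input on the preferred side of the
dendrite shuts off when a bright edge approaches, raising the cell's
input resistance just as the central excitatory input arrives.  The
wiring mirrors the inputs of the fly T4 neuron (Mi9: OFF, sustained,
inhibitory, preferred side; Mi1/Tm3: ON, transient, excitatory,
central; Mi4: ON, sustained, inhibitory, null side).

## Passive membrane algebra (`circuit`)

A single isopotential compartment with leak conductance `g_leak`
(all conductances expressed in its units) and synaptic batteries
`E_exc`, `E_inh` has the steady-state voltage

    Vm = (E_exc * g_exc + E_inh * g_inh) / (g_exc + g_inh + g_leak)

relative to the leak reversal (0 mV).  Capacitance is neglected
throughout: input dynamics (tens to hundreds of ms) are slow against
the membrane time constant, so each frame is solved at steady state.

Two configurations are solved in closed form for equal drives `x`:

* **exc–exc** (`g_exc1 = g_exc2 = x`): the nonlinear component
  `R12 − (R1 + R2) = −2 E_exc x² / (2x² + 3x + 1)` is strictly
  negative — mutual shunting makes summation sublinear.
* **exc–inh** (`g_exc = x`, tonic inhibition closed by the drive,
  `g_inh = 1 − x`, resting at `V_rest = E_inh / 2`): the nonlinear
  component `(E_exc (2 − x) + E_inh x) x² / (2 (4 − x²))` is strictly
  positive for `0 < x ≤ 1` whenever `|E_exc| > |E_inh|` — release from
  inhibition amplifies.  The supralinearity holds over the whole
  physiological drive range, unlike threshold nonlinearities that
  amplify only near their set point.

Unit tests verify both closed forms against brute-force composition of
the membrane equation (relative error < 1e-12 over randomized
parameters), plus the sign, bound and monotonicity properties.

## Stimuli (`stimuli`)

Movies are luminance fields over `(x, y, t)`: 200 × 200 pixels covering
180 × 180 deg (0.9 deg/px) and 1000 frames covering 10 s (dt = 10 ms).
Direction 0 deg = rightward = the detector's preferred direction.

* **Gratings**: sine, wavelength 36 deg, mean 0.5, contrast 1 (luminance
  0–1).  A motion schedule freezes or reverses the drift; the noise
  experiments use: stationary 0–0.5 s, PD drift 0.5–4.5 s, stationary
  4.5–5.5 s, ND drift 5.5–9.5 s, stationary to 10 s.
* **Photon noise**: every pixel is replaced by a Poisson draw with mean
  `factor × luminance`, factor ∈ {1, 2, 4, 8, 16, 32}; more photons
  mean relatively less shot noise.  The counts are then renormalized so
  all factors share the same mean luminance and contrast.  Default
  renormalization is a whole-movie affine rescale matching the clean
  movie's mean and standard deviation, clamped at 0 — at low photon
  counts the realized standard deviation is mostly shot noise, so this
  convention visibly shrinks the underlying signal (a real effect of
  photon-limited vision: at low light the *effective* stimulus contrast
  falls).  A `scale` convention (divide counts by the factor),
  preserving the underlying signal exactly, is provided as well.
* **Random-dot kinematograms**: 500 single-pixel dots at continuous
  sub-pixel positions with periodic wrap-around (constant density, no
  edge artifacts).  `round(coherence × 500)` dots form a fixed coherent
  subset moving rightward in the PD window and leftward in the ND
  window at 36 deg/s (one grating wavelength per second, matching the
  1 Hz grating condition; the speed is a configuration knob).  The
  remaining dots move at the same speed along independent uniformly
  random directions re-drawn every 50 ms.  The rendered movie is
  smoothed with a Gaussian of 4.5 deg full width at half maximum
  (σ ≈ 1.91 deg).  The smoothing kernel is **peak-normalized** for
  dots: each dot becomes a unit-amplitude Gaussian blob.  A unit-sum
  kernel would dilute a single pixel roughly 30-fold, leaving the
  stimulus everywhere below the detector's tonic inhibition and the
  full model exactly silent — incompatible with the strong coherence
  dependence this stimulus is meant to probe.  (`gaussian_blur` itself
  defaults to the ordinary unit-sum convention.)

All generators are pure functions of (spec, seed); identical inputs
give byte-identical movies.

## Periphery (`periphery`)

The movie is block-averaged onto 40 × 40 photoreceptors (5 × 5 pixels =
4.5 × 4.5 deg each).  First-order filters use the exact exponential
update `y[t] = y[t−1] + (1 − e^(−dt/τ))(x[t] − y[t−1])` (exact for
piecewise-constant input), with state initialized to the first sample
so static scenes produce no onset transient.  Pathways:

| signal   | role     | definition                                  |
|----------|----------|---------------------------------------------|
| `on_hp`  | Mi1/Tm3  | rectify(HP(I, 250 ms) + 0.1·I)               |
| `on_lp`  | Mi4      | LP(I, 50 ms)                                 |
| `off_lp` | Mi9      | LP(1 − I, 50 ms)                             |
| `off_hp` | (unused) | rectify(−(HP(I, 250 ms) + 0.1·I))            |

The 10% DC fraction is added after high-pass filtering and before
rectification.  `off_hp` belongs to the OFF-pathway detector (T5
analogue) and is exposed but not wired up.

## Detector array (`detector`)

38 × 40 rightward-preferring units; the unit in column *i* reads the
horizontally adjacent receptor columns *i*, *i+1*, *i+2*:
`g_exc = on_hp[i+1]`, `g_inh = off_lp[i] + on_lp[i+2]`, with
`E_exc = +50 mV`, `E_inh = −20 mV`, `g_leak = 1`.  Variants silence one
inhibitory arm: `nds_only` drops the left OFF input (no PDE),
`pde_only` drops the right ON input (no NDS).  Silencing zeroes the
conductance term only.  Conductances are additionally rectified at 0:
renormalized noisy movies can exceed luminance 1, which would push
`off_lp` slightly negative, and a synaptic conductance cannot be.  The
population output — a stand-in for a lobula-plate tangential cell — is
the spatial mean of the voltages rectified at 0 mV.

## Analyses (`analysis`)

The scalar response of a run is the time mean of the population output
from 1 s onward (onset transient excluded; stabilizes the 0.1 Hz
points).  Frequency tuning uses the log grid {0.1, 0.2, 0.5, 1, 2, 5,
10} Hz, PD and ND, normalized to the full model's PD peak when the full
model is included (per-variant PD peak otherwise).  Direction tuning
uses 0–330 deg in 30-deg steps at 1 Hz, each curve normalized to its
own peak.

The signal-to-noise ratio of a noise run is
`(mean_PD − mean_ND) / sqrt(var)` with means over the PD (0.5–4.5 s)
and ND (5.5–9.5 s) windows and `var` the within-window variance about
each window's own mean, pooled over both windows by default (PD-only
and ND-only estimators are switchable).  Zero variance (noiseless
runs) is flagged and reported as infinite.  Stochastic experiments run
10 replicate seeds per condition, derived from a single master seed,
and report per-replicate rows plus mean ± sd summaries.

## Known limitations

* The pooled within-window variance of the rectified population
  average contains deterministic, stimulus-locked components — the
  onset ramp at each motion transition (the peripheral filters need
  ~0.2 s to reach oscillatory steady state), residual 1–2 Hz ripple
  because 38 columns do not tile the 8-column grating wavelength, and
  8/16 Hz spatial-sampling harmonics of the rectified waveform.  For
  noisy gratings these components, not the photon noise, dominate the
  variance at high luminance factors, capping the measurable SNR near
  10; photon noise itself is strongly averaged out by the 5 × 5-pixel
  receptor integration and the 1520-unit population pooling.  SNR
  comparisons across luminance factors are therefore compressed
  relative to an ideal shot-noise-limited readout, although
  monotonicity in the factor and the relative ordering of model
  variants are robust.  The dot experiments do not suffer from this:
  their population signal carries no stimulus-locked oscillation, so
  the SNR spans its full dynamic range.
* The synthetic stimuli are ideal: no photoreceptor adaptation, no
  optics beyond the stated blur, luminance exactly in [0, 1].  Passing
  tests show the mechanism works under these conditions, not that it
  is robust to natural-scene statistics.
* Only the rightward-tuned ON-pathway detector is modelled; no OFF
  (T5) pathway, no opponent subtraction stage, no calcium-channel
  rectification biophysics.
* Voltages are reported relative to the leak reversal (0 mV); the
  exc–inh circuit additionally reports responses relative to its
  resting level `E_inh/2`.  Single-detector traces are exported
  relative to 0 mV.

## Problem sizes

The defaults are the full model geometry (200 × 200 × 1000 movies,
38 × 40 array).  A single run of the full pipeline takes well
under a second after stimulus generation; the complete experiment
battery (tuning grids plus 10-replicate noise experiments) runs in a
few minutes on one CPU core.  All movie dimensions are overridable for
quick exploration.
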