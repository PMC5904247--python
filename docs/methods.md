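# Methods

`charaph` models and measures the surface-pH signatures of H⁺/OH⁻ channel
activity in salt-stressed characean internodal cells.  This note records
the models, the conventions, the parameter choices, and their limits.

## Chemistry and constants

All pH arithmetic uses a fixed water ion product, pKw = 14 ("pOH = 14 −
pH"), without temperature correction or activity coefficients — the
package targets back-of-envelope-faithful estimation, not speciation
modelling.  The default temperature is 293.15 K (20 °C, the culture
temperature, and the reference temperature of the 15 fS unitary
proton-channel conductance); it is overridable everywhere.

Potentials are the cell interior minus the exterior, in mV, so resting
potentials are negative.  The Nernst potential is computed from
concentration ratios for either carrier; `E_H = E_OH` holds identically
for every pH pair because pH and pOH are complementary, which is the
reason a proton efflux and a hydroxide influx cannot be distinguished
electrically and the channel name stays ambiguous.  The package never
decides which ion is carried.

Defaults are CODATA 2018 constants.  A second constant set with
two-significant-figure values (N_A = 6.02×10²³, e = 1.6×10⁻¹⁹ C) is
provided for reproducing rounded worked arithmetic digit for digit; the
full-precision and two-figure chains agree to ~0.3%.

## The spot → channel-count chain

A transient alkaline spot of volume V at local pH 9 contains
N = c·V·N_A hydroxide ions (c = 10^(pH−14) mol/L).  If those ions crossed
the membrane within duration t (≈10 s, the observed spot rise time), the
mean current is i = N·e/t; against a PD excursion ΔV (≈10 mV, a large
noise spike) the chord conductance is g = i/ΔV; dividing by the unitary
conductance γ = 15 fS gives the open-channel count, and dividing an areal
membrane conductance (S/m²) by γ gives an areal channel density.

Two volume conventions coexist.  The geometric hemisphere volume of a
30 μm spot is 7.07×10⁻¹² L; published worked estimates of this kind quote
7.65×10⁻¹⁵ L, a ~900-fold smaller figure that the downstream numbers
(4.6×10⁴ ions, 7.36×10⁻¹⁶ A, 73.6 fS, ~5 open channels) are consistent
with.  The package does not guess which was intended: the quoted volume is
passed as `volume_override` (the default for reproduction), the hemisphere
formula is exposed separately, and the output provenance records which
path was used.  Channel counts round to the nearest integer, ties away
from zero (4.907 → 5).  The open fraction is assessed against the
eosinophil areal density range (125–200 channels/μm²) on a 1 μm² patch,
giving 2.5–4.0% for five open channels.

## Cell-wall transport

The wall is treated as a planar slab (thickness 6.5 μm ≪ cell radius, so
curvature is negligible) with Fickian diffusion at the bulk-water
hydroxide diffusivity D = 4.56×10⁻⁵ cm²/s; wall pores (~4–5 nm) are far
wider than a hydrated hydroxide ion, so unhindered diffusion is the
baseline and ×10 path length / ÷10 diffusivity factors are exposed as the
pessimistic correction.  The closed-form crossing time t = d²/2D is
4.6 ms (seconds with the pessimistic factors) — either way orders of
magnitude shorter than the 10–18 min delay before alkaline spots appear,
which motivates the buffered model.

The simulator solves, on the slab interior,

    ∂c/∂t = D ∂²c/∂x² − k_r·c·b        (free hydroxide)
    ∂b/∂t = −k_ex·b − k_r·c·b          (exchangeable bound H⁺)

with c fixed at the inner face, a zero-concentration sink at the outer
face, b initialized to the buffer capacity B₀ (mol per litre of wall
volume), k_ex the first-order Na⁺-driven release rate, and k_r the
bimolecular neutralization rate.  Saline exposure is represented
kinetically: toggling k_ex (and supplying B₀) switches the cation-exchange
pathway on; Na⁺ itself is not transported explicitly.

Numerics: coupled backward Euler.  Each step solves diffusion plus the
neutralization sink (linear in c at the current buffer level) in one
tridiagonal system, then updates b implicitly from the new c.  The sink
must not be operator-split from diffusion: a reaction-free diffusion
substep crosses the millisecond-scale slab within one minutes-scale step
and fakes instant breakthrough.  Boundary fluxes and the neutralized
amount are accounted with the same discrete operators, so the hydroxide
mass balance closes to machine precision (residuals ~1e-13, asserted
< 1e-3).  The scheme is unconditionally stable; dt is auto-reduced (with
a warning) only when it would under-resolve the k_ex release kinetics.

Because "breakthrough" has no single canonical definition, three
diagnostics are reported: the Daynes–Barrer time lag (the intercept of
the asymptotic cumulative-flux line; d²/6D for an unbuffered slab, the
analytic oracle the simulator is tested against to < 5%), the time the
outer-face flux reaches half its steady value, and the first crossing of
a detection threshold by the concentration at the last interior node
(the outer face itself is a sink and stays at zero).

B₀ has no measured value.  The package sizes it self-consistently: pool
depletion is front-limited (a shrinking core — the influx runs over the
depleted depth, not the full wall), so the pool that absorbs its own
influx for duration t is B₀ = 2·D·c₀·t/d².  A ten-minute pool
(B₀ ≈ 1.3 mol/L of wall volume for c₀ = 10⁻⁵ mol/L, consistent with the
high cation-binding capacity of plant walls) delays the threshold
breakthrough to ~10 min — the scale of the observed spot-onset delay.
Letting k_ex release the pool concurrently shortens the delay, since
released protons leave this model rather than neutralizing hydroxide;
the neutralization-limited variant is the demonstration scenario.  The
breakthrough time depends only logarithmically on k_r (default 10⁶
L·mol⁻¹·s⁻¹, fast but far below diffusion-limited); it is an exploratory
quantity, not a fitted one.

## Membrane model

The current–voltage behaviour across the stages of saline exposure is a
reconstruction from three parallel transporters (the equations behind
the published stage curves are not printed there):

* **Pump** — a two-state reduced enzyme cycle with voltage-split rates:
  I = I_max·(κ₊ − κ₋)/(κ₊ + κ₋), κ₊ = k_f·e^(s·u), κ₋ = k_b·e^(−(1−s)·u),
  u = FV/RT, symmetry s = 0.5.  Smooth, saturating at both extremes,
  reversing at (RT/F)·ln(k_b/k_f) (set to −400 mV).
* **Background** — ohmic leak g_b·(V − E_b).
* **OH⁻ channel** — Goldman–Hodgkin–Katz constant-field current for
  z = −1 with hydroxide concentrations from the internal/external pH
  (7.5 / 5.6 by default), gated by a Boltzmann open probability
  p_o(V) = 1/(1 + exp((V − V₅₀)/s)) that opens on hyperpolarization.
  The GHK current reverses exactly at E_OH independent of gating, and
  V = 0 is handled by the analytic limit.

Total current and conductance are pointwise sums (parallel conductances
are additive; asserted to 1e-9 relative).  Conductances are numerical
slopes dI/dV by central differences on a 1 mV grid (−350…+50 mV);
the resting PD is found by bracketed root finding on the total current.

Four presets are shipped.  For each, the qualitative shape parameters
were fixed first and a single free parameter was then solved numerically
so the resting PD lands on the stage anchor: the pump-dominated sorbitol
state (−247 mV; solved pump amplitude 0.0738 A/m²), the depolarized
early-saline background state (−100 mV; solved leak reversal −97.5 mV
with a tenfold-reduced pump), and the OH⁻-dominated late-saline state
(−52 mV; solved permeability 3.0×10⁻³ m/s).  An `early_saline` variant
adds a small just-opening OH⁻ conductance whose peak sits near −100 mV.
These are calibrated reconstructions pinned by regression tests, not fits
to recorded curves; only the resting PDs and the qualitative conductance
shapes are anchored, and the late-state peak conductance (≈5 S/m²) is
checked only to order of magnitude.

## Synthetic movies

The generator emulates the study's imaging: 1.2 s frame interval, ~30 μm
alkaline spots (Gaussian spatial profile, σ = radius/2), background
pH 5.6, stationary alkaline bands, and a non-ratiometric FITC-dextran
response that is linear from pH 5 to 7.5 and flat above — so spot peak pH
(default 9, an assumption; only "≥ 7.5" is observable) saturates the dye
and is deliberately not recoverable from intensity.  Spot envelopes are
piecewise linear (rise to peak, decay to zero; an exponential-decay
option exists) with kinetics drawn 50/50 from (25 s, 130 s) and
(50 s, 190 s).  Noise is Poisson (photon) followed by Gaussian (read),
then clipping and quantization (16-bit) or float32 (32-bit).  A seed
fixes the movie bit-exactly.

Scenarios: `control_afw` and `sorbitol` render bands but no transient
spots; `saline` drops the bands and spawns spots as a Poisson process
(default 2/min over the field — a chosen rate; no rate is reported) after
an onset delay drawn uniformly from 10–18 min; `saline_zncl2` spawns
spots at a rate decaying to zero within minutes (Zn²⁺ block).  Events are
placed at least three radii apart, away from borders, and only if their
envelope completes before the movie ends, so every ground-truth lifetime
is well defined.

`config_for_snr` sets the gain so the saturated spot amplitude is a
chosen multiple (the amplitude SNR) of the total per-pixel noise sigma at
the spot center; the recovery benchmarks run at SNR 5.

**Shared conventions (generator ↔ detector).**  Because saturation makes
the center-pixel signal plateau, the ground-truth observable is the
noiseless disk-mean background-subtracted intensity over the event radius.
An event is *visible* while that signal exceeds 10% of its own peak;
lifetime is the visible extent.  Rise and decay run from the 10% crossing
to the edges of the 95%-of-peak plateau (the argmax of a flat noisy top
is unstable; the plateau edges are not).  The detector measures the same
observable (disk radius estimated from the detected area) with the same
10%/95% rules, with both crossings sharpened by a local linear fit.

What the generator does **not** emulate: optics (no PSF; Z-projection is
a 2D field), bleaching, cytoplasmic streaming, spot amalgamation into
bands, cell curvature (rectangular field), or spatially varying
background pH drift.  Passing recovery tests therefore demonstrates the
pipeline's correctness under the stated noise and kinetics, not
robustness to every artefact of real confocal data.

## Detection pipeline

Frames are Gaussian-smoothed (σ = 2 px; spots are many pixels wide, so
smoothing buys low-SNR detectability without displacing centroids), a
per-pixel baseline and scale are taken as the temporal median and
1.4826·MAD over the first 50 frames (robust to the sparse bright events;
static bands are absorbed into the baseline — the robust model is used
instead of a global threshold such as Otsu precisely because the
background is structured), and pixels above baseline + 5σ are grouped by
8-connectivity and filtered at 100 μm².  Tracking is greedy
nearest-centroid linking (10 μm per frame step, gap closing up to 2
frames, minimum 5 detections); spots are sparse and near-stationary, so
global assignment would add complexity without benefit — a documented
limitation for dense or fast-moving scenes.  Tracks are classified
transient/persistent at a 300 s lifetime cutoff.  Kymographs follow the
reslice-then-maximum-project recipe: rows are positions along an image
axis (or a user line), columns are frames, each entry the maximum over
the perpendicular extent.  Time is frame_index × frame_interval (0-based
frames); pixels are (row, col), 0-based, row 0 at top.

Thresholds were validated only against synthetic ground truth (the
original assessment was visual; there is no recorded criterion to match).
At amplitude SNR 5 over ten 1000-frame 256×256 movies the pipeline
recovers events with precision = recall = 1.0, lifetimes within 2 frames,
and rise/decay within 3 frames, and produces zero tracks on sorbitol and
control movies.

## Problem sizes

Default test and acceptance runs use: wall grids of 40–80 interior nodes
(lag converges to < 2% under halving); a 1 mV voltage grid; and the
ten-movie benchmark above.  These sizes were chosen as the point where
the measured quantities stop changing, and they run on a single CPU in a
few minutes.
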