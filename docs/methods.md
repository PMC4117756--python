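# Methods

## The kinetic model

`helifret` models a single surface-tethered RNA duplex (donor/acceptor
labeled, low FRET in the duplex state) worked on by RNA helicase A
(RHA/DHX9). One binding event decomposes into five substeps:

- **B** — binding wait: pseudo-first-order, rate `k_on · [RHA]`;
- **A** — activation: the lag between binding and the first unwinding
  attempt, rate `k_act`; under wild-type defaults this is the slowest
  step (rate-limiting);
- **U** — unwinding: FRET rises gradually from `E_low` toward `E_high`
  as the unwound strand coils and brings the dyes together; the dwell
  is exponential with rate `k_unw · [ATP]/(Km_atp + [ATP])`
  (Michaelis–Menten ATP dependence);
- **S** — stall: FRET holds at `E_high`, exit rate `k_stall`;
- **R** — reactivation: after an instantaneous rewind back to `E_low`,
  a second lag (`k_react`) before the next unwinding cycle.

Cycles `U → S → (rewind) → R → U …` repeat until one of three
competing processes ends them: dissociation (`k_off`, active in every
bound state; the molecule returns to the unbound pool and may rebind),
terminal strand separation (with probability `p_sep` at the end of each
completed stall; the labeled strand diffuses away and the spot goes
dark), or photobleaching of the dye pair (`k_bleach`, a single global
exponential clock). All dwells are drawn exactly (Gillespie-style) in
continuous time; the camera then samples the trajectory at `frame_s`
(0.1 s default).

### Observation model

Total intensity is `I_total` when unbound and `pife_gamma · I_total`
while protein is bound (protein-induced fluorescence enhancement), and
zero-mean background after strand separation or bleaching. FRET is
`E_low` in bound non-U states, a linear ramp across each U dwell
(truncated dwells end below `E_high` at the proportional ramp height),
and `E_high` in S. Channels are `I_A = E·T`, `I_D = (1−E)·T` plus
independent per-frame Gaussian noise of sd `sigma_noise` per channel;
no clipping is applied, so noisy frames can go negative.

### Condition dependence

- ATP enters only through the unwinding rate (Michaelis–Menten).
- Temperature: the 37 °C condition multiplies *every* kinetic rate
  (`k_on, k_act, k_unw, k_stall, k_react, k_off`) by `temp_factor`
  (default 3, inside the experimentally typical 2–5× band). A single
  uniform factor is a deliberate simplification; per-substep factors
  would require data the model does not anchor to.
- GC content: `k_unw` and `k_stall` are scaled by
  `exp(−gc_slope · (gc − 0.5))` so AT-rich duplexes unwind and stall
  faster; only the direction of this effect is anchored, the
  exponential form and `gc_slope = 2` are model choices.

### Default parameters

The two presets (`wild_type`, `delta_dsRBD`) live in
`src/helifret/presets.yaml`. Two numbers are anchored measurements:
`k_on = 2.61×10⁶ M⁻¹s⁻¹` and `Km_atp = 26 µM`. Everything else is an
assumption chosen so the qualitative kinetics hold:

| parameter | wt | ΔdsRBDs | rationale |
|---|---|---|---|
| k_act (s⁻¹) | 0.05 | 0.15 | activation slowest for wt; mutant activates faster |
| k_unw (s⁻¹) | 0.5 | 0.5 | unchanged by the truncation |
| k_stall (s⁻¹) | 1.0 | 1.0 | stalls are brief high-FRET shoulders |
| k_react (s⁻¹) | 0.3 | 0.3 | shorter than activation, longer than stall |
| k_off (s⁻¹) | 0.005 | 0.04 | wt binds stably through many cycles; mutant leaves quickly |
| p_sep | 0.15 | 0.7 | wt: median ≈ 4 cycles per event (2–10 band); mutant: usually one |
| k_bleach (s⁻¹) | 0.001 | 0.001 | dyes outlive a typical binding event |
| E_low / E_high | 0.2 / 0.8 | — | two-state construct levels |
| pife_gamma | 1.5 | — | clear, step-like binding marker |
| sigma_noise | 10 (5 % of I_total) | — | realistic EMCCD shot noise scale |
| k_anneal_bind / k_anneal_unwind (s⁻¹) | 0.002 / 0.010 | 0.001 / 0.002 | enhancement factor ≈ 5 (wt) vs ≈ 2 (mutant) |

## Trace analysis

**FRET and masking.** `E = I_A/(I_D+I_A)`, `T = I_D+I_A` per frame.
Frames are invalidated from the first run of 3 consecutive frames with
`T` below a floor (background + 3 robust noise sd, where the noise sd
comes from the median absolute frame difference); the mask is monotone
because signal loss (bleach or strand separation) is irreversible.
Raw E (can exceed [0,1] under noise) is kept for segmentation; clamped
E is used for histograms. Population histograms pool the first 10
valid frames per molecule, additionally requiring each pooled frame to
carry above-floor signal so dark molecules' noise spikes cannot leak
in.

**Step detection.** Binding and dissociation are change points of `T`.
The detector is recursive binary segmentation with a windowed
mean-shift z test: within each segment, up to `window` (8) frames on
either side of each candidate split are compared using a single global
robust noise sd (the noise is homoscedastic by construction; a local
variance estimate would be inflated by any second step inside the
window). A split is accepted when it clears a Bonferroni threshold of
`alpha` (0.05) over all tested positions, which keeps the per-trace
false-positive rate near 5 %. Accepted breakpoints are then refined to
the full-segment CUSUM maximum between their neighbours and pruned if
the adjacent segment means no longer differ significantly. Up-steps
are classified binding; down-steps are dissociation when the post
level stays above the floor, otherwise end-of-signal.

**Substep idealization.** Within each bound interval the (median
filtered, width 3) FRET series is banded: low (< 0.4), high (> 0.6).
The filter is skipped on effectively noiseless data, where it would
only erase genuine single-frame features. Same-band runs separated
only by mid-band frames are fused, so noise excursions that never
reach the other band are absorbed. The first low plateau after binding
is A; later ones belong to R (A/R disambiguation is purely
positional). Each unwinding ramp is bracketed by the interpolated
crossings of the two band edges and extrapolated linearly to the
plateau levels (configured construct values 0.2/0.8 by default; a
plain data median would be biased by ramp frames inside the bands on
slow ramps). The stall is the high block from the extrapolated ramp
end to the drop; rewind drop frames attach to the following R. A
terminal high block that never reaches the high plateau is classified
as a censored, still-rising U. Boundaries snap to the frame grid; a
dwell spanning frames `[a, b)` lasts `(b−a)·frame_s`. The final
segment of every event is censored — whatever ended the event
truncated it.

On noiseless simulated traces this idealization reproduces the ground
truth exactly at frame resolution: every frame label agrees except
within ±1 frame of a true transition (verified on 100 traces).
Substeps shorter than one camera frame sample no frames and are
unresolvable by any method at 100-ms framing; at the default rates
they affect well under 1 % of cycles.

## Rate inference

Substep dwells are exponential, so the MLE rate is the reciprocal mean
of the uncensored dwells with delta-method SEM `rate/√n` (a seeded
bootstrap is available). Censored dwells are excluded and counted.
Two systematic properties of this (standard) estimator are worth
knowing:

- *Competing-risk inflation*: a dwell that completes has, by
  selection, survived dissociation and bleaching, so its distribution
  is `Exp(k + k_off + k_bleach)`; with the wild-type defaults the
  inflation is ≤ 0.006 s⁻¹ per substep (12 % of the activation rate,
  ≤ 1 % of the faster ones). Recovery tests compare against the
  competing-risk rate where this matters.
- *Off-rate inflation*: the off rate from uncensored total bound times
  conditions on observing dissociation before strand separation,
  bleaching or the end of the recording; under wild-type defaults the
  measured value (~0.02 s⁻¹) exceeds the generating `k_off` (0.005)
  several-fold. Comparisons that use the off rate (flatness across
  protein concentration, wild type vs mutant ordering) are unaffected
  because the inflation does not depend on concentration and is far
  larger for the mutant.

Higher-level fits: the association constant is a zero-intercept
weighted least-squares slope of binding rate vs [RHA] (the rate must
vanish at zero protein; a free intercept is available for
diagnostics); the ATP dependence is a Michaelis–Menten nonlinear fit
(initial guesses: max rate, concentration nearest half-max); the FP
binding curve is a hyperbolic isotherm with an identifiability flag;
temperature effects are per-substep rate ratios with propagated SEs.
When per-point errors are supplied, linear-fit parameter covariances
use those errors as absolute (no rescaling by the few-degree-of-freedom
residual variance, which would make slope tests on 4–7 point designs
badly over-dispersed).

## Annealing analysis

Each tethered duplex acquires its complementary strand at an
exponential time: rate 0 without protein, `k_anneal_bind` with protein
but no ATP (binding-induced partial melting), `k_anneal_unwind` with
protein and ATP (repetitive unwinding exposes the strand). Snapshot
counts give fractions with Wilson intervals; the rate comes from a
least-squares fit of `f(t) = 1 − exp(−kt)` (an initial-slope
alternative agrees within errors and is exposed). The enhancement
factor is the ratio of the +ATP to −ATP rates with propagated SE; as a
ratio of rates it is invariant to the number of molecules imaged.
Degenerate curves (all zero, all saturated) are flagged rather than
fitted. Both the fitted rate and the endpoint fraction are reported,
since either summary can be used to compare conditions.

## What the generator does and does not emulate

Emulated: exponential substep dwells; gradual FRET rise and abrupt
rewind; abrupt total-intensity steps on binding/dissociation (PIFE);
photobleaching; terminal strand separation; per-frame additive
Gaussian noise at 100-ms framing; rebinding after dissociation;
deterministic per-molecule substreams from one root seed.

Not emulated: donor leakage, gamma correction, dye blinking,
intensity drift, diffusing background spots, multiple simultaneous
binders, partial-unwinding amplitude structure, sequence-explicit
duplex energetics, or alternative labeling geometries (only the
low→high FRET construct is simulated). Whether rewinding reflects
enzyme back-slipping or duplex rezipping is not modeled — the
instantaneous drop is an operational choice. Strand separation is
modeled only at the end of a completed cycle. Consequently, passing
tests demonstrate that the inference chain recovers the model's
parameters from data *of this structure*; they do not certify
robustness to the photophysical artifacts real movies add.

## Numerical choices and problem sizes

- Zero rates are treated as infinite dwells (never fire); degenerate
  fits are flagged, never silently numeric.
- CSV/HDF5 round trips preserve float64; report JSON records package
  version, seed and a config hash; identical config + seed reproduces
  outputs byte-for-byte.
- Test and acceptance problem sizes were chosen to make the checks
  sharp but cheap: 100–160 traces × 250 s for rate recovery (~200
  binding events, ~850–1000 cycle dwells), 60 traces per grid point
  for the invariance suites, 5000 molecules × 10 frames per condition
  for the population histograms, 2000 molecules for annealing fields,
  200 dwells per concentration for the Km and association-constant
  recoveries (the sample sizes of the corresponding study design).
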