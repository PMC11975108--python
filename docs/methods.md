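# Methods

This note documents the models, algorithms and design choices behind
`gaitloop`, in the order the pipelines run. Units throughout: lengths mm,
mouse forces mN, human-model forces N, voltages V, times s, frequencies Hz.
Every delimited file carries units in its header to keep the human-model and
mouse scales from being mixed up.

## Species scaling of gait traces

A human walking simulation provides, for one gait cycle, the muscle fiber
length `L_human(t)`, the excitation `u(t) ∈ [0, 1]`, and the force of soleus
and EDL. Length is made dimensionless by the human optimal fiber length and
re-expressed as a signed change about the mouse optimal length:

    L~(t)       = L_human(t) / Lo_human
    dL_mouse(t) = L~(t) · Lo_mouse − Lo_mouse

The two steps compose to the affine map `(L/Lo_h − 1)·Lo_m`, which the test
suite checks against a one-line oracle at every sample. Forces are compared
across species only after normalization: human forces by the
musculoskeletal-model maximum isometric force, mouse forces by the maximum
measured in the pre-protocol force–frequency series.

No source prints the architecture constants themselves (optimal lengths,
maximal forces); they are required inputs. The values used in examples and
tests (human soleus Lo 44 mm / 2800 N, EDL 69 mm / 350 N; mouse Lo 12–12.5
mm) are representative of human lower-limb models and mouse muscle and are
labelled as such, never as measurements.

### Command discretization

Commands live on a uniform grid at 222 Hz, the rate at which stimulation is
synchronized with length change. One cycle at 1 cycle/s therefore holds
exactly 222 samples. The grid is half-open (the cycle end is exclusive), so
concatenated cycles never duplicate their boundary sample. Resampling from
the simulation grid uses shape-preserving piecewise-cubic interpolation
(PCHIP): a naive cubic can overshoot at the stance/swing turnarounds, and an
overshoot in a length command is a real displacement error at the lever arm.
PCHIP never leaves the local data range, so command extrema match the source
extrema to within one sample's slew (property-tested).

The human cycle (1.101 s at the walking cadence of 109 steps/min, i.e.
2·60/109 s per stride) is time-warped — not truncated — to the 1-s mouse
cycle; warping preserves the within-cycle phase relationships, which is what
the protocol aims to replicate.

### Eccentric waveforms

One repetition is a 500 ms isometric hold at optimal length followed by a
constant-rate ramp at `strain_rate · Lo` per second until the displacement
reaches `strain · Lo` (200/400/600 ms ramps for 10/20/30 % at 0.5 Lo/s).
The ramp sample count is `round(duration · sample_rate)` and the commanded
endpoint is then recomputed from the realized duration, so the final sample
equals `strain · Lo` exactly: the apparatus cares more about the delivered
strain than about a sub-sample error in rate. Rounding is always explicit —
never silent truncation. Eccentric commands default to a 1 kHz grid so the
published ramp durations are exactly representable; the voltage channel
carries a constant 30 V envelope (the supramaximal amplitude) with the 80 Hz
pulse frequency recorded as metadata.

### Voltage mapping and timelines

Excitation maps linearly onto the active voltage range and is multiplied by
a single calibration scale factor; the initial range is 0–20 V and the
escalated range 0–80 V. Timelines are ordered, non-overlapping event lists:
3 twitches and 3 tetani at 150 Hz (1 min apart), a 10-min quiescence, a
force–frequency series, then the protocol body. The force–frequency steps
are 1, 10, 20, 40, 60, 80, 100, 120, 150, 180 Hz — the endpoints and the 80
and 120 Hz anchors are fixed by the protocol's own normalizations; the
intermediate spacing is this package's choice, as no step list is published.
The 200-cycle protocol runs 8 sets of 25 cycles with 60-s inter-set rests; a
120-Hz viability tetanus is placed 1 s into the rest after cycle 100 (the
rest event is shortened so events never overlap), another follows 1 min
after the last cycle, and the post-force-frequency starts after 10 min. The
full 200-cycle timeline spans ~61 min, safely inside the 1.5-h budget the
protocol is designed for. The eccentric timeline runs 5 repetitions with
4-min quiescence and recovery tetani at 5/10/15/30 min after the final
stretch.

## Hill-type virtual muscle

The calibration step needs a muscle to push against. The simulator composes

    F(t) = Fmax · ( a(t) · fl(L/Lo) · fv(v) + fp(L/Lo) )

with:

* **Activation** `a`: first-order lag of excitation, rise constant
  `tau_act` (15 ms) and fall constant `tau_deact` (50 ms), integrated by the
  exact exponential update per step (unconditionally stable; sub-stepping
  engages if a time constant approaches twice the command step).
* **Active force–length** `fl`: Gaussian bell, 1 at optimal length,
  `exp(−1)` at `1 ± fl_width` (width 0.45).
* **Force–velocity** `fv`: hyperbolic Hill branch for shortening (zero at
  `−vmax`, curvature 0.25) and a saturating lengthening branch
  `1 + 0.4·v/(v + 0.25·vmax)` capped at 1.4× isometric — the classic
  eccentric plateau.
* **Passive** `fp`: zero at or below optimal length, exponential above,
  reaching one Fmax at 60 % strain.

Voltage maps to excitation through a saturating sigmoid (half-activation
12 V, slope 3 V) rebased so 0 V gives exactly zero excitation and ~30 V is
maximal, matching the observation that 30 V elicits maximal twitches and
tetani. All constants are explicit testbed defaults for a generic fast
mouse muscle — the real protocol runs on living muscle, and nothing here is
claimed to be physiological; the tests rely only on structural properties
(closed-form steady states, linearity in Fmax, eccentric monotonicity), not
on the default values.

## Voltage calibration

The matching criterion is the **peak normalized force over the cycle**
(per-cycle peaks are also what the downstream analysis reports). The
procedure mirrors the bench workflow: simulate at range 0–20 V, scale 1; if
the peak misses the target by more than the tolerance (default 0.05, i.e.
5 % of Fmax), escalate to 0–80 V and bisect the scale factor over [0, 8]
(four times the range ratio, spanning the escalation) on the peak-force
error. Bisection is justified by the monotone peak-vs-scale response, which
is itself property-tested; convergence on attainable targets takes ≤ 25
simulator evaluations. An unattainable target (above the muscle's eccentric
ceiling) returns a diagnostic result with `converged=False` rather than
raising — it is an experimental outcome, not a programming error.

## Histology pipeline

Order of operations, with the reasoning for each choice:

1. **CLAHE** on the laminin channel (clip limit 0.01, 64-px tiles; both
   exposed). A flat image passes through unchanged.
2. **Adaptive threshold**: after a 1-px Gaussian pre-smoothing, a pixel is
   border when it exceeds the local mean of its (51 px, odd) neighborhood
   plus `(0.5 − sensitivity)·σ`; sensitivity 0.5 is the plain local-mean
   rule. The pre-smoothing matters: CLAHE equalizes flat background, so
   unsmoothed pixel noise thresholds into dense speckle.
3. **Despeckle, clear frame, close gaps** — in that order. Despeckling
   (components ≤ 32 px removed) must precede frame clearing: the border
   network is one connected web, and a single chain of noise specks linking
   it to the frame would otherwise delete the web wholesale. Gap closing is
   a morphological closing with a 2-px disk, bridging border gaps up to
   ~3 px.
4. **Segmentation**: 10 iterations of morphological Chan–Vese active
   contouring initialized from (and run on) the binarized mask — region
   fidelity anchors the contour while the curvature term smooths ragged
   borders; an intensity image can be substituted when its two-phase
   contrast is trustworthy, which a CLAHE'd noisy image is not. Then the
   Euclidean distance transform of the interior is computed, shallow minima
   of its negation are suppressed (h-extrema, depth 2 px) so noise basins
   spawn no watershed markers, and a marker watershed splits touching
   fibers. Finally 15 more active-contour iterations smooth the fiber
   boundaries (only removals are applied, so labels never bleed across
   borders). Fibers are 4-connected, borders 8-connected — diagonal leakage
   through a thin border is impossible. Regions touching the image frame
   (the section exterior basin) and regions under 50 px are discarded;
   labels are renumbered in raster order for determinism.
5. **Layer peeling**: the published rule removes the outer two layers of
   fibers without defining a "layer". The definition used here: expand every
   fiber's label through the border zone to a full Voronoi territory
   (`expand_labels`); a fiber is in the current outer layer iff its
   territory reaches the image frame, i.e. it faces the exterior with no
   other included fiber in between. Remove that layer and repeat. This is
   parameter-free, and peeling n=1 twice is identical to peeling n=2 by
   construction (already-excluded fibers count as exterior). On a square
   5×5 lattice it reproduces the hand-countable 16/8/1 ring structure; on
   hexagonal lattices it can disagree with naive grid rings at offset-row
   edges, which is geometrically correct behavior — the reference truth for
   accuracy scoring is therefore peeling applied to the *perfect* truth
   labels.
6. **Positivity**: per fiber, the dye-mask area over the fiber's own pixels;
   positive iff the fraction **strictly** exceeds 0.5 (a fiber at exactly
   50.0 % is negative). The dye channel is binarized by a global threshold
   (default 0.5 of the [0, 1] scale); the bench threshold was calibrated
   against 16 manual segmentations that are not available, so an Otsu auto
   mode exists as a clearly flagged alternative. Dye fractions are computed
   on raw red intensities — no contrast operation touches the red channel.
   The section readout is `100 × #positive included / #included`; zero
   included fibers is an explicit error, never reported as 0 %.

## Synthetic data

The mosaic generator emulates what the pipeline consumes, not how a confocal
microscope forms images (no point-spread function, no photorealism):
jittered hexagonal (or square) seed lattices tessellated by nearest-seed
assignment into polygonal fibers (~30 px spacing, ~3 px borders), clipped by
the convex hull of the lattice so rim cells stay compact — distance-ball
clipping was found to create necked crescent cells that any watershed
correctly (but unhelpfully) splits. Corruptions are per-fiber border gaps of
a stated true width and additive Gaussian noise clipped to [0, 1]. Dye is
rendered into an exact count of randomly chosen fibers at a controllable
coverage fraction (innermost pixels first), so ground truth is exact by
construction; generators are pure functions of (spec, seed).

Gait-trace templates use a two-harmonic periodic length shape starting 2 %
of Lo below optimal length (all gait cycles start below optimal), with
peak-to-peak excursions of 40 % (soleus) and 20 % (EDL) of Lo — the study
conditions — and smoothed boxcar excitation bursts: one stance burst for
soleus, swing + heel-strike bursts for EDL, which is what gives EDL its
characteristic two-peak force cycle. The force channel is a plausibility
signal (excitation × force–length factor), used as a calibration target
shape but never as ground truth.

What passing tests show, and what they do not: exact percent-positive
recovery on these mosaics demonstrates the pipeline's logic (thresholding,
splitting, peeling, scoring) is correct under controlled geometry and the
stated corruption levels; it does not certify performance on real sections,
where staining variability, out-of-focus light and irregular fiber shapes
exceed anything the generator produces. The exposed parameters
(sensitivity, despeckle size, suppression depth, dye threshold) are the
knobs a real deployment would need to re-tune against manual counts.

## Force metrics and small statistics

Per-cycle peaks are strict local maxima (plateaus resolve to their first
sample) with a minimum separation of 10 % of the cycle duration in two-peak
mode; a missing second peak is reported as missing, and a cycle with no
interior maximum (monotone ramp) reports its maximum sample flagged as a
boundary case. Eccentric series normalize to the first contraction (the
first entry is exactly 1), cycling series to the pre-protocol
force–frequency maximum; force loss is `1 − post/pre` and may be negative
(force enhancement is a real observation in soleus, not an error).

Dixon's test uses the size-dependent ratio variants standard in practice —
r10 for n ≤ 7, r11 for 8–10, r21 for 11–13, r22 for 14–30 — with the
two-tailed 95 % critical values from Rorabacher's 1991 tabulation (the only
alpha shipped; the analysis it serves tests at 0.05). Both extremes are
evaluated and the larger ratio is the suspect; at most one value is removed
per pass, one pass by default; a zero-range sample removes nothing, and the
decision is invariant to affine transforms of the data (property-tested).
Holm–Bonferroni is implemented directly (step-down rejection plus the
monotone adjusted p-values) and cross-checked in the test suite against
statsmodels' independent implementation; it provably rejects a superset of
Bonferroni and a subset of unadjusted testing. Mixed-effects modelling is
deliberately out of scope — the module emits tidy per-cycle/per-recovery
tables that any LME tool can consume.

## Problem sizes and determinism

Test and acceptance runs use 11×11 mosaics (121 fibers, ≥ 50 surviving
two-layer peeling, ~340×400 px), five clean and five corrupted seeds, and
single-cycle simulations at 222 Hz — sizes chosen so the entire suite runs
in well under a minute per pipeline while every claim is still exercised at
the stated fiber counts. All randomness flows from explicit seeds
(generator specs carry their seed; the acceptance script derives all seeds
from its `--seed`); CLI runs record inputs, parameters, version and seed in
a JSON manifest next to their outputs.

## Known limitations

* The layer-peeling definition, while principled, is one reading of "outer
  two layers"; sections with deep concavities may peel differently than a
  human annotator would.
* The Hill testbed omits fatigue, residual force enhancement and calcium
  dynamics; calibration transfers to living muscle only as a starting
  point.
* The dye threshold default stands in for a manual-count calibration that
  cannot be reproduced here.
* Gait templates are stylized single cycles; subject-specific simulation
  exports should be used where available (the CSV reader accepts any trace
  with the documented header).
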