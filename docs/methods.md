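# Methods

`nanolock` models a digital immunoassay read out on a solid-state
nanopore.  A linear ~400 bp DNA probe ("NanoLock") with two 25 nt
single-stranded overhangs circularizes when a bridging reporter strand
hybridizes both overhangs; reporters are released in proportion to the
protein target by an upstream bead/AuNP immunoassay.  On the pore,
closed probes read as a digital "1" and open probes as "0", and the
target concentration is inferred from the counted closed fraction
rather than from the absolute event rate.  The package simulates the
whole chain with known ground truth and implements the analysis used on
real recordings.

## Trace synthesis

A recording is a baseline open-pore current `G_open * V` plus
rectangular conductance blockades, white Gaussian input noise, and a
causal low-pass Bessel filter cascade (analog hardware stage, then the
200 kHz software analysis stage applied at detection time).

Translocation geometries, for a single-file dwell draw
`tau ~ LogNormal(median 100 us, sigma 0.4)`:

| geometry | segments | digital truth |
|---|---|---|
| single file (ruler, end-captured open probe) | 1x for `tau` | 0 |
| circular (closed probe) | 2x for `tau/2` | 1 |
| folded (open probe captured at contour position `p`) | 2x for `m*tau`, then 1x for `(1-2m)*tau`, `m = min(p, 1-p)` | 0 |

The blockade area (event charge deficit) is identical across the three
realizations of the same dwell draw; the suite asserts this exactly on
ground truth and within 5% after detection.  Open probes are captured
by an end with probability 0.75 (persistence-length argument: the probe
is only ~2.7 persistence lengths long), otherwise at a uniform contour
position.  A capture near the midpoint leaves a 1x tail too short to
resolve at 200 kHz and is counted as a circular false positive — the
mechanism behind the sub-percent false-positive floor of the digital
scheme.

Defaults: 1x blockade 5 nS (so 2x = 10 nS), open-pore conductance
40 nS, 150 mV bias, 60 pA RMS noise at the 200 kHz analysis bandwidth
(the white input noise is scaled by the numerically computed equivalent
noise bandwidth of the filter cascade), zero baseline drift (a linear
drift option exercises the baseline tracker).  Capture is a Poisson
process per species with rate proportional to concentration
(0.0157 Hz/nM, i.e. ~0.47 Hz at 30 nM); overlapping events are
re-drawn, with a diagnostic failure beyond 100 retries.  Velocity
fluctuations within an event, electroosmotic effects and pore-geometry
physics are not modelled; dwell statistics and the noise spectrum are
stated choices, not measured quantities.

Sampling rates: the configuration default is the hardware chain
(4.17 MHz sampling, 1 MHz analog bandwidth).  The packaged studies and
most tests run at 1 MHz sampling with the same 200 kHz analysis filter
— the filter, not the sampler, limits time resolution, and this keeps
multi-thousand-event studies tractable.  When the sampling rate is
within ~2.2x of the analog bandwidth the separate analog stage is
skipped: it cannot be designed at Nyquist and the analysis filter
already band-limits the signal.  Study runs also use a densified
capture rate (50 Hz) purely to shorten the simulated recording; events
stay ~200x sparser than their duration, so pile-up remains negligible.

## Event detection

Detection operates on the 200 kHz-filtered signal:

1. **Baseline**: block-wise (10 ms) median/MAD estimates, iteratively
   re-estimated after masking excursions beyond `5 sigma`, so events do
   not bias the baseline; tracks drift at the block scale.
2. **Windows**: an event opens when the current drops more than
   `5 sigma` below baseline and closes when it returns within
   `1 sigma`; windows are padded by one filter rise time
   (`~0.34/f_c`), filtered by duration limits (10 us – 5 ms), and
   discarded at trace boundaries.
3. **Sublevels**: two-sided CUSUM for mean shifts in Gaussian noise,
   standardized units, against the running segment mean.  The reference
   shift `delta` defaults to 60% of the 1x level spacing; the decision
   interval `h` defaults to the value whose in-control average run
   length (Siegmund's approximation) is 10x the longest allowed event.
   The change point is the arg-extremum of the cumulative score before
   the alarm.  Adjacent sublevels closer than `delta` merge, as do
   sublevels shorter than one rise time (into the closer-mean
   neighbor).  Sublevel means exclude one rise time at each span edge,
   where the Bessel response smears transitions; without this trim the
   fitted levels of short events are biased shallow by several percent.
4. **Features**: dwell, deepest-sublevel blockade divided by voltage
   (max blockage, nS), and the ECD (integrated blockade, pC).

An exhaustive least-squares dynamic-programming segmentation serves as
the independent change-point oracle in tests (windows up to a few
thousand samples).

## Classification

A 400 bp dsDNA ruler run on the same pore calibrates the 1x level
(`delta_g_1x`): dominant histogram mode refined by a single-Gaussian
fit within +-30%, with a bimodality failure for contaminated runs.
Events are classified on the normalized depth `b = max_blockage /
delta_g_1x` with tolerance 0.35: the `1 +- t` band is single file
(bit 0); the `2 +- t` band is folded (bit 0) when a ~1x trailing
sublevel of at least `min_tail = 2x` rise time follows a ~2x sublevel,
otherwise circular (bit 1); anything else — band gap, deeper than
`(2+t)x` (co-translocation), shallow-before-deep shapes (which defy
tension propagation), out-of-range dwell — is rejected and excluded
from the count but tallied.  Classification is scale-invariant under a
common pore-size factor, which is the point of the ruler.  No false-
positive subtraction is applied; the floor is absorbed by the standard
curve.

## Quantification

The digital estimate is `f = n1/(n0+n1)` over counted events with a
Wilson 95% interval (correct coverage at small counts and extreme
fractions).  The analog estimate is the capture rate of bit-1 events,
by count-over-time (exact Poisson CI) or the censored-interarrival
exponential MLE.  Standard curves are unweighted least-squares 4PL fits
`y = d + (a-d)/(1 + (x/c)^b)` with multi-start initialization
(inverse-variance weighting optional), fitted on the monotonic branch
(reporter <= probe); hook-regime samples are resolved by split/dilution
— both aliquots measured, the higher fraction inverted on its own
curve, ties preferring the undiluted branch.

LoD is the concentration whose fitted response is 2.5 blank standard
deviations above the blank (blank SD across three replicate blank runs
by default; a config knob).  When the fitted curve's zero-concentration
response sits above the measured-blank threshold — a fit-offset
artifact common for strongly scattered analog responses — the threshold
is re-anchored at the curve's own blank response plus the same 2.5 SD
increment and flagged; with a zero blank SD the LoD degenerates to the
bottom of the calibrated span and is flagged as clamped.  Below-span
LoDs are returned flagged as extrapolated.

The paired digital/analog LoD study simulates the same event sets for
both readouts: 14,000 nominal events per run (the scale of the
original experiments), triplicate blanks, standards at 30 pM–30 nM
(reporter) with probe fixed at 30 nM, and an independent log-normal
capture-rate multiplier (CV 50%) per run emulating pore-to-pore and
run-to-run variability.  The closed fraction is multiplier-invariant by
construction; the bit-1 rate is not, which is the self-calibration
claim.  The study statistic is the median LoD ratio over 101
independent curve-pair replicates; single-pair ratios are heavy-tailed
because a 3-replicate SD estimate has only two degrees of freedom.

## Circularization kinetics

Irreversible network with hook effect:

    R + P -> H    rate 2 k_bind [R][P]   (either free overhang)
    H     -> C    rate k_close [H]       (intramolecular closure)
    R + H -> X    rate k_bind [R][H]     (second reporter caps the probe)

Deterministic integration (LSODA, rtol 1e-9) and an exact stochastic
simulation with identical propensities (>= 100 molecules enforced;
default volume 0.5 pL ~ 9e3 probes at 30 nM) agree within Monte-Carlo
error.  Equilibrium evaluation doubles the integration horizon until
the closed fraction converges: at reporter:probe ratio exactly 1 the
approach is algebraic (`R = P` decays second order) and a fixed horizon
would bias the hook maximum.

Rate constants are not separately observable in the assay.  Defaults:
`k_bind = 1e5 1/(M s)` (short-overhang hybridization order of
magnitude) and `k_close = 3.71e-4 1/s`, solved numerically so the 0.4:1,
30 nM condition reaches equilibrium (2% band) in 3.0 h, matching the
assay's incubation behavior.  Conclusions tested are limit and shape
properties, not absolute rates.  In the fast-closure limit
(`k_close/(k_bind P0) >= 1e3`) the equilibrium response approaches
`f = x` on `x <= 1` within 1%.

One subtlety is documented rather than hidden: at exact 1:1
stoichiometry every capped probe consumes two reporters and strands one
probe unclosed, so the network's true equilibrium optimum sits at
slight reporter excess (near `x ~ 1.15`, by a margin of order
`0.2 k_bind P0 / k_close` — a few parts in 1e4 in the fast-closure
regime).  This margin is far below what any counting measurement
resolves (distinguishing it would need >1e8 events), so
`hook_maximum` reports the peak at counting-resolvable precision: the
smallest grid ratio within 1e-3 of the response plateau, i.e. the onset
of saturation, which is 1.0.  The monotone decline beyond the plateau
(x >= ~1.3) is strict.

Observed fractions map the model through a phenomenological floor
(default 0.008, the blank level: mid-fold false positives, spontaneous
misfolding, probe dimerization) and ceiling (default 0.95, incomplete
circularization at saturation); neither is mechanistic.

The amplification chain is arithmetic: released reporter concentration
= target x capture efficiency x reporters per AuNP (default 200) x
release efficiency x volume concentration factor (default 500/30);
divided by the probe concentration it gives the effective ratio `x`,
and the dose response closes the loop back into a trace-synthesis
mixture.

## What the synthetic data does and does not show

The generator reproduces the signal chain (levels, filter, noise,
Poisson capture, fold positions) but not: 1/f noise and real noise
spectra, intra-event velocity fluctuations, clogging, multi-molecule
co-translocations, matrix effects beyond a dilution factor, or
capture-rate differences between open and closed probes (assumed equal;
any bias would fold into the standard curve).  Passing tests therefore
validate the *analysis* — detection, calibration, classification,
quantification, kinetics — under a faithful but idealized signal model;
they do not certify performance on real recordings.  Blank-level false
positives in real plasma data are attributed partly to upstream assay
chemistry, which is represented here only by the phenomenological
floor.

## Numerical choices and degenerate inputs

- Determinism: every stochastic stage takes a seed or Generator; equal
  seeds give bit-identical traces and reports.
- Noiseless traces: MAD-based sigma degenerates to 0; thresholding
  substitutes an epsilon, and the ruler calibration returns an
  (effectively) zero-width fit rather than failing.
- CUSUM threshold solving uses Siegmund's approximation in log domain
  (overflow-safe at the very large standardized shifts of noiseless
  data), floored at h = 0.01.
- The 4PL fit refuses fewer than 5 points, non-finite or constant
  responses; the inverse refuses responses outside the fitted
  asymptotes, with a hook-suspect diagnostic above the upper asymptote.
- Events touching the trace boundary are discarded; windows shorter
  than 10 us or longer than 5 ms are rejected and tallied.

## Study sizes

Packaged studies (also used by `scripts/acceptance.py`): 20,000 events
for the false-positive bound, 600 events per geometry for level
recovery, 101 curve-pair replicates for the LoD comparison, and a
25-point ratio grid for the hook maximum.  These sizes give sampling
error comfortably below the asserted tolerances (e.g. binomial SE
~0.07 pp at 20,000 events for a ~0.9% rate).
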