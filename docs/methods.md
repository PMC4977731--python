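# Methods

## Signal models

All supported acquisitions reduce to a three-parameter mono-exponential in
the preparation time *t* (ms). For magnetization recovery (inversion or
saturation prepared),

    S(t) = A (1 − B e^(−t/τ)),

where A is the equilibrium signal amplitude (arbitrary units), B the
dimensionless preparation-efficiency factor (ideally 2 for inversion, 1 for
saturation) and τ the longitudinal time constant. Magnitude-reconstructed
variants wrap the prediction in |·|; phase-sensitive (PSIR) variants keep
the sign and expect polarity-restored input — the package never
reconstructs sign from phase data. For transverse decay,

    S(t) = A e^(−t/T2) + B,   B ≥ 0,

with B an additive signal offset (2-parameter variants pin B at its ideal
value: 2, 1 or 0). Two-parameter fits are unavailable for MOLLI because the
efficiency factor there is a fitted physical quantity, not a nuisance
parameter: the continuous bSSFP readout shortens the apparent constant to
T1\*, and the Look-Locker correction T1 = T1\*(B − 1) converts back. Fitted
B ≤ 1 would make the correction non-positive; such pixels are flagged and
excluded rather than silently emitted.

The saturation-recovery row is written without a modulus, matching the
model table it implements; with B > 1 its prediction can dip slightly below
zero at very short saturation times even though SR maps are computed from
magnitude images.

## Initialization

**T1 (lookup table).** A two-pass grid search over 0–4000 ms: a 50 ms
coarse pass, then a 5 ms pass within ±100 ms of the coarse winner. Each
pixel series is normalized by its maximum absolute value; candidate curves
assume unit amplitude and ideal efficiency and are likewise normalized by
their own maximum over the schedule, so the comparison is amplitude-free on
both sides — without this the noiseless example "grid contains the true T1"
would not score zero error. Scoring is the sum of absolute errors; ties
break toward the smaller T1 (grids are evaluated in ascending order). The
τ → 0 grid entry uses the limit e^(−t/τ) → 0 (t > 0).

**T2 (weighted log-linear regression).** log S = log A − t/T2 is fitted by
linear least squares with weights S² (the first-order compensation for the
variance inflation of log-transformed data; the weighting scheme is a
package choice, as only the regression itself is prescribed). The fit is
repeated while truncating the longest echo stepwise until three points
remain; each candidate is scored by the absolute error of its
back-transformed curve over *all* samples, and the minimum wins. Truncation
matters when an offset contaminates the tail. Non-positive samples are
dropped before the logarithm; fewer than three survivors mark the pixel
unrefined.

## Exclusion

Initial T2 estimates outside the *open* interval 0 < T2 < 400 ms are
excluded before refinement and emitted as 0, with the pixel flagged in the
exclusion mask. Because the bound is open, estimates within 10⁻⁶ ms of a
bound are classified outside: a noiseless series generated exactly at the
boundary initializes to 400 ms only up to floating-point rounding, and the
guard keeps the boundary classification deterministic. T1 estimates are
confined to the 0–4000 ms lookup range by construction; unrefined pixels of
either family emit 0, mirroring the T2 rule.

## Nelder-Mead refinement

Refinement minimizes the sum of squared residuals (sum of absolute
residuals is available via `FitSettings.objective`; least squares is the
community default and the refinement objective is otherwise unspecified)
over (A, τ) or (A, B, τ) with a standard Nelder-Mead simplex (reflection 1,
expansion 2, contraction ½, shrink ½). The implementation is in-package
because the convergence rule and the acceptance diagnostics need the
simplex trajectory, which library optimizers do not expose; scipy's
Nelder-Mead serves as an independent cross-check in the test suite.

Numerical choices:

- **Initial simplex.** Vertices at the initial point plus a 5 % perturbation
  per coordinate; absolute fallbacks for zero coordinates (5 ms for τ, a
  twentieth of the amplitude for a zero offset) keep degenerate starts
  non-singular. Initial values: A = max |S| of the series, B at the ideal
  efficiency (T1) or 0 (T2 offset), τ from the initializer.
- **Constraints by reparameterization.** The T2 offset enters the objective
  as |B|, so the vanilla unconstrained simplex respects B ≥ 0. Non-positive
  τ is rejected with an infinite objective.
- **Convergence.** The simplex is converged when the maximum absolute
  change of the τ coordinate over corresponding (rank-ordered) vertices of
  consecutive simplexes falls below 0.10 ms *and* the simplex has collapsed
  geometrically (per-coordinate diameter ≤ 10⁻⁵·max(1, |best|)). The second
  condition guards against a failure mode of the τ-only rule: in the
  3-parameter T2 fit without an anchor the simplex can transiently stall in
  τ while still crawling along the flat A/B valley, stopping ~6 % off with
  the offset un-estimated. Restarting converges back to the same point;
  requiring geometric collapse resolves it at ~50–150 iterations per pixel.
  At termination the τ spread is below 0.10 ms either way, and the
  best-vertex objective is non-increasing throughout (both are recorded per
  fit and aggregated in map diagnostics).
- **Iteration cap.** 1000 iterations; pixels hitting the cap are marked
  unrefined (map value 0) rather than raising.
- **Divergence.** A non-finite objective at the start excludes the pixel.

**SR anchor.** For T2-prepared bSSFP 3-parameter fits, a saturation-recovery
image with short saturation time can be appended to the series. Its model
prediction is the asymptote B (an effective infinite-preparation sample),
and it enters the objective as one additional equally weighted residual.
How the anchor enters the objective was genuinely open; the extra-sample
reading anchors the offset, which is the anchor's stated purpose, and
degrades gracefully when B is small. The anchor frame carries a NaN time in
the series (it is a flag, not a finite preparation time) and is left out of
residual computation.

## Residuals

The curve-fit residual of a pixel is the mean absolute difference between
the fitted curve and the samples, normalized by the pixel's maximum
absolute signal, reported in percent. It is scale-invariant and defined
only where the fit refined (NaN in the residual map elsewhere); for MOLLI
it is evaluated against the fitted T1\* curve.

## Map assembly

Pixels are fitted independently, so ROI-restricted maps equal the full map
sampled at the ROI and maps are invariant to consistent frame/time
permutations (frames are sorted by time internally). Pixels whose peak
signal falls below 1 % of the image maximum (configurable) are skipped as
background — real series carry large signal-free regions and refined-pixel
counts in map reports reflect this gate. ROI-mean fitting averages the
signal over the mask per frame and runs the identical single-pixel
pipeline, so both routes satisfy the same convergence criterion. A
pixelwise 3-parameter fit of a full-coverage 192×144, 15-frame series takes
roughly 15–35 s on one CPU (pure-Python inner loop; the per-map problem
sizes in the tests are chosen around this).

## Phantom simulator

The simulator emulates a 12-vial gadolinium/agarose gel set (Eurospin-like)
on a 3×4 grid with a 10 % margin: circular vials, homogeneous parameters,
zero-signal background. Presets span the reference ranges T1 214–1643 ms /
T2 46–338 ms ("1.5T") and 229–1752 ms / 45–316 ms ("3T"), log-spaced with
endpoints included — only the ranges are standardised, so interior values
interpolate. Default timing schedules per model mirror typical phantom
protocols (17 IR spin-echo TIs from 21–4300 ms, 18 SR delays to 8000 ms,
16 multi-echo TEs 9–144 ms, T2-prep durations 25–200 ms in 5 ms steps,
etc.). Default amplitude is A = 100 with ideal efficiency; noise defaults
to zero and is otherwise specified directly as σ (SNR 50 ⇒ σ = 2).

Noise is Rician for magnitude conventions (modulus of two independent
Gaussian-corrupted channels — the standard magnitude-MR statistics) and
additive Gaussian for signed (PSIR) data; generation is deterministic under
a fixed seed.

MOLLI acquisitions are simulated phenomenologically: the merged inversion
times of the 5(3b)3 and 4(1b)3(1b)2 breath-hold schemes are built from
per-epoch inversion times TI_k = 130 + 80·k ms plus multiples of the
cardiac interval (at 60 bpm, 5(3b)3 yields the familiar eight delays
130…4130 ms), and the signal follows the T1\* model with a user-chosen B
(vial T1 values are *true* T1; the synthesized T1\* is T1/(B − 1), so the
Look-Locker correction recovers the truth exactly). The simulator does
**not** solve Bloch equations: readout-induced T1\* perturbation beyond the
phenomenological model, the T2 sensitivity of MOLLI at low T2, slice
profiles, B0/B1 inhomogeneity, partial volume and motion are all outside
its scope. Passing tests therefore demonstrate correctness of the
estimation pipeline under the assumed signal models and noise statistics,
not accuracy on scanner data subject to those system effects.

## Agreement statistics

The modified Bland-Altman analysis plots candidate-minus-reference
differences against the reference (not the pair mean). Bias is the mean
difference, variability the sample (n−1) SD, limits of agreement
bias ± 1.96·SD; percentage forms divide each pair's difference by its
reference value before averaging. Per-vial pairing averages the map over
each vial's refined pixels and drops vials without any (with a warning).
The imperfect-efficiency scenario used in tests sets the SR efficiency to
B = 1.05: the 3-parameter fit absorbs it (|bias| < 1 %) while the
2-parameter fit, with B pinned at 1, overestimates T1 by several percent —
an efficiency above ideal is what reproduces the positive 2-parameter bias
observed when SR maps are validated against reference relaxometry, whereas
B < 1 would bias the other way.

## I/O conventions

Times are milliseconds everywhere; sidecars declaring other units are
rejected, never converted. DICOM times resolve from the first standard tag
(Inversion Time, Echo Time, Trigger Time) present on every frame and
varying across frames, with per-file diagnostics when resolution fails;
private vendor headers are out of scope and a JSON sidecar always wins over
tags. Maps are written as float64 NIfTI (lossless round trip) plus a
provenance JSON carrying the model, fit variant and a settings digest;
16-bit PNG previews document their window and scale factor. ROI masks
round-trip as binary PNG or a run-length text format.

## Known limitations

- No rigid or non-rigid registration: frames must be co-registered.
- MOLLI accuracy effects rooted in Bloch-level physics are not modelled.
- The background gate is a heuristic on peak signal, not a tissue mask.
- The per-vial values of a physical gel set are nominal ranges here;
  absolute agreement with any particular physical phantom is not claimed.
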