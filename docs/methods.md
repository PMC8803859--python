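# Methods

This note records the scientific and numerical choices behind
`dropsense`: the model assumptions, the parameter conventions, what the
synthetic generator does and does not emulate, and the places where the
design was genuinely open.

## Units and constants

Canonical units are minutes, micrometres (electrode areas in mm²),
micromolar and nanoamperes. The Faraday constant is stored pre-converted
(`F_eff = 96485.332 C mol⁻¹ × 10⁻⁶/60 ≈ 1.608×10⁻³ nA·min·mm⁻²·µm⁻¹·µM⁻¹`)
so that slope expressions like `F·A·D/H` evaluate directly to nA/µM.
The current–flux relation is written without an explicit electron count,
although H₂O₂ oxidation transfers two electrons; the count is folded
into effective constants (notably the mass-transport coefficient m_h),
and `PhysicalConstants(n_electrons=2)` makes it explicit when wanted.
With hydrogel-range diffusivities and n = 1 the default sensor's
sensitivity is ~3.4 nA/mM; with n = 2 it is ~6.9 nA/mM, at the lower
edge of the 9 ± 2 nA/mM band typical of fresh sensors — consistent with
the published current-density conversion being ambiguous at the factor-2
level. We do not attempt to resolve that ambiguity.

## Model assumptions

* **First-order kinetics everywhere.** Both GOx conversion in the film
  and cellular uptake in the spheroid are linear in glucose. This is the
  starvation-regime (≤150 µM) approximation; Michaelis–Menten or
  zeroth-order uptake invalidates the closed forms and is out of scope.
* **Quasi-steady microscales.** Film and spheroid profiles are at
  steady state with respect to the slowly varying bulk; the bulk obeys
  lumped first-order ODEs.
* **Well-mixed, independent drops.** Cross-electrode and cross-drop
  diffusion are neglected (drops are processed independently); the
  conjugate-pair fit class is the diagnostic that flags when this
  neglect bites (see below).
* **Constant evaporation rate** within a measurement: V(t) = V₀ − V_t·t.
  The ODE test oracle accepts this form only; time-varying evaporation
  records are out of scope for the closed forms.

## Key parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| A | electrode area (0.4 mm disk) | 0.1257 | mm² |
| H | hydrogel thickness | 5 | µm |
| D_g | glucose diffusivity in hydrogel | 2800 | µm²/min |
| D_h | H₂O₂ diffusivity in hydrogel | 28000 | µm²/min |
| v_g | first-order GOx rate | 7.0 | min⁻¹ |
| D_S | glucose diffusivity in tissue | (required input) | µm²/min |
| V₀ | initial drop volume | 6.5 | µL |
| V_t | evaporation rate | 0.002 | µL/min |
| c*_g0 | initial bulk glucose | 150 | µM |
| m_h | H₂O₂ mass-transport coefficient | 400 | µm/min |

D_g and D_h are buffer values scaled by the hydrogel hindrance factors
(glucose 0.062–0.086×, H₂O₂ 0.25–0.40×); config accepts any value in
range. v_g = 7 min⁻¹ puts the default sensor at the B̃ ≈ 0.25 operating
point reported for this electrode design. m_h = 400 µm/min corresponds
to a diffusion layer of a few hundred µm in the unstirred drop and
reproduces the observed 0.2–0.5 nA responses at 2–7 µM bulk H₂O₂.

**D_S is deliberately a required, recorded input.** The experiments this
package models print fitted spheroid numbers but not the tissue
diffusivity used to obtain them, and the printed (diameter, S̃, rate)
triplets are not mutually consistent with any single D_S. Every fitted
S̃ scales through D_S, so the pipeline refuses to default it and writes
it into every report.

**Hydrogel-to-bulk rate scaling.** The microscale q_E of the biosensor
model is an average over the film volume A·H; the drop ODEs need the
rate at which the *drop's* glucose is consumed. `biosensor.bulk_rate`
applies the volume ratio A·H/V (~10⁻⁴), which lands calibration-derived
enzyme rates on the ~10⁻³ min⁻¹ scale that empty-drop decay rates
actually show. The chain in the model equations leaves this scaling
implicit; we make it explicit.

## The two-pseudoinverse exponential fit

Stage 1 solves the order-2 linear-prediction system
`y[k+2] = p·y[k+1] + q·y[k]` in least squares; the recurrence roots give
the rates. Stage 2 solves for the amplitudes on the exponential basis.
No starting guesses anywhere; complex-conjugate roots are legitimate
solutions and are reported as the `conjugate-pair` class with exact
conjugate symmetry enforced.

Numerical choices:

* **Stage 1 runs on a block-averaged grid (default 32 bins).** Bin means
  of a geometric sequence form a scaled geometric sequence with the
  *same* ratio, so binning leaves the rates exactly identified on
  noiseless data, while (i) averaging sensor noise ~10× per bin and
  (ii) moving the recurrence roots away from the ill-conditioned
  neighbourhood of z = 1 that 0.1 min sampling of ~10⁻² min⁻¹ decays
  produces. Naive least squares on the raw grid is useless under noise
  (errors-in-variables bias of linear prediction); 32 bins over a
  300 min trace keeps the bin width (~9 min) below the fastest decay
  time constants seen (~16 min) while averaging ~100 samples per bin.
  Faster decays than ~0.1 min⁻¹ warrant a larger `n_prediction`.
* **Amplitudes on the full grid**, so no binning bias enters a or c.
* **Rate labelling.** `b` is assigned the slower |Re| (and, for
  conjugate pairs, the root with Im ≤ 0), matching the published
  convention and the physical reading b = −q_e in the spheroid-drop
  regime. The sum of two exponentials is symmetric under exchanging its
  terms, so when total glucose consumption is *slower* than the
  electrode rate (possible in empty drops) the labels swap and per-drop
  data cannot disambiguate; consumers that need the physical q_e in that
  regime must bring cross-drop information (q_e is electrode-specific
  and approximately constant). Tests therefore validate the recovered
  (slow, fast) pair.
* **Degeneracies.** A rank-deficient prediction system or repeated root
  (separation < 10⁻⁸ relative) falls back to a single-exponential fit,
  reported as `degenerate-single` with a warning; a confluent
  a·e^{bt}(1+κt) form is intentionally not fitted.
* **Grids** must be uniform to 10⁻⁶ relative; anything worse raises a
  resample-required error rather than silently fitting.
* An optional Levenberg–Marquardt polish (`fit(polish=True)`) exists but
  is off by default to preserve the guess-free character.

The rate-degenerate manifold of the measurement model itself
(q_E + q_S = q_e, where the closed form's denominator vanishes) is
handled by the analytic limit `(c*_h0 + c*_g0 q_E t)e^{−q_e t}`,
switching within 10⁻⁹ min⁻¹ of the manifold.

Root finding for the two inversions (slope → B̃ and q_S → S̃) uses
bracketed Brent iteration on strictly monotone functions (`1 − sech B`
on [0, 10³]; `S coth S − 1` with a series branch below 10⁻² and a
bracket that grows with the right-hand side), to ~10⁻¹⁴ absolute.
Hyperbolic forms are evaluated via cancellation-free identities
(`1 − sech x = 2 sinh²(x/2)/cosh x`) and overflow-guarded exponentials.

## Synthetic data: what it emulates, what it does not

The generator replaces the unavailable instrument recordings with:

* metabolism traces sampled from the closed-form current at 0.1 min
  (decimated from the instrument's 5.56 Hz — rates of ≤0.07 min⁻¹ are
  vastly oversampled even at 0.1 min);
* additive white Gaussian current noise, default σ = 1 pA (the
  readout's stated noise floor); no 1/f or drift-within-trace component
  is modelled because none is characterized;
* 3-point calibration staircases (0/75/150 µM, 20 min steps) with
  first-order drop-exchange lag (τ = 2 min, consistent with the
  several-minute full-drop exchange of this fluidic network);
* multiplicative sensitivity drift across repeated measurements,
  default factor (3.1/9)^(1/9) per measurement so ten successive
  measurements span the observed 9 → 3.1 nA/mM decline;
* replays of the eight published coefficient rows (five
  conjugate-pair, three real-pair), used verbatim as fixtures;
* a zero-phase Blackman-window FIR low-pass mirroring the instrument's
  cleanup; super-Nyquist cutoff requests are refused (the instrument's
  printed cutoff exceeds its own decimated Nyquist rate — likely a unit
  slip — so the cutoff is always explicit config here).

Because generated traces come from the same closed forms the fitter
assumes, passing recovery tests demonstrates correctness of the
*inference machinery* under the stated noise, not robustness to model
misspecification. Real traces additionally contain cross-electrode
diffusion, H₂O₂ accumulation delays (the conjugate-pair class), slow
baseline drifts and GOx deactivation within a measurement; of these,
only the conjugate-pair structure is represented (via the replayed
rows).

## Problem sizes used in the test and acceptance runs

Traces of 300 min at 0.1 min (3001 samples); BVP oracles on 10⁴-node
meshes; quadrature oracles on 4×10⁴-point grids; the end-to-end recovery
study uses 100 seeded replicates of an 8-drop experiment (2 empty, 3
small-spheroid at 285–286 µm, 3 large at 452–453 µm), with rate scales
taken from the published coefficient table (q_e ≈ 6.6×10⁻³ min⁻¹, total
consumption ≈ 1.15×10⁻² min⁻¹ small / 6.2×10⁻² min⁻¹ large). These sizes
were chosen to be the experiment's own scales.

## Known limitations

* First-order kinetics only; no necrotic-core spatial variation of v_S.
* The bulk measurement model cannot produce complex rates, so
  conjugate-pair traces (H₂O₂ build-up/delay) are fitted and flagged but
  m_h and c*_h0 are not separable there (reported NaN with the |Im|
  delay diagnostic).
* Rate-label ambiguity when q_E + q_S < q_e (see above).
* Calibration-derived q_E assumes the film's D_g, H used in config match
  the deposited film; errors propagate linearly into q_S = −Re(d) − q_E
  (small in absolute terms since q_E is ~10× smaller than spheroid-drop
  totals).
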