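# Methods

## The model

Lock-in feedback treats a sequential experiment as a feedback circuit. One
scalar response `y` is observed once per trial `i` (one subject, one
rating); `K` continuous treatment variables are under the experimenter's
control. Each treatment dimension `k` is assigned a dither frequency
`ω_k` (radians per trial), an amplitude `δ_k`, a window length `n_k` and a
learn rate `γ_k`, and is presented at

```
x_{k,i} = x̃_{k,i} + δ_k cos(ω_k i),
```

clipped to the attribute bounds. The trial index is the time base: a
"period" is a number of subjects, not seconds. Writing the response as a
smooth unimodal function `f` plus zero-mean noise, a second-order expansion
around the center gives

```
y_i = k + δ f'(x̃) cos(ω i) + (δ²/4) f''(x̃) cos(2ω i) + ε_i ,
      k = f(x̃) + (δ²/4) f''(x̃).
```

Multiplying by `cos(ω i)` and summing over a window of `n` trials isolates
the first-harmonic line: for the quadratic surface used throughout,
`f(x) = A (x − x_max)² + y₀`,

```
y_lock = Σ y_i cos(ω i) = A δ n (x̃ − x_max) + leakage + Σ ε_i cos(ω i).
```

The leakage terms are oscillatory sums (`Σcos`, `Σcos·cos2ω`, …) that
vanish *exactly* when `ω n` is a whole number of periods and no low
harmonic aliases onto the window (`m, 2m, 3m ≢ 0 mod n` for
`ω = 2πm/n`), and stay `O(1)` — versus the `O(n)` signal — otherwise.
`suggest_window` finds whole-period windows; the shipped configuration
(`ω₁ = 2.63`, `n = 150` ≈ 62.8 periods) tolerates the residual leakage,
which for its frequency pair is audited by `analysis.crosstalk`
(normalized leakage 0.042, diagonal 0.996).

The demodulated sum is a gradient estimate, so the loop ascends with

```
x̃ := x̃ + γ y_lock        (maximize; −γ for minimize),
```

applied every trial from a sliding window once the first `n` responses have
accumulated (the warm-up, during which the center is pinned at its initial
value). Phase always uses the absolute trial index, so windows slide and
shocks land without phase discontinuities. Centers are clipped to
`[lo + δ, hi − δ]` so the full dither stays inside the attribute bounds.

Multiple dimensions run in parallel against the same response at separated
frequencies; each dimension's demodulation is near-orthogonal to the
others' dither lines (the cross-talk audit quantifies "near").

### Sign and baseline conventions

Two conventions exist in the field for the discrete update, and the package
implements both:

* **Sign.** For a concave response (`A < 0`), `y_lock` has the sign of
  `x_max − x̃`, so ascent requires `+γ y_lock`. That is the default
  (`raw_sign=False`); the opposite sign — which appears in some write-ups
  of the windowed update — is available as `raw_sign=True` and, on a
  concave surface, walks away from the optimum. Replay mode can discriminate
  the two empirically on a recorded stream.
* **Baseline.** The default update starts from the current center
  (`baseline="current"`), the classic ascent rule. The alternative starts
  from the mean of the centers over the demodulation window
  (`baseline="window_mean"`). With per-trial sliding updates the two differ
  sharply: the closed-loop contraction toward the optimum is `γ|A|δn` per
  trial for the current-center rule but only `≈ 2γ|A|δ·2/(n+1)` — a factor
  `(n+1)/2` slower — for the window-mean rule, because each step discards
  the progress accumulated inside the window. At the shipped parameters
  (`γ|A₁|δn ≈ 0.0072`) the current-center loop converges from 35 attribute
  units away in ≈500 trials, matching the behavior the method is meant to
  deliver, while the window-mean loop would need tens of thousands of
  trials; the window-mean variant is therefore exposed for sensitivity
  analysis, not as the default. Its compensating virtue — a ≈`n/2`-fold
  narrower noise bandwidth — is discussed under *Noise* below.

## Parameters and defaults

| parameter | default | units | role |
|---|---|---|---|
| ω₁, ω₂ | 2.63, 2.51 | rad/trial | dither frequencies, separated and incommensurate with common periodicities |
| δ | 8 | attribute units | dither amplitude: probe strength vs. stimulus distortion |
| γ | 6·10⁻⁴ | attr. units per lock-in unit | learn rate: convergence speed vs. noise amplification |
| n | 150 | trials | demodulation window and warm-up length |
| x̃₁ | 20 | attribute units | initial center (both dimensions) |
| bounds | [1, 100] | attribute units | attribute grid of the emulated stimulus |
| direction | maximize | — | ascent/descent switch |

These are the tuning values of the two-attribute sequential rating study
the simulator emulates, and they ship as the packaged default config
(`lifopt.io.DEFAULT_CONFIG`).

## The synthetic-data generator

`lifopt.simulate` emulates a sequential rating experiment: a quadratic
two-attribute surface

```
y = a₁(x₁−x₁ₘ)² + a₂(x₂−x₂ₘ)² + c·(x₁−x₁ₘ)(x₂−x₂ₘ) + y₀ + ε
```

with defaults `a₁ = −0.01`, `a₂ = −0.02`, optimum `(55, 60)`, `y₀ = 70`,
`c = 0` (the coupled variant used in the cross-term analyses sets
`c = −0.005`, which keeps `4a₁a₂ − c² > 0` and moves the conditional
optimum of `x₂` at `x₁ = 90` to `x₂ₘ − c(x₁−x₁ₘ)/(2a₂) = 55.625`). Rater
noise is Gaussian with sd 25 by default — chosen so that raw ratings span
most of the 1–100 slider at any stimulus, while a 150-trial running
average remains informative — and the rating is clipped to the slider
range *after* adding noise (a physical slider cannot report outside its
track). Clipping biases the mean near the boundaries, so unbiasedness
checks in the tests disable it. Noise draws are keyed by `(seed, trial)`
via a counter-based generator, so a single trial's draw is reproducible in
isolation and equal seeds give bit-identical trajectories.

Shock events overwrite exactly one dimension's center at exactly one trial
(the canonical schedule forces `x̃₁ = 90` at trial 3,637), probing the
loop's self-healing. An optional deterministic drift displaces the optimum
per trial (off by default); an optional integer rounding of responses
mimics a coarse slider (off by default).

What the generator does **not** emulate: real rating noise is neither
Gaussian nor homoscedastic (empirical rating streams show boundary pile-up
and strong rater heterogeneity), the true attractiveness surface is only
locally quadratic, and subjects arrive non-exchangeably (time-of-day,
cohort effects). Passing tests therefore demonstrate correctness of the
*algorithmic machinery* under the stated statistical model, not
field performance on human raters.

## Noise, and the accuracy floor of the trailing mean

Pure noise demodulates to `Σ ε_i cos(ω i)`, with mean 0 and variance
`σ² Σcos²(ω i) ≈ σ² n/2` — verified by Monte Carlo (10⁴ windows, 3
standard errors). Because consecutive sliding windows share `n − 1`
responses, the per-trial update noise is strongly autocorrelated; for the
current-center rule the center behaves near the optimum like an AR(1)
process with contraction `ρ = γ|A|δn` driven by noise of DC spectral
density `γ²σ²n²/2`, giving stationary variance `γσ²n/(4|A|δ)` and, for the
mean of `T` consecutive centers (`T` ≫ `1/ρ`),

```
sd(mean_T) ≈ σ / (√(2T) · |A| δ).
```

Both `γ` and `n` cancel: at `σ = 25`, `δ = 8`, `T = 500` this floor is
≈9.9 attribute units for `|A| = 0.01` and ≈4.9 for `|A| = 0.02`. The
trailing-mean localization accuracy is thus set by the curvature-to-noise
ratio `|A|δ/σ` alone, and no learn-rate or window choice can buy it back —
only a stronger dither, more curvature, less noise, or a longer averaging
span. The simulation study in the acceptance script measures exactly this:
with the default surface, the fraction of 20 seeded 3,600-trial runs whose
trailing-500 means land within ±5 of the optimum on both dimensions is
≈30–35%, consistent with the formula above.

## Numerical and design choices

* **Demodulation** is a plain cosine-weighted dot product over the ring
  buffer; no FFT, no phase-locked loop, no third-harmonic estimation.
* **Whole-period tests** require `m, 2m, 3m ≢ 0 (mod n)`: the cubic term
  of the demodulated quadratic contains `Σcos³(ω i)`, which survives when
  the *third* harmonic aliases to DC, not only the second.
* **Warm-up** is exactly `n` trials per dimension with the center pinned;
  the first update fires on the trial that completes the first full window
  and sets the center used on the next trial.
* **Degenerate settings are legal**: `δ = 0` (static design, no gradient
  signal — on whole-period windows the center is then exactly constant in
  the noiseless case), `γ = 0` (frozen controller, used by replay
  validation).
* **Sequencing is strict**: proposals and responses must alternate with
  consecutive trial indices; gaps, duplicates and non-finite responses
  raise typed errors rather than corrupting the window.
* **Replay** re-runs the identical controller code path over a recorded
  (trial, response) stream, so a replayed simulation reproduces its center
  trajectory bit-for-bit; recorded trial numbers (from any offset) drive
  the dither phase.
* **Trajectory CSVs** store floats with 9 significant digits — enough for
  convergence and recovery reports to survive a round trip at reporting
  precision (round-trips are not bit-exact; in-memory replay is).
* **Reports**: "converged" means trailing sd below tolerance and all
  trailing centers inside the tolerance band around the trailing mean;
  "recovered" means the center re-enters a ±tolerance band (default 5
  attribute units, ±2 in the deterministic shock analyses) around the
  pre-shock trailing mean and stays for a sustain period (default: one
  window). A shock on the final trial is reported unrecovered.
* **Quantization** of proposals to the integer stimulus grid is available
  but off by default; whether deployed systems round is
  implementation-specific, and rounding is irrelevant to the controller
  mathematics.

## Problem sizes

The shipped analyses use 3,600-trial runs (20 seeds) for the noisy
simulation study, a 5,200-trial noiseless run for shock recovery, 10⁴
Monte-Carlo windows for noise rejection, and a 378-combination sweep for
the closed-form identity; together they complete in well under a minute on
one CPU.

## Known limitations

* Behavior on multimodal or non-smooth response surfaces is undefined; the
  controller assumes a single interior extremum within the bounds.
* The quadratic surface is global in the simulator but only local in any
  real experiment; far from the optimum the gradient estimate of a real
  surface need not point home.
* Response clipping at the slider bounds biases the demodulated gradient
  when the noise band hits a rail; the simulator reproduces this bias
  deliberately.
* Cross-talk between dimensions is small but nonzero for non-whole-period
  windows; strongly coupled surfaces (cross term near the
  positive-definiteness limit) slow joint convergence.
* The AR(1) noise analysis above is a small-fluctuation approximation; it
  breaks down when the center random-walks far enough to feel the bounds
  or the clip rail.
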