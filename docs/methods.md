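# Methods

## The model

The package implements a dynamical priority-map model of saccade-target
selection during scene viewing, in two variants.

**Baseline variant.** Two activation streams evolve on an `n_x × n_y` grid
(default 128 × 128) laid over the image, with coordinates in degrees of
visual angle. The *attention* stream `A` relaxes toward the Gaussian-windowed
local saliency around the current fixation `(x_f, y_f)`:

    dA/dt = ω_A (S·G_A / Σ S·G_A − A),     G_A = N((x_f, y_f), σ_A²)

and the *inhibition* stream `F` relaxes toward a Gaussian blob at the
fixation (inhibitory tagging of visited locations):

    dF/dt = ω_F (G_F / Σ G_F − F),         G_F = N((x_f, y_f), σ_F²)

Both are integrated exactly with the closed form
`M(t) = target + e^{−ω t} (M₀ − target)` over every phase with a constant
target; no numerical ODE stepping is used in production code (a Runge–Kutta
integrator exists only as a test oracle). The streams combine subtractively
after shaping,

    u = A^γ / Σ A^γ − C_F · F^γ / Σ F^γ,

are rectified at zero, and mixed with uniform selection noise
ζ ∈ (0, 1]:

    π = (1 − ζ) u⁺ / Σ u⁺ + ζ / (n_x n_y).

`π` is the probability map over next saccade targets. With γ = 1 and
C_F = 0, selection reduces to Luce's choice rule on the attention map.

**Extended variant.** Four perisaccadic mechanisms are added:

1. *Phase schedule.* Each fixation of duration `t_fix` splits into a
   post-saccadic phase `(0, τ_post)` with attention centered at a *remap*
   point, a main phase, and a pre-saccadic phase `(t_fix − τ_pre, t_fix)`
   with attention centered at the already-selected next target. The target
   is selected from `π` at `t_fix − τ_pre`. Inhibition stays centered on
   the current fixation throughout.
2. *Post-saccadic remap.* The remap point extends the previous saccade
   vector by η degrees beyond the landing point; the post-phase attention
   Gaussian has width σ_post.
3. *Facilitation of return.* Inside a square window of half-size ν around
   the previous fixation, attention decays at the slow rate ω_FoR instead
   of ω_A, so activation there lingers and return saccades are favored.
   The window changes only the approach rate, never the fixed point.
4. *Center bias and oculomotor potential.* The first fixation starts from
   a central Gaussian activation (widths σ_CB_x, σ_CB_y) that decays at
   ω_CB toward the ordinary local-saliency input; and a plus-shaped map
   `OMP = ((x−x_f)² (y−y_f)²)^χ` is combined with `u` before rectification,
   expressing the oculomotor preference for cardinal-direction saccades.

## Parameters

Estimated (both variants): ω_A (1/s), σ_A, σ_F (deg), γ, log ζ. Extended
adds χ, η (deg), log ψ. ζ and ψ are carried on the log scale and applied on
the natural scale. Fixed values and couplings: ω_F = ω_FoR = ω_A/10 (slow
inhibition and facilitation enable long-range inhibition of return),
C_F = 0.3, σ_CB = 4.3°, ω_CB = 1.5 1/s, ν = 2° (about the fovea),
τ_pre = 0.1 s, τ_post = 0.05 s. σ_post defaults to σ_A (it is nominally
free but no reference value is fixed here); it is overridable in the
parameter config. Simulation defaults for the estimated parameters are
subject-average reference estimates: baseline ω_A = 14.802, σ_A = 7.482,
σ_F = 4.629, γ = 0.935, log ζ = −1.132; extended ω_A = 9.996, σ_A = 7.320,
σ_F = 6.834, γ = 0.956, log ζ = −1.727, χ = 0.059, η = 0.415,
log ψ = −0.613.

## Conventions and numerical choices

- Maps live on cell centers; all normalizations are plain discrete sums
  over grid cells, so border-near Gaussians are implicitly truncated and
  renormalized. Positions outside the extent clamp to border cells only
  when converting to cell indices; Gaussian centers themselves (e.g., a
  remap point beyond the image edge) are never clamped.
- `γ`-shaping clips tiny negative round-off at zero before exponentiation;
  `0^0` in the oculomotor map at χ = 0 is defined as 0, preserving the
  plus shape continuously in χ.
- The sign of the oculomotor term is a genuine ambiguity: the additive
  absolute-value form rewards *off*-cardinal cells, which contradicts its
  stated purpose. The default therefore subtracts the normalized map
  (`u − ψ·OMP/ΣOMP`), leaving the cardinal cross untouched; the verbatim
  additive form is available via `omp_sign="literal"`.
- Short fixations (`t_fix < τ_pre + τ_post`): the pre-saccadic phase keeps
  priority (selection must occur), the post-saccadic phase is truncated to
  `max(0, t_fix − τ_pre)`, the main phase to the remainder.
- First fixation: no post-saccadic phase and no facilitation window (no
  previous saccade exists). Under center-bias initialization, A starts as
  the normalized central Gaussian and relaxes at ω_CB during the main
  phase; the pre-saccadic shift phase uses the ordinary rate ω_A.
  Inhibition starts at zero under center bias and uniform otherwise.
  The probability of the first fixation is read from the initial
  activation map with selection noise applied — uniform for the baseline
  variant, hence exactly log₂(1/128²) = −14 bits on the default grid.
- Zero-length "saccades" (identical consecutive positions) define no
  direction: the post-saccadic remap is skipped for that fixation, and
  turning angles involving them are flagged undefined, not zeroed.
- The facilitation window is square (coordinate-wise inequalities), side
  2ν, applied only for the immediately preceding fixation.

## Likelihood and inference

The scan-path likelihood factorizes per fixation; each conditional
probability is read off `π` at the selection instant of the preceding
fixation, with observed fixations driving the dynamics (teacher forcing).
Probabilities are reported in log₂ (bits). Model comparison uses the mean
bits per fixation; estimation uses the non-normalized sum. ζ > 0 bounds
every per-fixation term below by log₂(ζ/(n_x n_y)).

Inference is per subject: bounded-uniform priors (ω_A ∈ (0.1, 60), σ_A,
σ_F ∈ (0.5, 15), γ ∈ (0.1, 3), log ζ ∈ (−6, 0), χ ∈ (0, 0.5), η ∈ (0, 3),
log ψ ∈ (−4, 1)), sampled with a differential-evolution MCMC of the DREAM
family: a few chains propose jumps from difference vectors of a growing
archive of past states, with DREAM-style subspace crossover, occasional
γ = 1 mode-jump steps, and 10% snooker updates. Chains start at the best
of a prior-sample pool (overdispersed but informed). The first 50% of
iterations are discarded as burn-in. Convergence is reported via the
Gelman–Rubin statistic for every parameter and surfaced to the caller,
never hidden. Point estimates are the midpoints of 50% highest-posterior-
density intervals, with the interval bounds as the credibility interval.

## Synthetic data

The generator produces mixture-of-Gaussian-blob saliency maps with a
uniform floor, ground-truth scan paths simulated from either variant
(per-subject log-normal parameter jitter, 15% by default), and raw gaze
traces at 500 Hz in which fixations hold position with 0.05° jitter and
saccades follow a raised-cosine position profile over 40 ms. Fixation
durations are gamma distributed (shape 9, scale 0.0305 s: mean ≈ 275 ms,
CV ≈ 1/3, typical of free scene viewing). The saccade detector applies an
elliptic velocity threshold of λ = 6 median-based standard deviations
(1.4826 × MAD per component) on 5-point smoothed velocities, requires at
least 6 consecutive samples (12 ms at 500 Hz), and discards candidates
below the 0.5° amplitude floor.

What the generator does *not* emulate: image-content statistics of real
scenes (objects, photographer bias), measurement artifacts (blinks,
drift, calibration error), duration dependence on local content, and
binocular disparities. Passing tests therefore demonstrate internal
consistency of model, likelihood and inference — not empirical adequacy
on real corpora.

## Study scales

The validation studies are sized for a single-CPU desk run: qualitative
gaze-statistics comparisons use a 64 × 64 grid with about 20 simulated
subjects and 15–30 paths × 30 fixations each; parameter-recovery fits use
a 32 × 32 grid, 20 paths × 40 fixations per replicate, and 3 chains ×
2000 DE-MC iterations, five replicates. These sizes are the package's own
defaults for its validation suite; the model itself defaults to the full
128 × 128 grid. Likelihood replay runs through a compiled (numba) kernel
that the test suite pins to the reference implementation at 1e-10.

A caution on desk-scale recovery: at ~800 fixations the joint posterior
of the extended model has a pronounced ridge coupling γ, ψ and σ_F (with
χ piling at its lower bound), and the marginal credible interval for γ
often sits above the generating value even for well-converged chains —
maximum-likelihood fits started at the truth do recover it, and the bias
vanishes with more data. Recovery checks on γ at this scale test the
geometry of the posterior as much as the implementation.

## Known limitations

- With the reference parameter values and the default σ_post = σ_A
  (≈ 7.3°), the post-saccadic remap displaces a very broad attention
  Gaussian by only η ≈ 0.4° — a sub-percent perturbation of the map.
  Simulations at these values therefore show a strong return-saccade
  structure (the saccade-relative joint density concentrates ~9× the
  window average at (−1, 0)) but no detectable *forward* coupling: no
  local 0° turning-angle mode beyond the baseline's, no mass
  concentration at (1, 0), and no shortening of fixations preceding
  forward saccades. A compact post-saccadic trace (σ_post on the foveal
  scale, ~1°) strengthens these signatures; σ_post is overridable in the
  parameter config, but the package keeps σ_A as the declared default and
  reports the forward-coupling checks as failing rather than calibrating
  σ_post against them.
- The DE-MC sampler at desk scale leaves Monte-Carlo error in credible
  intervals; Gelman–Rubin values near 1.1 should be treated as marginal
  and longer runs used for production fits.
- Likelihood evaluation assumes fixation positions are measured in the
  same degree coordinates as the saliency map; no pixel-space handling is
  provided.
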