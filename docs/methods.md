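# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and the known limits of what desk-scale runs
can show.

## Model overview

The framework nests two loops. The outer loop is an evolution strategy over
a genotype that directly encodes phenotypic traits of a visual system; the
inner loop trains a policy network by reinforcement learning for each
candidate and scores it on one of three visual tasks. Selection acts on the
post-learning score, so lineages that *learn* better are favored — a
computational analogue of lifetime adaptation biasing inheritance.

## Genotype

| field | range | notes |
|---|---|---|
| num_eyes | 1–16 (int) | eyes on the body equator |
| placement_range_deg | (0, 180] | span of the uniform, bilaterally symmetric layout |
| fov_deg | [1, 100] | per-eye field of view |
| res_w, res_h | 1–16 (int) | photoreceptor grid per eye |
| phase_mask | 4×4 in [0, 1] | diffractive height-fraction map |
| refractive_index η | [1, 2] | thin-element index |
| aperture_fraction a | [0, 1] | pupil radius r = a·L |
| hidden_neurons | 1–512 (int) | both trunk layers |
| memory_frames | 0–16 (int) | temporal stack depth (0 treated as 1) |

The body is a sphere of fixed radius 0.2 world units. Placement is an
inclusive uniform grid over [−range/2, +range/2]; a single eye looks dead
ahead. This reproduces both canonical worked layouts (3 eyes/90° →
±45°, 0°; 3 eyes/20° → ±10°, 0°).

**Overlap constraint.** Adjacent eyes must be at least one *eye footprint*
apart, where footprint = 2·asin(min(1, L/(2R)))·180/π for sensor side L and
body radius R — the angular chord one sensor occupies on the equator. The
constraint is stated qualitatively in the literature this model follows;
the chord formula is this package's concrete choice.

**Mutation.** Continuous fields: Gaussian perturbation with σ = 10% of the
field's range, clamped at the bounds (clamping, not rejection, keeps the
operator total). Integers: one ±1 step with equal probability. With the
width-only resolution axis (used for the essentially two-dimensional
navigation task) only res_w mutates; otherwise both axes step together
(square growth). Invalid intermediate states are repaired by clamping and,
for overlap, shedding eyes — repair rather than penalty keeps the fitness
landscape smooth for the optimizer.

**Codec.** Masked-in fields are normalized to [0,1] and concatenated;
integers travel as continuous values and are rounded at decode. The
optics-only mask yields an 18-vector (16 phase + η + a).

## Imaging model

The pupil plane is sampled on a 51×51 grid spanning 2L per side (the fully
open pupil, radius a·L at a = 1, inscribes exactly). The 4×4 phase gene is
bilinearly upsampled onto this grid and mapped to an optical delay
(2π/λ)(η−1)·h_max·φ with h_max = 1.5 µm — the standard thin-element phase
of a height map, which couples the refractive-index gene to the mask (a
formulation that omits η would make that gene inert). Wavelengths default
to 640/550/460 nm for R/G/B.

A point source at distance z contributes a spherical wave
exp(ik√(x²+y²+z²)); the post-pupil field, zero-padded 4×, is propagated a
focal distance s by the exact angular-spectrum transfer function
exp(iks√(1−(λf_x)²−(λf_y)²)) with evanescent components suppressed. The
squared magnitude is binned into (res+1, res+1) sensor-pitch cells and
normalized to unit sum. The PSF is computed once per genotype at the
reference source distance (depth independence: one convolution per eye per
step); the latent depth map is carried but unused by the convolution.

Geometry defaults: L = s = 0.05 world units, z = 3 (typical object
distance), sensor noise σ = 0.02 of full scale. At this macroscopic scale
the model is dominated by geometric blur — a fully open pupil smears the
scene across the whole kernel, a pinhole approaches a delta — which is
exactly the regime the aperture-evolution experiments need. Wave phenomena
(Airy rings, lens focusing) are validated in a separate diffraction-regime
configuration (L = 0.2 mm, s = 30 mm, plane-wave source, 4× finer grid,
12× padding) where the 51-sample pupil resolves the physics; the same code
path serves both. The Airy oracle compares against the effective radius of
the discretely sampled pupil (√(area/π)), since a circle a few samples wide
has a quantized radius.

Image formation: valid-mode convolution of the padded latent with the
unit-sum kernel, center-cropped to (res_h, res_w), scaled by the a²
relative throughput, identity sensor response, additive Gaussian noise,
clipped to [0,1]. Latent padding per side is ⌈(res+1)/2⌉, so a 15×15 eye
consumes a 31×31 latent. a = 0 is a *blind eye* (zero image + noise), not
an error — evolution is free to visit it.

**Metrics.** MTF: radially averaged FFT magnitude of the kernel on a
Nyquist-normalized axis, DC anchored at 1. Image quality: channel-mean MTF
area × a², so a sharp fully open eye scores 1. Acuity: the Nyquist
sampling limit res_w/(2·FOV) in cycles per degree; the agent-level value is
the per-eye maximum (all eyes share one morphology). The exact agent-level
acuity definition used in the source experiments is not published in full;
the Nyquist form is this package's documented stand-in.

## World

The world is top-down 2D: navigation corridors are effectively planar and
the object patterns are azimuthal stripes, so a 2D raycaster reproduces
the discriminative structure of the tasks at a fraction of the cost of a
3D engine. The renderer is a contract (anything producing a padded latent
per eye), so a 3D rasterizer could substitute without touching optics or
learning.

- Navigation: a randomized 5×5 perfect maze (DFS), corridor width 1.0,
  wall stripes drawn from {2, 4, 8} cycles per wall.
- Detection/Tracking: a 10×10 walled arena with one goal and two
  adversary spheres (radius 0.3), identical except that the goal's
  8-stripe azimuthal pattern is rotated 22.5°. Tracking objects move at
  0.3 units/s with headings resampled every 50 steps.
- Agent: point mass, actions (Δheading ∈ [−0.3, 0.3] rad, speed ∈ [0, 1]
  units/s), dt = 0.1 s, 500-step episodes by default. Wall penetration is
  resolved by projection (contact flag set); captures fire at the sum of
  radii. Arena dimensions, action bounds, and episode lengths are not
  dictated by the source experiments and are config-exposed defaults.
- Each eye casts one ray per latent column over FOV·(padded/native width)
  — the padded margin sees slightly beyond the nominal FOV, as a wide-open
  pupil physically would — and the scanline is extruded to all rows.

## Rewards and fitness

Navigation rewards moving away from the start: λ(‖x_t−x₀‖−‖x_{t−1}−x₀‖)
plus event terms. Detection/tracking reward *approach*:
λ(‖x_{t−1}−x_f‖−‖x_t−x_f‖). As printed in the source, the detection
distance term has the opposite sign, which would reward fleeing the goal
and contradicts the stated intent ("navigate to the goal as quickly as it
can"); this package follows the intent and negates the term. The contact
penalty applies per step while contact persists (contact is a per-step
observation). Training episodes terminate on first capture; fitness
evaluation (λ=1.5, w_g=10, w_a=−10, w_c=−2) respawns captured objects and
averages total reward over exactly six episodes.

## Learning

Observations composite per-eye retinal images into a
(depth, eyes, res_h, res_w, 3) tensor. Stack depth equals memory_frames
(the canonical worked example — buffer size 10 → leading dimension 10 —
decides an ambiguity in the prose, which elsewhere implies depth =
memory + 1); at episode start the buffer repeats the first frame rather
than zero-padding, which would alias darkness. A contact boolean and the
previous action are appended — auxiliary signals that markedly speed
convergence.

The policy gives each eye its own extractor (one hidden layer of 16 tanh
units — "small" per-eye processing with a concrete width chosen here) over
its flattened stacked pixels; concatenated features feed a trunk of two
hidden layers of hidden_neurons each, then a 2-output action head.
Pre-squash actions are Gaussian with learned log-σ; tanh squashing maps
them into the actuator bounds (the squash correction to the log-density is
omitted — actions stay well inside the linear region at these scales).
The parameter count N counts the behavior policy (extractors, trunk, head,
log-σ); the critic is PPO scaffolding and excluded.

PPO is implemented in numpy with hand-rolled backpropagation: clipped
surrogate (clip 0.2), GAE (γ=0.99, λ=0.95), Adam (3e-4), 10 epochs of
64-sample minibatches per 1024-step rollout, gradient-norm clip 0.5 —
standard defaults of widely used implementations. Evaluation every 10k
steps (3 episodes, deterministic actions); training stops early after 5
evaluations without ≥1e-3 improvement on the best, and the best-evaluation
parameters are returned. The step cap is 1M; desk-scale runs and tests use
2k–20k. Everything is seeded from
seed_RL = num_envs·(generation·population_size + rank) + agent_id and runs
single-threaded, so results are bit-reproducible.

## Evolution

CMA-ES (standard rank-one + rank-µ updates with cumulative step-size
adaptation, implemented in-package) operates on the unit-cube codec vector
with initial σ = 0.15. Candidates are clipped to the box, decoded, and
repaired. The fitness passed to the optimizer is the negated mean episode
reward (the optimizer minimizes). Elitism injects the previous best vector
into each generation's evaluation set (re-evaluated under a fresh seed; it
competes for best-so-far but is not fed back to the optimizer, whose batch
stays at population size). How the source experiments fed the
mixed-integer genotype to CMA-ES is not stated; rounding at decode is the
choice here, with native mixed-integer handling as the obvious
alternative. A surrogate-fitness mode (any function of the vector, no
reinforcement learning) is first-class and is how the outer loop is
validated: on a 5-dimensional quadratic bowl, 30 generations of population
16 reach the optimum to ~1e-4. The archive (config, per-generation JSONL
records, best genotype, optimizer state) checkpoints after every
generation and supports exact resume. The standard replicate protocol uses
CMA-ES seeds {0, 42, 420, 1337, 4002}.

## Scaling analysis

Task error is L = (F_max − F)/F_max, with F_max the six-episode fitness of
a scripted privileged oracle (greedy one-step lookahead on the true
geometry) on the same task configuration — the source experiments never
define L operationally, so this normalization is config-exposed. The
acuity grid is realized by res_w at fixed FOV 45° (res_h = 1, perfect-lens
imaging, isolating sampling from blur); unrealizable acuities snap to the
nearest integer resolution and record the request. Power laws are fit by
least squares on log L vs log N; bootstrap intervals are percentile
bootstraps (B = 2000) over replicates.

## What the tests do and do not show

The synthetic tasks reproduce the *structure* of the study conditions —
striped mazes, pattern-discriminable spheres, aperture-limited imaging —
at sizes a single CPU can train in seconds to minutes (episodes of 50–100
steps, budgets of 2k–20k PPO steps, populations of 6–16 for embodied
runs). At these budgets the learning smoke test and the directional
scaling probes are meaningful (reward improves; records are exact and
reproducible), but the evolved morphologies (e.g., seven-eyelet layouts,
15×15 camera eyes), the full lens-emergence trajectory, and the published
scaling exponents (0.69/0.74/0.59) required cluster-scale training and are
explicitly not reproduction targets. Directional claims at small budgets
are noisy and are reported, not gated. The 2D world omits 3D rigid-body
dynamics, vertical parallax, and occlusion-rich geometry; optics omit
depth-dependent blur, chromatic aberration beyond per-channel wavelengths,
and polarization/spectral sampling.

## Numerical notes

- PSF kernels are unit-sum to 1e-9; a² carries all throughput (blur shape
  and brightness are deliberately separated).
- The FFT propagation is validated against a direct O(N⁴) DFT summation
  (relative error < 1e-6 on 8×8 grids).
- Degenerate inputs: a = 0 → blind PSF stack; single eye → placement [0];
  memory 0 → stack depth 1; budget 0 → baseline evaluation only; single
  replicate → degenerate (zero-width, flagged) bootstrap interval.
- Ties in the greedy oracle resolve to the smallest turn scanned first;
  integer codec rounding is round-half-even (numpy).
- Bootstrap coverage is slightly anti-conservative at few replicates
  (~89% at 8 replicates for a nominal 95%); it reaches nominal coverage
  by ~50 replicates.
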