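# eyevo

Co-evolution of eyes and behavior in embodied agents: a desk-scale
framework for asking *what-if* questions about vision evolution. Agents
carry a heritable visual system — eye morphology, physically based optics,
and neural capacity — and must *learn* their behavior from scratch each
generation. An outer evolutionary loop (CMA-ES) selects and mutates the
genotype; an inner reinforcement-learning loop (PPO) scores it on a visual
task. The package is aimed at researchers in computational vision science
and evolutionary robotics who want to isolate how task demands, optical
physics, and neural scaling shape sensory design.

## The model

**Genotype.** Three independently mutable gene clusters:

- *morphological*: eye count `E`, placement range (eyes sit uniformly on
  the body's equator, bilaterally symmetric about the heading — three eyes
  over 90° sit at −45°, 0°, +45°), per-eye field of view (1–100°), and
  photoreceptor resolution;
- *optical*: a 4×4 programmable phase mask φ(x,y) ∈ [0,1] (a diffractive
  surface, upsampled to 51×51), refractive index η ∈ [1, 2], and aperture
  fraction a ∈ [0, 1] with pupil radius r = a·L for sensor size L;
- *neural*: hidden width of the two-layer policy trunk (1–512) and
  temporal memory depth (stacked past frames).

**Imaging.** The pupil function P = A·exp(i·(2π/λ)(η−1)·h·φ) is propagated
to the sensor by the angular-spectrum method for a point source at distance
z, giving a depth-independent per-channel PSF `H` of size (res+1, res+1),
normalized to unit sum. Image formation is one convolution per eye per
channel:

    I = clip( (H ∗ X) · a² + N(0, σ²), 0, 1 )

where `X` is the sharp padded latent scene (raycast from a 2D world) and
the a² factor is the quadratic light-throughput cost of a small pupil —
the physical trade-off that drives lens evolution.

**Learning and selection.** Per-step rewards pair distance shaping with
event terms (weights λ=0.25, w_g=1, w_a=−1, w_c=−1 during training;
λ=1.5, w_g=10, w_a=−10, w_c=−2 during fitness evaluation). Fitness is the
mean total reward over six evaluation episodes, with captured objects
respawned. Each agent trains under the deterministic seed

    seed_RL = num_envs · (generation · population_size + rank) + agent_id

CMA-ES (population 16, elitist re-evaluation, duplicates permitted)
optimizes the masked genotype vector on the unit cube.

**Analysis.** Acuity is summarized as cycles per degree (res_w / 2·FOV),
optics as a radially averaged MTF and an image-quality score
(MTF area × a²), and scaling experiments fit power laws L = a·Nᵇ to task
error vs. policy parameter count, with bootstrap confidence intervals
across replicate runs.

## Worked example

```
python examples/train_detection_smoke.py
```

trains the ancestral agent (one eye, one photoreceptor, 45° FOV) on a
detection arena with the goal dead ahead, and prints:

```
policy parameters: 316
evaluation history (env steps, mean episode reward):
       0  -0.019
    5120  +1.634
   10240  +1.635
   15360  +1.626
   20000  +1.626
stopped early: False
```

The untrained policy wanders (reward ≈ 0); within ~5000 steps the agent
learns to drive toward the goal, and the mean evaluation reward settles
around +1.6 — approach shaping plus a capture bonus per episode. The other
scripts in `examples/` each demonstrate one capability: placement and
mutation, PSF/image-quality trade-offs, retinal rendering, the reward
ledger, surrogate and embodied evolution, and the scaling sweep.

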