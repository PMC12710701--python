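"""Evolution: the outer CMA-ES loop, surrogate-checked and then embodied.

First, a surrogate-fitness run (a quadratic bowl on the genotype vector,
no reinforcement learning) demonstrates the optimizer machinery converging
in seconds. Then a small embodied run evolves only the pupil aperture on
the detection task — the experiment in which, without a lens, evolution
shrinks the pupil toward a pinhole to sharpen the image. Scaled far down
(small population, few generations, short training) this takes a couple of
minutes; expect the trend, not the converged pinhole.
"""

import numpy as np

from eyevo.evolution import EvolutionConfig, run_evolution
from eyevo.genome import MutationMask, primitive_genotype
from eyevo.learning import PPOConfig
from eyevo.world import TaskSpec

# --- surrogate mode: exercise the optimizer alone ------------------------
mask = MutationMask(allow_placement=True, allow_fov=True,
                    allow_aperture=True, allow_refractive_index=True,
                    allow_neurons=True)
target = np.array([0.3, 0.7, 0.5, 0.2, 0.8])
cfg = EvolutionConfig(
    mask=mask, generations=30, cma_seed=0,
    surrogate_fitness=lambda v: -float(np.sum((np.asarray(v) - target) ** 2)))
state = run_evolution(cfg)
print(f"surrogate bowl: best fitness {state.best_fitness:.2e} "
      "(0 is the optimum) after 30 generations")

# --- embodied mode: aperture-only evolution on detection ------------------
g = primitive_genotype()
g.morph.res_w = g.morph.res_h = 5
g.neural.hidden_neurons = 8
g.optics.aperture_fraction = 1.0  # start fully open

cfg = EvolutionConfig(
    task=TaskSpec.detection(spawn_mode="dead_ahead", episode_steps=60),
    mask=MutationMask.aperture_only(),
    initial_genotype=g,
    population_size=6, generations=3, cma_seed=0, train_budget=2048,
    ppo=PPOConfig(n_steps=256, eval_interval=1024, eval_episodes=1))
state = run_evolution(cfg)
for rec in state.records:
    apertures = [gd["optics"]["aperture_fraction"] for gd in rec.genotypes]
    print(f"generation {rec.generation}: best-so-far fitness "
          f"{rec.best_fitness:+.2f}, aperture range "
          f"[{min(apertures):.2f}, {max(apertures):.2f}]")
print("best aperture found:",
      round(state.best_genotype.optics.aperture_fraction, 3))
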