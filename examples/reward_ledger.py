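"""Rewards: the per-step ledger of a scripted episode.

A straight-to-goal policy runs on the dead-ahead detection arena under the
fitness weights (lambda = 1.5, w_g = 10, w_a = -10, w_c = -2). Every step
earns a distance-shaping term proportional to the approach speed, and the
capture step adds the goal bonus; in evaluation mode the goal respawns and
the episode continues.
"""

import numpy as np

from eyevo.analysis import oracle_policy
from eyevo.rewards import RewardWeights, evaluate_fitness, rollout_episode
from eyevo.world import TaskSpec

spec = TaskSpec.detection(spawn_mode="dead_ahead", episode_steps=26)
straight = lambda state, scene: np.array([0.0, 1.0])  # full speed ahead

ledger = []
total = rollout_episode(straight, spec, np.random.default_rng(0),
                        RewardWeights.fitness(), evaluation=True,
                        ledger=ledger)
captures = sum(e["goal"] for e in ledger)
print(f"episode reward {total:.2f} over {len(ledger)} steps, "
      f"{captures} goal capture(s)")
print("ledger around the capture:")
for entry in ledger[:2] + ledger[23:26]:
    print("  ", {k: (round(v, 3) if isinstance(v, float) else v)
                 for k, v in entry.items()})
# 25 approach steps at 1.5 * 0.1 units each, then +10 on the capture step:
# the distance shaping and the event bonus are separable by eye.

spec_long = TaskSpec.detection(episode_steps=100)
fitness = evaluate_fitness(oracle_policy(spec_long), spec_long,
                           np.random.default_rng(0))
print(f"\nsix-episode fitness of the privileged oracle on random arenas: "
      f"{fitness:.2f}")
# Fitness is the mean total episode reward over exactly six evaluation
# episodes — the quantity the outer evolutionary loop selects on, and the
# reference F_max of the scaling analysis' task error.
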