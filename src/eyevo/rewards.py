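"""Per-step reward functions, termination semantics, and fitness evaluation.

Each task pairs a distance-shaping term with sparse event terms:

* NAVIGATION:   R = lambda * (||x_t - x_0|| - ||x_{t-1} - x_0||) + w_g + w_c
  (move away from the start as fast as possible; w_c fires on wall contact)
* DETECTION / TRACKING:
                R = lambda * (||x_{t-1} - x_f|| - ||x_t - x_f||) + w_g + w_a + w_c
  (approach the goal x_f; w_g on goal capture, w_a on adversary capture).
  Note the sign: the distance term rewards *approach*. The event weights are
  zero except on the step their condition fires.

Training uses (lambda, w_g, w_a, w_c) = (0.25, 1, -1, -1) and terminates the
episode on the first capture. Fitness evaluation uses (1.5, 10, -10, -2),
respawns captured objects instead of terminating, and averages total episode
reward over exactly six episodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import (Task, TaskSpec, Scene, StepEvents, build_task_scene,
                    spawn_agent, step_dynamics, step_objects, respawn_object)

__all__ = [
    "RewardWeights",
    "StepContext",
    "step_reward",
    "rollout_episode",
    "evaluate_fitness",
    "N_FITNESS_EPISODES",
]

N_FITNESS_EPISODES = 6


@dataclass(frozen=True)
class RewardWeights:
    lambda_scale: float
    w_goal: float
    w_adversary: float
    w_contact: float

    @classmethod
    def training(cls) -> "RewardWeights":
        return cls(0.25, 1.0, -1.0, -1.0)

    @classmethod
    def fitness(cls) -> "RewardWeights":
        return cls(1.5, 10.0, -10.0, -2.0)


@dataclass
class StepContext:
    """Positions and event flags needed to score one step."""

    x_t: np.ndarray
    x_prev: np.ndarray
    x_start: np.ndarray
    x_goal: np.ndarray | None = None
    goal_captured: bool = False
    adversary_captured: bool = False
    contact: bool = False


def step_reward(task: Task, ctx: StepContext, w: RewardWeights) -> float:
    """Scalar reward for one step of the given task."""
    task = Task(task)
    if task is Task.NAVIGATION:
        dist = np.linalg.norm(ctx.x_t - ctx.x_start) \
            - np.linalg.norm(ctx.x_prev - ctx.x_start)
    else:
        if ctx.x_goal is None:
            raise ValueError(f"{task.value} requires a goal position")
        dist = np.linalg.norm(ctx.x_prev - ctx.x_goal) \
            - np.linalg.norm(ctx.x_t - ctx.x_goal)
    r = w.lambda_scale * float(dist)
    if ctx.goal_captured:
        r += w.w_goal
    if ctx.adversary_captured:
        r += w.w_adversary
    if ctx.contact:
        r += w.w_contact
    return r


def _context(task: Task, prev_pos, state, scene: Scene, ev: StepEvents
             ) -> StepContext:
    goal = None
    if task is not Task.NAVIGATION:
        goals = [o for o in scene.objects if o.kind.value == "goal"]
        goal = goals[0].position if goals else None
    return StepContext(
        x_t=state.position, x_prev=prev_pos, x_start=scene.start,
        x_goal=goal, goal_captured=ev.goal_captured,
        adversary_captured=ev.adversary_captured, contact=ev.contact)


def rollout_episode(policy, spec: TaskSpec, rng: np.random.Generator,
                    weights: RewardWeights | None = None,
                    evaluation: bool = False, scene: Scene | None = None,
                    ledger: list | None = None) -> float:
    """Run one episode and return total reward.

    ``policy`` is any callable mapping (state, scene) -> action, with an
    optional ``reset()`` hook invoked at episode start (observation-driven
    agents use it to clear their memory buffer; see learning.VisionAgent).
    In training mode the episode ends on the first capture; in evaluation
    mode captured objects respawn and the episode always runs its full
    length.
    """
    weights = weights or (RewardWeights.fitness() if evaluation
                          else RewardWeights.training())
    if scene is None:
        scene = build_task_scene(spec, rng)
    state = spawn_agent(scene, rng)
    if hasattr(policy, "reset"):
        policy.reset()
    total = 0.0
    for t in range(spec.episode_steps):
        action = policy(state, scene)
        prev = state.position.copy()
        # score against the goal position *before* any respawn this step
        state, ev = step_dynamics(state, action, spec, scene)
        ctx = _context(spec.task, prev, state, scene, ev)
        r = step_reward(spec.task, ctx, weights)
        total += r
        if ledger is not None:
            ledger.append({"step": t, "reward": r,
                           "goal": ev.goal_captured,
                           "adversary": ev.adversary_captured,
                           "contact": ev.contact})
        if ev.captured_object is not None:
            if evaluation:
                respawn_object(scene, ev.captured_object, state, rng)
            else:
                break
        step_objects(scene, t + 1, rng)
    return total


def evaluate_fitness(policy, spec: TaskSpec, rng: np.random.Generator,
                     n_episodes: int = N_FITNESS_EPISODES) -> float:
    """Mean total episode reward over six evaluation episodes with the
    fitness weights; captures respawn the object rather than ending the
    episode. Deterministic given the generator state."""
    totals = [rollout_episode(policy, spec, rng, RewardWeights.fitness(),
                              evaluation=True) for _ in range(n_episodes)]
    return float(np.mean(totals))
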