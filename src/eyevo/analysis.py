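"""Post-hoc science: scaling-law sweeps, power-law fits, bootstrap
confidence intervals, and scripted oracle policies.

The scaling experiments vary visual acuity (cycles per degree, realized by
the eye's horizontal photoreceptor count at fixed field of view), neural
capacity (hidden width, hence policy parameter count N), and temporal
memory, training one agent per grid cell per seed — no evolution — and
summarize task performance as a task error

    L = (F_max - F) / F_max

the normalized shortfall from the fitness F_max of a scripted privileged
oracle policy on the same task configuration. Power-law structure L = a N^b
is fit by least squares on log L vs log N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genotype, MorphologicalGene, OpticalGene, NeuralGene
from .learning import PPOConfig, VisionAgent, build_policy, train_agent
from .optics import OpticsConfig, compute_cpd
from .rewards import evaluate_fitness
from .world import Task, TaskSpec, step_dynamics

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "BootstrapCI",
    "bootstrap_ci",
    "oracle_policy",
    "oracle_fitness",
    "ScalingRecord",
    "sweep_scaling",
    "records_to_frame",
    "SWEEP_FOV_DEG",
]

SWEEP_FOV_DEG = 45.0  # acuity grid realized by res_w at this fixed FOV


# ---------------------------------------------------------------------------
# Power-law machinery


@dataclass(frozen=True)
class PowerLawFit:
    prefactor: float   # a in L = a * N^b
    exponent: float    # b
    r_squared: float
    n_points: int

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(n, dtype=float) ** self.exponent


def fit_power_law(records) -> PowerLawFit:
    """Least-squares fit of log L on log N.

    ``records`` is an iterable of (N, L) pairs with N, L > 0 (at least 3).
    Noiseless power-law data are recovered exactly; a flat line yields
    exponent 0.
    """
    pts = np.asarray(list(records), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (N, L) points")
    n, ell = pts[:, 0], pts[:, 1]
    if np.any(n <= 0) or np.any(ell <= 0):
        raise ValueError("power-law fit requires positive N and L")
    x, y = np.log(n), np.log(ell)
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return PowerLawFit(prefactor=float(np.exp(log_a)), exponent=float(b),
                       r_squared=r2, n_points=len(n))


@dataclass
class BootstrapCI:
    mean: np.ndarray
    low: np.ndarray
    high: np.ndarray
    level: float
    degenerate: bool = False  # single replicate: zero-width interval


def bootstrap_ci(traces, level: float = 0.95, n_boot: int = 2000,
                 rng: np.random.Generator | None = None) -> BootstrapCI:
    """Percentile bootstrap of the per-generation mean across replicates.

    ``traces`` is (n_replicates, n_generations); replicates are resampled
    with replacement ``n_boot`` times.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    r = traces.shape[0]
    mean = traces.mean(axis=0)
    if r < 2:
        return BootstrapCI(mean=mean, low=mean.copy(), high=mean.copy(),
                           level=level, degenerate=True)
    rng = rng or np.random.default_rng(0)
    idx = rng.integers(0, r, size=(n_boot, r))
    boots = traces[idx].mean(axis=1)          # (n_boot, n_generations)
    alpha = (1.0 - level) / 2.0
    low = np.quantile(boots, alpha, axis=0)
    high = np.quantile(boots, 1.0 - alpha, axis=0)
    return BootstrapCI(mean=mean, low=low, high=high, level=level)


# ---------------------------------------------------------------------------
# Oracle policies (privileged, scripted)


def oracle_policy(spec: TaskSpec, n_candidates: int = 9):
    """Greedy one-step-lookahead policy with privileged scene access.

    Scans candidate heading changes, simulates the kinematics for each, and
    picks the one that best advances the task objective (away from the
    start for navigation; toward the goal otherwise), penalizing wall
    contact. Serves as the performance reference F_max of the task-error
    normalization.
    """
    turns = np.linspace(-spec.max_turn, spec.max_turn, n_candidates)

    def policy(state, scene):
        goals = [o for o in scene.objects if o.kind.value == "goal"]
        best_turn, best_score = 0.0, -np.inf
        for turn in turns:
            nxt, ev = step_dynamics(state, np.array([turn, spec.max_speed]),
                                    spec, scene)
            if spec.task is Task.NAVIGATION:
                score = float(np.linalg.norm(nxt.position - scene.start))
            else:
                score = -float(np.linalg.norm(nxt.position - goals[0].position))
            if ev.adversary_captured:
                score -= 100.0
            if ev.contact:
                score -= 0.5
            if score > best_score:
                best_score, best_turn = score, float(turn)
        return np.array([best_turn, spec.max_speed])

    return policy


def oracle_fitness(spec: TaskSpec, seed: int = 0) -> float:
    """Fitness of the scripted oracle on this task configuration."""
    return evaluate_fitness(oracle_policy(spec), spec,
                            np.random.default_rng((seed, 7)))


# ---------------------------------------------------------------------------
# Scaling sweep


@dataclass
class ScalingRecord:
    task: str
    cpd: float
    requested_cpd: float
    res_w: int
    parameter_count: int
    hidden_neurons: int
    memory_frames: int
    seed: int
    fitness: float
    oracle_fitness: float
    task_error: float


def _genotype_for_cell(res_w: int, hidden: int, memory: int) -> Genotype:
    return Genotype(
        morph=MorphologicalGene(num_eyes=1, placement_range_deg=90.0,
                                fov_deg=SWEEP_FOV_DEG, res_w=res_w, res_h=1),
        optics=OpticalGene(enabled=False),  # perfect-lens imaging isolates
                                            # acuity from optical blur
        neural=NeuralGene(hidden_neurons=hidden, memory_frames=memory),
    )


def sweep_scaling(cpd_values, hidden_values, memory_values, spec: TaskSpec,
                  budget: int = 20_000, seeds=(0,),
                  ppo: PPOConfig | None = None,
                  optics_cfg: OpticsConfig | None = None
                  ) -> list[ScalingRecord]:
    """Train and evaluate one agent per (cpd, hidden, memory, seed) cell.

    The acuity grid is realized by the horizontal photoreceptor count at a
    fixed 45-degree field of view; a requested cpd that no integer res_w
    realizes is replaced by the nearest realizable value (recorded in the
    ``requested_cpd`` column).
    """
    records: list[ScalingRecord] = []
    f_max = oracle_fitness(spec)
    for req_cpd in cpd_values:
        res_w = max(1, int(round(2.0 * SWEEP_FOV_DEG * req_cpd)))
        for hidden in hidden_values:
            for memory in memory_values:
                g = _genotype_for_cell(res_w, hidden, memory)
                actual_cpd = compute_cpd(g.morph)
                n_params = build_policy(g).parameter_count
                for seed in seeds:
                    result = train_agent(g, spec, int(seed), budget=budget,
                                         ppo=ppo, optics_cfg=optics_cfg)
                    agent = VisionAgent(g, result.net, spec, optics_cfg,
                                        noise_rng=np.random.default_rng(5),
                                        stochastic=False)
                    f = evaluate_fitness(agent, spec,
                                         np.random.default_rng((seed, 11)))
                    ell = max(0.0, (f_max - f) / f_max) if f_max > 0 \
                        else float("nan")
                    records.append(ScalingRecord(
                        task=spec.task.value, cpd=actual_cpd,
                        requested_cpd=float(req_cpd), res_w=res_w,
                        parameter_count=n_params, hidden_neurons=hidden,
                        memory_frames=memory, seed=int(seed),
                        fitness=float(f), oracle_fitness=float(f_max),
                        task_error=float(ell)))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
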