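"""Outer evolutionary loop.

CMA-ES searches the masked genotype vector (normalized to the unit cube);
each candidate is decoded, repaired to validity, trained by the inner PPO
loop under a seed derived from its (generation, rank) identity, and scored
by the six-episode fitness protocol. The previous generation's best agent
is re-evaluated alongside every asked batch (elitism), and the optimizer is
free to sample the same genotype more than once — with distinct seeds, this
averages away reinforcement learning luck.

A surrogate-fitness mode (an arbitrary function of the genotype vector, no
reinforcement learning) is a first-class feature for exercising the outer
loop at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._cmaes import CMAES
from .genome import Genotype, MutationMask, GenotypeCodec, WorldConstants, \
    primitive_genotype
from .learning import AgentIdentifier, derive_seed, train_agent, PPOConfig
from .optics import OpticsConfig
from .rewards import evaluate_fitness
from .world import TaskSpec

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "EvolutionState",
    "run_generation",
    "run_evolution",
    "REPLICATE_SEEDS",
]

#: the five inter-run replicate seeds of the standard protocol
REPLICATE_SEEDS = (0, 42, 420, 1337, 4002)


@dataclass
class EvolutionConfig:
    task: TaskSpec = field(default_factory=TaskSpec.detection)
    mask: MutationMask = field(default_factory=MutationMask.morphology)
    initial_genotype: Genotype = field(default_factory=primitive_genotype)
    population_size: int = 16
    generations: int = 50
    cma_seed: int = 0
    num_envs: int = 1
    sigma0: float = 0.15          # initial step on the unit cube
    train_budget: int = 20_000    # PPO steps per candidate
    ppo: PPOConfig | None = None
    optics_cfg: OpticsConfig | None = None
    surrogate_fitness: "callable | None" = None  # f(vector) -> fitness (max)

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.mask.any_enabled():
            raise ValueError("mutation mask enables no fields")


@dataclass
class GenerationRecord:
    generation: int
    vectors: list[list[float]]
    genotypes: list[dict]
    fitnesses: list[float]
    seeds: list[int]
    elite_vector: list[float] | None
    elite_fitness: float | None
    best_fitness: float          # best-so-far (non-decreasing trace)
    best_genotype: dict


@dataclass
class EvolutionState:
    config: EvolutionConfig
    codec: GenotypeCodec
    optimizer: CMAES
    generation: int = 0
    best_vector: np.ndarray | None = None
    best_genotype: Genotype | None = None
    best_fitness: float = -np.inf
    records: list[GenerationRecord] = field(default_factory=list)


def _init_state(cfg: EvolutionConfig) -> EvolutionState:
    codec = GenotypeCodec(cfg.mask, cfg.initial_genotype)
    x0 = codec.encode(cfg.initial_genotype)
    es = CMAES(x0, cfg.sigma0, cfg.population_size, seed=cfg.cma_seed)
    return EvolutionState(config=cfg, codec=codec, optimizer=es)


def _fitness_of(vector: np.ndarray, genotype: Genotype, seed: int,
                cfg: EvolutionConfig) -> float:
    if cfg.surrogate_fitness is not None:
        return float(cfg.surrogate_fitness(vector))
    result = train_agent(genotype, cfg.task, seed, budget=cfg.train_budget,
                         ppo=cfg.ppo, optics_cfg=cfg.optics_cfg)
    agent = _policy_from(result, cfg)
    return evaluate_fitness(agent, cfg.task,
                            np.random.default_rng((seed, 99)))


def _policy_from(result, cfg: EvolutionConfig):
    from .learning import VisionAgent

    return VisionAgent(result.genotype, result.net, cfg.task, cfg.optics_cfg,
                       noise_rng=np.random.default_rng(1234),
                       stochastic=False)


def run_generation(state: EvolutionState) -> GenerationRecord:
    """One ask -> evaluate -> tell cycle with elitist re-evaluation.

    The asked batch (population_size vectors, duplicates permitted) is
    decoded, repaired, trained, and scored; the previous best vector is
    additionally re-evaluated with this generation's elite seed and competes
    for best-so-far, but only the asked batch is fed back to the optimizer.
    """
    cfg = state.config
    gen = state.generation
    vectors = state.optimizer.ask()
    genotypes = [state.codec.decode(v) for v in vectors]
    seeds = [derive_seed(AgentIdentifier(
        num_envs=cfg.num_envs, generation=gen,
        population_size=cfg.population_size, rank=r, agent_id=0))
        for r in range(cfg.population_size)]
    fitnesses = [
        _fitness_of(v, g, s, cfg)
        for v, g, s in zip(vectors, genotypes, seeds)]

    elite_vec, elite_fit = None, None
    if state.best_vector is not None:
        elite_vec = state.best_vector.copy()
        elite_seed = derive_seed(AgentIdentifier(
            num_envs=cfg.num_envs, generation=gen,
            population_size=cfg.population_size,
            rank=cfg.population_size - 1, agent_id=0)) + 1_000_000
        elite_fit = _fitness_of(elite_vec, state.codec.decode(elite_vec),
                                elite_seed, cfg)

    state.optimizer.tell(vectors, [-f for f in fitnesses])

    # best-so-far bookkeeping (the trace records the running max; an elite
    # re-evaluation may score lower than its original record and is then
    # simply not promoted)
    gen_best = int(np.argmax(fitnesses))
    if fitnesses[gen_best] > state.best_fitness:
        state.best_fitness = fitnesses[gen_best]
        state.best_vector = vectors[gen_best].copy()
        state.best_genotype = genotypes[gen_best]
    if elite_fit is not None and elite_fit > state.best_fitness:
        state.best_fitness = elite_fit

    record = GenerationRecord(
        generation=gen,
        vectors=[v.tolist() for v in vectors],
        genotypes=[g.to_dict() for g in genotypes],
        fitnesses=[float(f) for f in fitnesses],
        seeds=seeds,
        elite_vector=elite_vec.tolist() if elite_vec is not None else None,
        elite_fitness=float(elite_fit) if elite_fit is not None else None,
        best_fitness=float(state.best_fitness),
        best_genotype=state.best_genotype.to_dict(),
    )
    state.records.append(record)
    state.generation += 1
    return record


def run_evolution(cfg: EvolutionConfig,
                  out_dir: str | Path | None = None,
                  resume_from: str | Path | None = None) -> EvolutionState:
    """Run (or resume) a full evolutionary experiment.

    When ``out_dir`` is given, the archive is checkpointed after every
    generation (config summary, one JSON line per generation record, the
    best genotype, and the optimizer state), so an interrupted run resumes
    without partial-record corruption.
    """
    if resume_from is not None:
        state = load_archive(Path(resume_from), cfg)
    else:
        state = _init_state(cfg)
    while state.generation < cfg.generations:
        run_generation(state)
        if out_dir is not None:
            save_archive(state, Path(out_dir))
    return state


# ---------------------------------------------------------------------------
# Archive I/O


def save_archive(state: EvolutionState, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = state.config
    summary = {
        "task": cfg.task.task.value,
        "population_size": cfg.population_size,
        "generations": cfg.generations,
        "cma_seed": cfg.cma_seed,
        "num_envs": cfg.num_envs,
        "sigma0": cfg.sigma0,
        "train_budget": cfg.train_budget,
        "mask": asdict(cfg.mask),
        "surrogate": cfg.surrogate_fitness is not None,
    }
    (out_dir / "config.json").write_text(json.dumps(summary, indent=1))
    with open(out_dir / "generations.jsonl", "w") as fh:
        for rec in state.records:
            fh.write(json.dumps(asdict(rec)) + "\n")
    (out_dir / "best_genotype.json").write_text(
        json.dumps(state.best_genotype.to_dict() if state.best_genotype
                   else None, indent=1))
    (out_dir / "optimizer.json").write_text(
        json.dumps({"state": state.optimizer.to_dict(),
                    "generation": state.generation,
                    "best_vector": (state.best_vector.tolist()
                                    if state.best_vector is not None else None),
                    "best_fitness": float(state.best_fitness)}))
    with open(out_dir / "fitness.csv", "w") as fh:
        fh.write("generation,rank,fitness,best_so_far\n")
        for rec in state.records:
            for r, f in enumerate(rec.fitnesses):
                fh.write(f"{rec.generation},{r},{f},{rec.best_fitness}\n")


def load_archive(out_dir: Path, cfg: EvolutionConfig) -> EvolutionState:
    out_dir = Path(out_dir)
    opt = json.loads((out_dir / "optimizer.json").read_text())
    state = _init_state(cfg)
    state.optimizer = CMAES.from_dict(opt["state"])
    state.generation = int(opt["generation"])
    state.best_fitness = float(opt["best_fitness"])
    if opt["best_vector"] is not None:
        state.best_vector = np.asarray(opt["best_vector"])
        state.best_genotype = state.codec.decode(state.best_vector)
    with open(out_dir / "generations.jsonl") as fh:
        for line in fh:
            state.records.append(GenerationRecord(**json.loads(line)))
    return state
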