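"""Inner-loop behavior learning.

Deterministic seed derivation, observation assembly (per-eye compositing,
temporal frame stacking, contact flag + previous action), a
morphology-conditioned policy network, and proximal policy optimization
(PPO) with periodic evaluation and early stopping.

The policy architecture follows the agent's genotype: each eye owns a small
feature extractor (a single-hidden-layer MLP) over its flattened stacked
pixels; the per-eye features are concatenated with the contact boolean and
the previous action and fed to a trunk of two identically sized hidden
layers (width = the neural gene's hidden_neurons), ending in a two-output
action head (heading change, forward speed). Pre-squash actions are
Gaussian; tanh squashing maps them into the actuator bounds.

PPO is implemented directly in numpy (clipped surrogate objective,
generalized advantage estimation, Adam) with hand-rolled backpropagation —
the networks involved are small dense MLPs, so this stays fast and exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import Genotype, NeuralGene, compute_eye_placements
from .optics import OpticsConfig, PSFStack, compute_psf_stack, \
    render_retinal_image
from .world import TaskSpec, Scene, build_task_scene, spawn_agent, \
    step_dynamics, step_objects, render_eye_latent
from .rewards import RewardWeights, StepContext, step_reward, _context, \
    rollout_episode

__all__ = [
    "AgentIdentifier",
    "derive_seed",
    "Observation",
    "ObservationBuffer",
    "assemble_observation",
    "stack_depth",
    "PolicySpec",
    "PolicyNetwork",
    "build_policy",
    "VisionAgent",
    "TrainResult",
    "PPOConfig",
    "train_agent",
]

EXTRACTOR_WIDTH = 16  # per-eye visual processing unit hidden width
N_EXTRA_INPUTS = 3    # contact boolean + previous action (2)
N_ACTIONS = 2


# ---------------------------------------------------------------------------
# Seeds


@dataclass(frozen=True)
class AgentIdentifier:
    """Locates one agent evaluation within an evolutionary run."""

    num_envs: int = 1
    generation: int = 0
    population_size: int = 16
    rank: int = 0
    agent_id: int = 0

    def __post_init__(self):
        if self.num_envs < 1:
            raise ValueError("num_envs must be >= 1")
        if min(self.generation, self.rank, self.agent_id) < 0:
            raise ValueError("generation, rank, agent_id must be >= 0")
        if not self.rank < self.population_size:
            raise ValueError("rank must be < population_size")


def derive_seed(idn: AgentIdentifier) -> int:
    """seed = num_envs * (generation * population_size + rank) + agent_id.

    Injective over (generation, rank, agent_id) for a fixed num_envs as long
    as agent_id < num_envs, so every agent trains under a unique seed.
    """
    return idn.num_envs * (idn.generation * idn.population_size + idn.rank) \
        + idn.agent_id


# ---------------------------------------------------------------------------
# Observations


def stack_depth(neural: NeuralGene) -> int:
    """Temporal stack depth: the memory gene, floored at one (the current
    frame is always present)."""
    return max(1, neural.memory_frames)


@dataclass
class Observation:
    visual: np.ndarray          # (depth, num_eyes, res_h, res_w, 3)
    contact: bool
    prev_action: np.ndarray     # (2,)


class ObservationBuffer:
    """FIFO memory of composited eye frames.

    At episode start the buffer is seeded by repeating the first frame, so
    every stack slice is defined from step one (zero-padding would alias
    darkness).
    """

    def __init__(self, depth: int):
        self.depth = depth
        self._frames: list[np.ndarray] = []

    def reset(self) -> None:
        self._frames = []

    def push(self, frame: np.ndarray) -> None:
        if not self._frames:
            self._frames = [frame.copy() for _ in range(self.depth)]
        else:
            self._frames.pop(0)
            self._frames.append(frame)

    def stacked(self) -> np.ndarray:
        if not self._frames:
            raise RuntimeError("buffer empty: push a frame first")
        return np.stack(self._frames, axis=0)


def assemble_observation(eye_images: list[np.ndarray],
                         buffer: ObservationBuffer, contact: bool,
                         prev_action: np.ndarray,
                         neural: NeuralGene) -> Observation:
    """Composite per-eye retinal images and stack them with the memory.

    ``eye_images`` holds one (res_h, res_w, 3) array per eye this step; the
    composite (num_eyes, res_h, res_w, 3) frame is pushed into the FIFO and
    the stacked (depth, num_eyes, res_h, res_w, 3) tensor returned together
    with the contact flag and previous action.
    """
    if buffer.depth != stack_depth(neural):
        raise ValueError("buffer depth does not match the neural gene")
    frame = np.stack([np.asarray(im, dtype=float) for im in eye_images], axis=0)
    buffer.push(frame)
    return Observation(visual=buffer.stacked(), contact=bool(contact),
                       prev_action=np.asarray(prev_action, dtype=float))


# ---------------------------------------------------------------------------
# Policy network


@dataclass(frozen=True)
class PolicySpec:
    num_eyes: int
    eye_input: int          # flattened stacked pixels per eye
    extractor_width: int
    hidden_neurons: int
    parameter_count: int


def policy_parameter_count(num_eyes: int, eye_input: int,
                           hidden_neurons: int,
                           extractor_width: int = EXTRACTOR_WIDTH) -> int:
    """Closed-form dense-layer parameter count of the behavior policy
    (extractors + trunk + action head + action log-std)."""
    e, w, h = num_eyes, extractor_width, hidden_neurons
    feat = e * w + N_EXTRA_INPUTS
    n = e * (eye_input * w + w)          # per-eye extractors
    n += feat * h + h                    # trunk layer 1
    n += h * h + h                       # trunk layer 2
    n += h * N_ACTIONS + N_ACTIONS       # action mean head
    n += N_ACTIONS                       # action log-std
    return n


def build_policy(g: Genotype) -> PolicySpec:
    """Policy architecture implied by a genotype, with exact parameter
    count."""
    depth = stack_depth(g.neural)
    eye_input = depth * g.morph.res_h * g.morph.res_w * 3
    return PolicySpec(
        num_eyes=g.morph.num_eyes, eye_input=eye_input,
        extractor_width=EXTRACTOR_WIDTH,
        hidden_neurons=g.neural.hidden_neurons,
        parameter_count=policy_parameter_count(
            g.morph.num_eyes, eye_input, g.neural.hidden_neurons))


def _init_dense(rng, fan_in, fan_out, scale=None):
    scale = scale if scale is not None else math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, scale, size=(fan_in, fan_out)), np.zeros(fan_out)


class _MLPHead:
    """Extractors + trunk + linear head with manual backprop (tanh units)."""

    def __init__(self, spec: PolicySpec, head_out: int,
                 rng: np.random.Generator):
        self.spec = spec
        e, w, h = spec.num_eyes, spec.extractor_width, spec.hidden_neurons
        self.We, self.be = [], []
        for _ in range(e):
            W, b = _init_dense(rng, spec.eye_input, w)
            self.We.append(W)
            self.be.append(b)
        feat = e * w + N_EXTRA_INPUTS
        self.W1, self.b1 = _init_dense(rng, feat, h)
        self.W2, self.b2 = _init_dense(rng, h, h)
        self.Wo, self.bo = _init_dense(rng, h, head_out, scale=0.01)

    def params(self) -> list[np.ndarray]:
        return [*self.We, *self.be, self.W1, self.b1, self.W2, self.b2,
                self.Wo, self.bo]

    def forward(self, eyes: np.ndarray, extra: np.ndarray):
        """eyes: (B, E, eye_input); extra: (B, 3). Returns output and a
        cache for backward."""
        hs = [np.tanh(eyes[:, i] @ self.We[i] + self.be[i])
              for i in range(self.spec.num_eyes)]
        f = np.concatenate(hs + [extra], axis=1)
        t1 = np.tanh(f @ self.W1 + self.b1)
        t2 = np.tanh(t1 @ self.W2 + self.b2)
        out = t2 @ self.Wo + self.bo
        return out, (eyes, hs, f, t1, t2)

    def backward(self, d_out: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients in the order of params()."""
        eyes, hs, f, t1, t2 = cache
        e, w = self.spec.num_eyes, self.spec.extractor_width
        gWo = t2.T @ d_out
        gbo = d_out.sum(0)
        dt2 = (d_out @ self.Wo.T) * (1 - t2 ** 2)
        gW2 = t1.T @ dt2
        gb2 = dt2.sum(0)
        dt1 = (dt2 @ self.W2.T) * (1 - t1 ** 2)
        gW1 = f.T @ dt1
        gb1 = dt1.sum(0)
        df = dt1 @ self.W1.T
        gWe, gbe = [], []
        for i in range(e):
            dh = df[:, i * w:(i + 1) * w] * (1 - hs[i] ** 2)
            gWe.append(eyes[:, i].T @ dh)
            gbe.append(dh.sum(0))
        return [*gWe, *gbe, gW1, gb1, gW2, gb2, gWo, gbo]


class PolicyNetwork:
    """Actor-critic pair; the actor's parameters are the genotype-implied
    behavior policy counted by build_policy."""

    def __init__(self, spec: PolicySpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.actor = _MLPHead(spec, N_ACTIONS, rng)
        self.log_std = np.full(N_ACTIONS, -0.5)
        self.critic = _MLPHead(spec, 1, rng)

    def actor_params(self) -> list[np.ndarray]:
        return self.actor.params() + [self.log_std]

    def all_params(self) -> list[np.ndarray]:
        return self.actor.params() + [self.log_std] + self.critic.params()

    def n_policy_parameters(self) -> int:
        return int(sum(p.size for p in self.actor_params()))

    def act_mean(self, eyes: np.ndarray, extra: np.ndarray) -> np.ndarray:
        return self.actor.forward(eyes, extra)[0]

    def value(self, eyes: np.ndarray, extra: np.ndarray) -> np.ndarray:
        return self.critic.forward(eyes, extra)[0][:, 0]


def flatten_observation(obs: Observation) -> tuple[np.ndarray, np.ndarray]:
    """(eyes, extra) network inputs from one Observation."""
    depth, e = obs.visual.shape[0], obs.visual.shape[1]
    eyes = obs.visual.transpose(1, 0, 2, 3, 4).reshape(e, -1)
    extra = np.concatenate([[float(obs.contact)], obs.prev_action])
    return eyes[None], extra[None]


def squash_action(u: np.ndarray, spec: TaskSpec) -> np.ndarray:
    """Map pre-squash Gaussian outputs into actuator bounds."""
    return np.array([
        spec.max_turn * math.tanh(float(u[0])),
        spec.max_speed * 0.5 * (math.tanh(float(u[1])) + 1.0),
    ])


# ---------------------------------------------------------------------------
# Embodied agent: genotype + policy + sensor pipeline


class VisionAgent:
    """Callable (state, scene) -> action wrapping the full sensory chain:
    raycast latents per eye, PSF blur + throughput + sensor noise, memory
    stacking, policy forward pass. ``stochastic`` samples the Gaussian
    policy (training); otherwise the mean action is used (evaluation)."""

    def __init__(self, genotype: Genotype, net: PolicyNetwork,
                 task_spec: TaskSpec, optics_cfg: OpticsConfig | None = None,
                 noise_rng: np.random.Generator | None = None,
                 stochastic: bool = False,
                 action_rng: np.random.Generator | None = None):
        self.genotype = genotype
        self.net = net
        self.task_spec = task_spec
        self.cfg = optics_cfg or OpticsConfig()
        self.noise_rng = noise_rng or np.random.default_rng(0)
        self.action_rng = action_rng
        self.stochastic = stochastic
        self.placements = compute_eye_placements(
            genotype.morph.num_eyes, genotype.morph.placement_range_deg)
        self.psf: PSFStack = compute_psf_stack(
            genotype.optics, genotype.morph, self.cfg)
        self.buffer = ObservationBuffer(stack_depth(genotype.neural))
        self.last: tuple | None = None  # (obs inputs, u, logp, value)

    def reset(self) -> None:
        self.buffer.reset()

    def observe(self, state, scene: Scene, peek: bool = False) -> Observation:
        images = []
        for lon in self.placements:
            latent = render_eye_latent(scene, state, lon, self.genotype.morph)
            img = render_retinal_image(latent, self.psf, self.genotype.optics,
                                       self.cfg, rng=self.noise_rng)
            images.append(img.pixels)
        if peek:
            # value bootstrap between rollout chunks: do not consume a
            # buffer slot
            frame = np.stack(images, axis=0)
            frames = self.buffer._frames[1:] + [frame] \
                if self.buffer._frames else [frame] * self.buffer.depth
            visual = np.stack(frames, axis=0)
            return Observation(visual=visual, contact=bool(state.contact),
                               prev_action=np.asarray(state.prev_action,
                                                      dtype=float))
        return assemble_observation(images, self.buffer, state.contact,
                                    state.prev_action, self.genotype.neural)

    def __call__(self, state, scene: Scene) -> np.ndarray:
        obs = self.observe(state, scene)
        eyes, extra = flatten_observation(obs)
        mean = self.net.act_mean(eyes, extra)[0]
        if self.stochastic:
            std = np.exp(self.net.log_std)
            u = mean + std * self.action_rng.normal(size=N_ACTIONS)
            logp = float(
                -0.5 * np.sum(((u - mean) / std) ** 2)
                - np.sum(self.net.log_std) - N_ACTIONS * 0.5 * math.log(2 * math.pi))
            value = float(self.net.value(eyes, extra)[0])
            self.last = ((eyes[0], extra[0]), u, logp, value)
        else:
            u = mean
        return squash_action(u, self.task_spec)


# ---------------------------------------------------------------------------
# PPO


@dataclass
class PPOConfig:
    n_steps: int = 1024          # rollout length per update
    n_epochs: int = 10
    minibatch_size: int = 64
    gamma: float = 0.99
    gae_lambda: float = 0.95
    clip_range: float = 0.2
    learning_rate: float = 3e-4
    vf_coef: float = 0.5
    ent_coef: float = 0.0
    max_grad_norm: float = 0.5
    eval_interval: int = 10_000
    eval_episodes: int = 3
    improvement_tol: float = 1e-3
    patience: int = 5


@dataclass
class TrainResult:
    net: PolicyNetwork
    eval_history: list[tuple[int, float]]
    steps_used: int
    stopped_early: bool
    genotype: Genotype = None
    best_eval: float = -np.inf


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, max_norm=None):
        if max_norm is not None:
            norm = math.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if norm > max_norm:
                grads = [g * (max_norm / norm) for g in grads]
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g ** 2
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _evaluate_policy(agent: VisionAgent, spec: TaskSpec, seed: int,
                     n_episodes: int) -> float:
    agent.stochastic = False
    rng = np.random.default_rng(seed)
    totals = [rollout_episode(agent, spec, rng, RewardWeights.training())
              for _ in range(n_episodes)]
    return float(np.mean(totals))


def train_agent(genotype: Genotype, spec: TaskSpec,
                idn: AgentIdentifier | int = 0, budget: int = 100_000,
                ppo: PPOConfig | None = None,
                optics_cfg: OpticsConfig | None = None) -> TrainResult:
    """Train an agent's behavior with PPO under a derived seed.

    ``budget`` caps total environment steps (the full protocol uses up to
    one million; desk-scale runs use far less). Training stops early when
    ``patience`` consecutive evaluations fail to improve on the best mean
    evaluation reward by at least ``improvement_tol``; the returned network
    carries the parameters of the best evaluation. budget = 0 returns the
    untrained policy with its baseline evaluation.
    """
    ppo = ppo or PPOConfig()
    if budget > 1_000_000:
        raise ValueError("budget exceeds the 1M-step cap")
    seed = derive_seed(idn) if isinstance(idn, AgentIdentifier) else int(idn)
    pspec = build_policy(genotype)
    net = PolicyNetwork(pspec, seed=seed)
    noise_rng = np.random.default_rng((seed, 1))
    action_rng = np.random.default_rng((seed, 2))
    env_rng = np.random.default_rng((seed, 3))
    agent = VisionAgent(genotype, net, spec, optics_cfg,
                        noise_rng=noise_rng, stochastic=True,
                        action_rng=action_rng)

    def snapshot():
        return [p.copy() for p in net.all_params()]

    def restore(saved):
        for p, s in zip(net.all_params(), saved):
            p[:] = s

    history: list[tuple[int, float]] = []
    best = _evaluate_policy(agent, spec, seed + 10_000, ppo.eval_episodes)
    history.append((0, best))
    best_params = snapshot()
    if budget <= 0:
        agent.stochastic = False
        return TrainResult(net=net, eval_history=history, steps_used=0,
                           stopped_early=False, genotype=genotype,
                           best_eval=best)

    opt = _Adam(net.all_params(), ppo.learning_rate)
    steps_done = 0
    since_eval = 0
    no_improve = 0
    stopped_early = False

    # persistent episode state across rollout chunks
    scene = build_task_scene(spec, env_rng)
    state = spawn_agent(scene, env_rng)
    agent.reset()
    ep_step = 0

    while steps_done < budget:
        n = min(ppo.n_steps, budget - steps_done)
        eyes_b = np.empty((n, pspec.num_eyes, pspec.eye_input))
        extra_b = np.empty((n, N_EXTRA_INPUTS))
        u_b = np.empty((n, N_ACTIONS))
        logp_b = np.empty(n)
        val_b = np.empty(n)
        rew_b = np.empty(n)
        done_b = np.zeros(n, dtype=bool)

        agent.stochastic = True
        for t in range(n):
            action = agent(state, scene)
            (ei, ex), u, logp, value = agent.last
            prev = state.position.copy()
            state, ev = step_dynamics(state, action, spec, scene)
            ctx = _context(spec.task, prev, state, scene, ev)
            r = step_reward(spec.task, ctx, RewardWeights.training())
            ep_step += 1
            done = (ev.captured_object is not None
                    or ep_step >= spec.episode_steps)
            eyes_b[t], extra_b[t] = ei, ex
            u_b[t], logp_b[t], val_b[t], rew_b[t] = u, logp, value, r
            done_b[t] = done
            if done:
                scene = build_task_scene(spec, env_rng)
                state = spawn_agent(scene, env_rng)
                agent.reset()
                ep_step = 0
            else:
                step_objects(scene, ep_step, env_rng)
        steps_done += n
        since_eval += n

        # bootstrap value for the final state
        obs = agent.observe(state, scene, peek=True)
        ei, ex = flatten_observation(obs)
        last_val = float(net.value(ei, ex)[0])
        adv = np.zeros(n)
        gae = 0.0
        for t in reversed(range(n)):
            next_val = last_val if t == n - 1 else val_b[t + 1]
            nonterm = 0.0 if done_b[t] else 1.0
            delta = rew_b[t] + ppo.gamma * next_val * nonterm - val_b[t]
            gae = delta + ppo.gamma * ppo.gae_lambda * nonterm * gae
            adv[t] = gae
        returns = adv + val_b
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        idx = np.arange(n)
        perm_rng = np.random.default_rng((seed, 4, steps_done))
        for _ in range(ppo.n_epochs):
            perm_rng.shuffle(idx)
            for s0 in range(0, n, ppo.minibatch_size):
                mb = idx[s0:s0 + ppo.minibatch_size]
                _ppo_update(net, opt, ppo, eyes_b[mb], extra_b[mb], u_b[mb],
                            logp_b[mb], adv[mb], returns[mb])

        while since_eval >= ppo.eval_interval or steps_done >= budget:
            since_eval -= ppo.eval_interval
            score = _evaluate_policy(agent, spec, seed + 10_000,
                                     ppo.eval_episodes)
            history.append((steps_done, score))
            if score > best + ppo.improvement_tol:
                best = score
                best_params = snapshot()
                no_improve = 0
            else:
                no_improve += 1
            if steps_done >= budget:
                break
        if no_improve >= ppo.patience:
            stopped_early = True
            break

    restore(best_params)
    agent.stochastic = False
    return TrainResult(net=net, eval_history=history, steps_used=steps_done,
                       stopped_early=stopped_early, genotype=genotype,
                       best_eval=best)


def _ppo_update(net: PolicyNetwork, opt: _Adam, cfg: PPOConfig,
                eyes, extra, u, logp_old, adv, returns):
    B = eyes.shape[0]
    mean, cache_a = net.actor.forward(eyes, extra)
    std = np.exp(net.log_std)
    z = (u - mean) / std
    logp = (-0.5 * (z ** 2).sum(1) - net.log_std.sum()
            - N_ACTIONS * 0.5 * math.log(2 * math.pi))
    ratio = np.exp(logp - logp_old)
    unclipped = ratio * adv
    clipped = np.clip(ratio, 1 - cfg.clip_range, 1 + cfg.clip_range) * adv
    # gradient flows only through the active (unclipped-min) branch
    active = unclipped <= clipped
    d_logp = np.where(active, -ratio * adv, 0.0) / B

    d_mean = d_logp[:, None] * (z / std)          # dlogp/dmean = z/std
    d_log_std = (d_logp[:, None] * (z ** 2 - 1.0)).sum(0)
    if cfg.ent_coef:
        d_log_std -= cfg.ent_coef * np.ones(N_ACTIONS)
    grads_actor = net.actor.backward(d_mean, cache_a)

    val, cache_c = net.critic.forward(eyes, extra)
    err = val[:, 0] - returns
    d_val = (cfg.vf_coef * 2.0 * err / B)[:, None]
    grads_critic = net.critic.backward(d_val, cache_c)

    opt.step(net.all_params(),
             grads_actor + [d_log_std] + grads_critic,
             max_norm=cfg.max_grad_norm)
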