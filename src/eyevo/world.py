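"""Lightweight 2D kinematic world: procedural task scenes, point-mass agent
dynamics, and per-eye latent-scene rendering by raycasting.

Tasks
-----
NAVIGATION   a randomized perfect maze whose walls carry black-and-white
             stripe patterns of differing frequencies; the agent is rewarded
             for moving away from its start as fast as possible without
             hitting walls.
DETECTION    an open walled arena holding one goal sphere and two adversary
             spheres, visually identical except for the rotation of a
             high-frequency azimuthal stripe pattern.
TRACKING     the detection arena with moving objects (fixed speed, random
             headings resampled periodically).

The world is top-down 2D: each eye casts one ray per latent-image column
across its field of view and the resulting 1-pixel-tall strip is extruded
vertically to the eye's row count. Hit distances form the depth map. The
renderer is a pluggable contract — anything producing a LatentScene per eye
can substitute without touching optics or learning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genome import MorphologicalGene, AGENT_RADIUS
from .optics import LatentScene, latent_shape

__all__ = [
    "Task",
    "TaskSpec",
    "AgentState",
    "SceneObject",
    "Wall",
    "Scene",
    "StepEvents",
    "build_task_scene",
    "spawn_agent",
    "step_dynamics",
    "step_objects",
    "render_eye_latent",
    "respawn_object",
    "scene_to_json",
    "scene_from_json",
]

BACKGROUND_COLOR = (0.12, 0.12, 0.15)
FAR_DEPTH = 50.0


class Task(str, Enum):
    NAVIGATION = "navigation"
    DETECTION = "detection"
    TRACKING = "tracking"


class ObjectKind(str, Enum):
    GOAL = "goal"
    ADVERSARY = "adversary"


@dataclass
class TaskSpec:
    """Task identity plus episode and dynamics constants."""

    task: Task = Task.DETECTION
    episode_steps: int = 500
    dt: float = 0.1
    max_turn: float = 0.3        # |delta heading| per step, radians
    max_speed: float = 1.0       # units / s
    object_speed: float = 0.0    # TRACKING only
    object_heading_period: int = 50  # steps between heading resamples
    arena_size: float = 10.0
    object_radius: float = 0.3
    n_adversaries: int = 2
    pattern_stripes: int = 8
    goal_rotation_deg: float = 22.5
    maze_cells: int = 5
    corridor_width: float = 1.0
    spawn_mode: str = "random"   # "random" | "dead_ahead"

    def __post_init__(self):
        self.task = Task(self.task)
        if self.episode_steps <= 0:
            raise ValueError("episode_steps must be > 0")
        if self.task is not Task.TRACKING:
            self.object_speed = 0.0
        elif self.object_speed == 0.0:
            self.object_speed = 0.3

    @classmethod
    def navigation(cls, **kw) -> "TaskSpec":
        return cls(task=Task.NAVIGATION, **kw)

    @classmethod
    def detection(cls, **kw) -> "TaskSpec":
        return cls(task=Task.DETECTION, **kw)

    @classmethod
    def tracking(cls, **kw) -> "TaskSpec":
        return cls(task=Task.TRACKING, **kw)


@dataclass
class AgentState:
    position: np.ndarray
    heading: float = 0.0
    speed: float = 0.0
    contact: bool = False
    prev_action: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def copy(self) -> "AgentState":
        return AgentState(self.position.copy(), self.heading, self.speed,
                          self.contact, self.prev_action.copy())


@dataclass
class SceneObject:
    kind: ObjectKind
    position: np.ndarray
    radius: float
    pattern_stripes: int
    pattern_rotation_deg: float
    heading: float = 0.0
    speed: float = 0.0


@dataclass
class Wall:
    """A line segment with an optional stripe texture (cycles per wall)."""

    a: np.ndarray
    b: np.ndarray
    stripe_cycles: int = 0  # 0 = untextured (plain wall color)

    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))


@dataclass
class Scene:
    spec: TaskSpec
    walls: list[Wall]
    objects: list[SceneObject]
    start: np.ndarray
    exit_direction: np.ndarray | None = None
    seed: int | None = None


@dataclass
class StepEvents:
    goal_captured: bool = False
    adversary_captured: bool = False
    contact: bool = False
    captured_object: SceneObject | None = None


# ---------------------------------------------------------------------------
# Scene construction

WALL_COLOR = (0.45, 0.45, 0.45)


def _boundary_walls(size: float) -> list[Wall]:
    s = size / 2.0
    corners = [(-s, -s), (s, -s), (s, s), (-s, s)]
    return [Wall(np.array(corners[i], float), np.array(corners[(i + 1) % 4], float))
            for i in range(4)]


def _perfect_maze(cells: int, rng: np.random.Generator) -> list[tuple]:
    """Randomized-DFS perfect maze; returns closed wall segments on the unit
    cell grid as ((x1,y1),(x2,y2)) tuples."""
    visited = np.zeros((cells, cells), bool)
    h_walls = np.ones((cells + 1, cells), bool)  # horizontal walls below row i
    v_walls = np.ones((cells, cells + 1), bool)  # vertical walls left of col j
    stack = [(0, 0)]
    visited[0, 0] = True
    while stack:
        i, j = stack[-1]
        nbrs = []
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < cells and 0 <= nj < cells and not visited[ni, nj]:
                nbrs.append((ni, nj, di, dj))
        if not nbrs:
            stack.pop()
            continue
        ni, nj, di, dj = nbrs[rng.integers(len(nbrs))]
        if di:  # knock out horizontal wall between rows
            h_walls[max(i, ni), j] = False
        else:
            v_walls[i, max(j, nj)] = False
        visited[ni, nj] = True
        stack.append((ni, nj))
    segs = []
    for r in range(cells + 1):
        for c in range(cells):
            if h_walls[r, c]:
                segs.append(((c, r), (c + 1, r)))
    for r in range(cells):
        for c in range(cells + 1):
            if v_walls[r, c]:
                segs.append(((c, r), (c, r + 1)))
    return segs


def build_task_scene(spec: TaskSpec, rng: np.random.Generator) -> Scene:
    """Procedurally generate the scene for a task.

    NAVIGATION: a maze with striped walls, agent starting in the corner
    cell. DETECTION / TRACKING: an open arena with one goal and
    ``n_adversaries`` adversary spheres, identical except pattern rotation.
    """
    if spec.task is Task.NAVIGATION:
        cw = spec.corridor_width
        segs = _perfect_maze(spec.maze_cells, rng)
        half = spec.maze_cells * cw / 2.0
        walls = []
        freqs = (2, 4, 8)
        for (x1, y1), (x2, y2) in segs:
            a = np.array([x1 * cw - half, y1 * cw - half])
            b = np.array([x2 * cw - half, y2 * cw - half])
            walls.append(Wall(a, b, stripe_cycles=int(freqs[rng.integers(3)])))
        start = np.array([cw / 2.0 - half, cw / 2.0 - half])
        return Scene(spec=spec, walls=walls, objects=[], start=start,
                     exit_direction=np.array([1.0, 0.0]))

    walls = _boundary_walls(spec.arena_size)
    objects: list[SceneObject] = []
    kinds = [ObjectKind.GOAL] + [ObjectKind.ADVERSARY] * spec.n_adversaries
    if spec.spawn_mode == "dead_ahead":
        start = np.array([0.0, 0.0])
        positions = [np.array([3.0, 0.0])]
        for i in range(spec.n_adversaries):
            ang = np.pi * (0.6 + 0.5 * i)
            positions.append(3.0 * np.array([math.cos(ang), math.sin(ang)]))
    else:
        start = rng.uniform(-spec.arena_size / 4, spec.arena_size / 4, size=2)
        positions = []
        lim = spec.arena_size / 2 - spec.object_radius - 0.2
        while len(positions) < len(kinds):
            p = rng.uniform(-lim, lim, size=2)
            if np.linalg.norm(p - start) < 1.5:
                continue
            if any(np.linalg.norm(p - q) < 2.5 * spec.object_radius
                   for q in positions):
                continue
            positions.append(p)
    for kind, pos in zip(kinds, positions):
        rot = spec.goal_rotation_deg if kind is ObjectKind.GOAL else 0.0
        objects.append(SceneObject(
            kind=kind, position=np.asarray(pos, float),
            radius=spec.object_radius, pattern_stripes=spec.pattern_stripes,
            pattern_rotation_deg=rot,
            heading=float(rng.uniform(0, 2 * np.pi)),
            speed=spec.object_speed))
    return Scene(spec=spec, walls=walls, objects=objects, start=start)


def spawn_agent(scene: Scene, rng: np.random.Generator | None = None
                ) -> AgentState:
    heading = 0.0
    if scene.spec.task is Task.NAVIGATION:
        heading = math.atan2(*(scene.exit_direction[::-1]
                               if scene.exit_direction is not None
                               else (0.0, 1.0)))
    return AgentState(position=scene.start.copy(), heading=heading)


# ---------------------------------------------------------------------------
# Dynamics


def _seg_point_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    ab = b - a
    t = float(np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0))
    closest = a + t * ab
    return float(np.linalg.norm(p - closest)), closest


def _resolve_walls(pos: np.ndarray, walls: list[Wall], radius: float
                   ) -> tuple[np.ndarray, bool]:
    contact = False
    for _ in range(4):  # a few passes handle corners
        moved = False
        for w in walls:
            d, closest = _seg_point_distance(pos, w.a, w.b)
            if d < radius:
                contact = True
                n = pos - closest
                nn = np.linalg.norm(n)
                n = n / nn if nn > 1e-9 else np.array([0.0, 1.0])
                pos = closest + n * radius
                moved = True
        if not moved:
            break
    return pos, contact


def step_dynamics(state: AgentState, action: np.ndarray, spec: TaskSpec,
                  scene: Scene) -> tuple[AgentState, StepEvents]:
    """Advance the point-mass agent one step.

    ``action`` = (delta_heading, speed), clipped to the actuator bounds.
    Wall penetration is resolved by projecting the body circle back onto
    the wall surface (contact = True); captures fire when the agent comes
    within the sum of radii of an object.
    """
    d_heading = float(np.clip(action[0], -spec.max_turn, spec.max_turn))
    speed = float(np.clip(action[1], 0.0, spec.max_speed))
    new = state.copy()
    new.heading = (state.heading + d_heading) % (2 * np.pi)
    direction = np.array([math.cos(new.heading), math.sin(new.heading)])
    new.position = state.position + speed * spec.dt * direction
    new.speed = speed
    new.position, contact = _resolve_walls(new.position, scene.walls,
                                           AGENT_RADIUS)
    new.contact = contact
    new.prev_action = np.array([d_heading, speed])

    ev = StepEvents(contact=contact)
    for obj in scene.objects:
        if np.linalg.norm(new.position - obj.position) < AGENT_RADIUS + obj.radius:
            if obj.kind is ObjectKind.GOAL:
                ev.goal_captured = True
            else:
                ev.adversary_captured = True
            ev.captured_object = obj
            break
    return new, ev


def step_objects(scene: Scene, step_index: int, rng: np.random.Generator) -> None:
    """Advance non-trainable objects (TRACKING): fixed speed, headings
    resampled every object_heading_period steps, reflected off walls."""
    spec = scene.spec
    if spec.task is not Task.TRACKING:
        return
    lim = spec.arena_size / 2 - spec.object_radius
    for obj in scene.objects:
        if step_index % spec.object_heading_period == 0:
            obj.heading = float(rng.uniform(0, 2 * np.pi))
        d = np.array([math.cos(obj.heading), math.sin(obj.heading)])
        obj.position = obj.position + obj.speed * spec.dt * d
        for axis in range(2):
            if abs(obj.position[axis]) > lim:
                obj.position[axis] = float(np.clip(obj.position[axis], -lim, lim))
                obj.heading = float(math.atan2(
                    -d[1] if axis == 1 else d[1],
                    -d[0] if axis == 0 else d[0]))


def respawn_object(scene: Scene, obj: SceneObject, agent: AgentState,
                   rng: np.random.Generator, min_distance: float = 2.0) -> None:
    """Move a captured object to a fresh random position (evaluation mode)."""
    lim = scene.spec.arena_size / 2 - obj.radius - 0.2
    for _ in range(200):
        p = rng.uniform(-lim, lim, size=2)
        if np.linalg.norm(p - agent.position) >= min_distance:
            obj.position = p
            return
    obj.position = np.array([lim, lim])


# ---------------------------------------------------------------------------
# Raycast renderer


def _ray_segment(origin, direction, a, b) -> float | None:
    # solve origin + t*direction = a + u*(b-a), t>0, 0<=u<=1
    v = b - a
    denom = direction[0] * (-v[1]) - direction[1] * (-v[0])
    if abs(denom) < 1e-12:
        return None
    w = a - origin
    t = (w[0] * (-v[1]) - w[1] * (-v[0])) / denom
    u = (direction[0] * w[1] - direction[1] * w[0]) / denom
    if t > 1e-9 and 0.0 <= u <= 1.0:
        return t
    return None


def _ray_circle(origin, direction, center, radius) -> float | None:
    oc = origin - center
    b = np.dot(oc, direction)
    c = np.dot(oc, oc) - radius * radius
    disc = b * b - c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    for t in (-b - sq, -b + sq):
        if t > 1e-9:
            return t
    return None


def _wall_color(wall: Wall, hit: np.ndarray) -> tuple:
    if wall.stripe_cycles <= 0:
        return WALL_COLOR
    u = np.linalg.norm(hit - wall.a) / max(wall.length(), 1e-9)
    phase = u * wall.stripe_cycles
    return (1.0, 1.0, 1.0) if (int(phase * 2) % 2 == 0) else (0.02, 0.02, 0.02)


def _object_color(obj: SceneObject, hit: np.ndarray) -> tuple:
    ang = math.degrees(math.atan2(hit[1] - obj.position[1],
                                  hit[0] - obj.position[0])) % 360.0
    phase = (ang + obj.pattern_rotation_deg) / 360.0 * obj.pattern_stripes
    base = (1.0, 1.0, 1.0) if (int(phase * 2) % 2 == 0) else (0.05, 0.05, 0.05)
    return base


def raycast(scene: Scene, origin: np.ndarray, angle: float
            ) -> tuple[tuple, float]:
    """Nearest-hit color and distance for one ray; background at FAR_DEPTH
    when nothing is hit."""
    direction = np.array([math.cos(angle), math.sin(angle)])
    best_t, best_color = None, BACKGROUND_COLOR
    for w in scene.walls:
        t = _ray_segment(origin, direction, w.a, w.b)
        if t is not None and (best_t is None or t < best_t):
            best_t = t
            best_color = _wall_color(w, origin + t * direction)
    for obj in scene.objects:
        t = _ray_circle(origin, direction, obj.position, obj.radius)
        if t is not None and (best_t is None or t < best_t):
            best_t = t
            best_color = _object_color(obj, origin + t * direction)
    if best_t is None:
        return BACKGROUND_COLOR, FAR_DEPTH
    return best_color, float(best_t)


def render_eye_latent(scene: Scene, agent: AgentState, eye_longitude_deg: float,
                      morph: MorphologicalGene) -> LatentScene:
    """Raycast the padded sharp latent image for one eye.

    One ray per latent column, spread over the eye's FOV (scaled up so the
    padded margin sees beyond the nominal FOV, as a wide-open pupil would);
    the single scanline is extruded to all latent rows. Depth is the hit
    distance per column.
    """
    hp, wp = latent_shape(morph.res_h, morph.res_w)
    fov = math.radians(morph.fov_deg) * (wp / max(morph.res_w, 1))
    center = agent.heading + math.radians(eye_longitude_deg)
    img = np.empty((hp, wp, 3))
    depth = np.empty((hp, wp))
    if wp == 1:
        angles = [center]
    else:
        angles = center + np.linspace(fov / 2, -fov / 2, wp)  # left-to-right
    for col, ang in enumerate(angles):
        color, dist = raycast(scene, agent.position, float(ang))
        img[:, col, :] = color
        depth[:, col] = dist
    return LatentScene(image=img, depth=depth)


# ---------------------------------------------------------------------------
# Serialization


def scene_to_json(scene: Scene) -> str:
    d = {
        "task": scene.spec.task.value,
        "seed": scene.seed,
        "start": scene.start.tolist(),
        "walls": [
            {"a": w.a.tolist(), "b": w.b.tolist(), "stripe_cycles": w.stripe_cycles}
            for w in scene.walls
        ],
        "objects": [
            {"kind": o.kind.value, "position": o.position.tolist(),
             "radius": o.radius, "pattern_stripes": o.pattern_stripes,
             "pattern_rotation_deg": o.pattern_rotation_deg,
             "heading": o.heading, "speed": o.speed}
            for o in scene.objects
        ],
    }
    return json.dumps(d, indent=1)


def scene_from_json(text: str, spec: TaskSpec) -> Scene:
    d = json.loads(text)
    walls = [Wall(np.array(w["a"]), np.array(w["b"]), w["stripe_cycles"])
             for w in d["walls"]]
    objects = [SceneObject(
        kind=ObjectKind(o["kind"]), position=np.array(o["position"]),
        radius=o["radius"], pattern_stripes=o["pattern_stripes"],
        pattern_rotation_deg=o["pattern_rotation_deg"],
        heading=o["heading"], speed=o["speed"]) for o in d["objects"]]
    return Scene(spec=spec, walls=walls, objects=objects,
                 start=np.array(d["start"]), seed=d.get("seed"))
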