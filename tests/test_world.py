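"""2D world: scene generation, kinematics, wall containment, raycast
rendering, respawn semantics."""

import numpy as np
import pytest

from eyevo.genome import MorphologicalGene
from eyevo.optics import latent_shape
from eyevo.world import (
    ObjectKind, Scene, SceneObject, Task, TaskSpec, Wall, build_task_scene,
    render_eye_latent, respawn_object, scene_from_json, scene_to_json,
    spawn_agent, step_dynamics, step_objects, AgentState, BACKGROUND_COLOR,
)


class TestSceneGeneration:
    def test_detection_scene_composition(self, rng):
        scene = build_task_scene(TaskSpec.detection(), rng)
        kinds = [o.kind for o in scene.objects]
        assert len(scene.objects) == 3
        assert kinds.count(ObjectKind.GOAL) == 1
        assert kinds.count(ObjectKind.ADVERSARY) == 2

    def test_goal_differs_only_by_pattern_rotation(self, rng):
        scene = build_task_scene(TaskSpec.detection(), rng)
        goal = next(o for o in scene.objects if o.kind is ObjectKind.GOAL)
        adv = next(o for o in scene.objects if o.kind is ObjectKind.ADVERSARY)
        assert goal.pattern_stripes == adv.pattern_stripes
        assert goal.radius == adv.radius
        assert goal.pattern_rotation_deg != adv.pattern_rotation_deg

    def test_tracking_objects_move(self, rng):
        scene = build_task_scene(TaskSpec.tracking(), rng)
        assert all(o.speed > 0 for o in scene.objects)
        headings = {o.heading for o in scene.objects}
        assert len(headings) > 1  # random headings

    def test_detection_objects_static(self, rng):
        scene = build_task_scene(TaskSpec.detection(), rng)
        assert all(o.speed == 0 for o in scene.objects)

    def test_deterministic_under_seed(self):
        s1 = build_task_scene(TaskSpec.detection(), np.random.default_rng(9))
        s2 = build_task_scene(TaskSpec.detection(), np.random.default_rng(9))
        assert scene_to_json(s1) == scene_to_json(s2)

    def test_navigation_maze_has_striped_walls(self, rng):
        scene = build_task_scene(TaskSpec.navigation(), rng)
        assert scene.objects == []
        assert all(w.stripe_cycles in (2, 4, 8) for w in scene.walls)
        assert len(scene.walls) > 10

    def test_scene_json_roundtrip(self, rng):
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, rng)
        back = scene_from_json(scene_to_json(scene), spec)
        assert scene_to_json(back) == scene_to_json(scene)


class TestDynamics:
    def test_zero_speed_is_stationary(self, rng):
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, rng)
        state = spawn_agent(scene)
        nxt, _ = step_dynamics(state, np.array([0.1, 0.0]), spec, scene)
        assert np.allclose(nxt.position, state.position)

    def test_forward_kinematics(self, rng):
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, rng)
        state = AgentState(position=np.zeros(2), heading=0.0)
        nxt, _ = step_dynamics(state, np.array([0.0, 1.0]), spec, scene)
        assert np.allclose(nxt.position, [0.1, 0.0])  # speed * dt along +x

    def test_wall_projection_and_contact(self):
        spec = TaskSpec.detection(arena_size=4.0)
        wall = Wall(np.array([1.0, -2.0]), np.array([1.0, 2.0]))
        scene = Scene(spec=spec, walls=[wall], objects=[],
                      start=np.zeros(2))
        state = AgentState(position=np.array([0.85, 0.0]), heading=0.0)
        nxt, ev = step_dynamics(state, np.array([0.0, 1.0]), spec, scene)
        assert ev.contact
        # projected back to the wall surface minus the body radius
        assert nxt.position[0] == pytest.approx(1.0 - 0.2)

    def test_goal_capture_event(self):
        spec = TaskSpec.detection()
        goal = SceneObject(ObjectKind.GOAL, np.array([0.55, 0.0]), 0.3, 8, 22.5)
        scene = Scene(spec=spec, walls=[], objects=[goal], start=np.zeros(2))
        state = AgentState(position=np.zeros(2), heading=0.0)
        nxt, ev = step_dynamics(state, np.array([0.0, 1.0]), spec, scene)
        assert ev.goal_captured and ev.captured_object is goal

    def test_arena_containment_long_rollout(self):
        """The agent can never leave the walled arena under random
        actions."""
        spec = TaskSpec.detection(arena_size=6.0)
        rng = np.random.default_rng(0)
        scene = build_task_scene(spec, rng)
        state = spawn_agent(scene)
        lim = spec.arena_size / 2
        for _ in range(100_000):
            a = np.array([rng.uniform(-0.3, 0.3), rng.uniform(0, 1)])
            state, _ = step_dynamics(state, a, spec, scene)
            assert np.all(np.abs(state.position) <= lim)


class TestTrackingObjects:
    def test_objects_advance_and_stay_inside(self, rng):
        spec = TaskSpec.tracking()
        scene = build_task_scene(spec, rng)
        before = [o.position.copy() for o in scene.objects]
        lim = spec.arena_size / 2
        for t in range(500):
            step_objects(scene, t, rng)
            for o in scene.objects:
                assert np.all(np.abs(o.position) <= lim)
        moved = [np.linalg.norm(o.position - b)
                 for o, b in zip(scene.objects, before)]
        assert all(m > 0 for m in moved)


class TestRenderer:
    def test_point_object_dead_ahead_is_central(self):
        spec = TaskSpec.detection()
        # stripe count 0 renders the sphere uniformly white
        obj = SceneObject(ObjectKind.GOAL, np.array([3.0, 0.0]), 0.1, 0, 0.0)
        scene = Scene(spec=spec, walls=[], objects=[obj], start=np.zeros(2))
        state = AgentState(position=np.zeros(2), heading=0.0)
        morph = MorphologicalGene(res_w=9, res_h=1, fov_deg=60.0)
        latent = render_eye_latent(scene, state, 0.0, morph)
        brightness = latent.image.sum(axis=2)[0]
        assert brightness.argmax() == latent.image.shape[1] // 2

    def test_object_outside_fov_invisible(self):
        spec = TaskSpec.detection()
        obj = SceneObject(ObjectKind.GOAL, np.array([-3.0, 0.0]), 0.3, 8, 0.0)
        scene = Scene(spec=spec, walls=[], objects=[obj], start=np.zeros(2))
        state = AgentState(position=np.zeros(2), heading=0.0)  # looking +x
        morph = MorphologicalGene(res_w=5, res_h=1, fov_deg=45.0)
        latent = render_eye_latent(scene, state, 0.0, morph)
        assert np.allclose(latent.image, np.broadcast_to(
            BACKGROUND_COLOR, latent.image.shape))

    def test_striped_wall_projection_period(self):
        """A wall with known stripe count maps to the predicted pixel
        period in the latent row."""
        spec = TaskSpec.detection()
        wall = Wall(np.array([2.0, -20.0]), np.array([2.0, 20.0]),
                    stripe_cycles=0)
        scene = Scene(spec=spec, walls=[wall], objects=[], start=np.zeros(2))
        state = AgentState(position=np.zeros(2), heading=0.0)
        morph = MorphologicalGene(res_w=15, res_h=1, fov_deg=60.0)
        latent = render_eye_latent(scene, state, 0.0, morph)
        # untextured wall: uniform wall color across the row, and depth
        # follows 2 / cos(angle) per column
        assert np.allclose(latent.image[0, :, 0], latent.image[0, 0, 0])
        wp = latent.image.shape[1]
        fov = np.radians(60.0) * wp / 15
        angles = np.linspace(fov / 2, -fov / 2, wp)
        assert np.allclose(latent.depth[0], 2.0 / np.cos(angles), rtol=1e-6)

    def test_goal_adversary_identical_up_to_rotation(self):
        """The discriminability premise: with the rotation offset removed,
        goal and adversary render pixel-identically."""
        spec = TaskSpec.detection()
        morph = MorphologicalGene(res_w=15, res_h=3, fov_deg=45.0)
        state = AgentState(position=np.zeros(2), heading=0.0)

        def latent_for(kind, rotation):
            obj = SceneObject(kind, np.array([2.0, 0.0]), 0.3, 8, rotation)
            scene = Scene(spec=spec, walls=[], objects=[obj],
                          start=np.zeros(2))
            return render_eye_latent(scene, state, 0.0, morph)

        goal = latent_for(ObjectKind.GOAL, 22.5)
        adv_same_rot = latent_for(ObjectKind.ADVERSARY, 22.5)
        adv = latent_for(ObjectKind.ADVERSARY, 0.0)
        assert np.array_equal(goal.image, adv_same_rot.image)
        assert not np.array_equal(goal.image, adv.image)

    def test_rendering_deterministic(self, rng):
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, rng)
        state = spawn_agent(scene)
        morph = MorphologicalGene(res_w=7, res_h=2, fov_deg=45.0)
        a = render_eye_latent(scene, state, 10.0, morph)
        b = render_eye_latent(scene, state, 10.0, morph)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.depth, b.depth)

    def test_latent_shape_matches_contract(self):
        morph = MorphologicalGene(res_w=15, res_h=15, fov_deg=45.0)
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, np.random.default_rng(0))
        latent = render_eye_latent(scene, spawn_agent(scene), 0.0, morph)
        assert latent.image.shape[:2] == latent_shape(15, 15) == (31, 31)


class TestRespawn:
    def test_respawn_keeps_object_count(self, rng):
        spec = TaskSpec.detection()
        scene = build_task_scene(spec, rng)
        agent = spawn_agent(scene)
        goal = next(o for o in scene.objects if o.kind is ObjectKind.GOAL)
        old_pos = goal.position.copy()
        respawn_object(scene, goal, agent, rng)
        assert len(scene.objects) == 3
        assert not np.allclose(goal.position, old_pos)
        assert np.linalg.norm(goal.position - agent.position) >= 2.0

    def test_respawn_reproducible(self, rng):
        spec = TaskSpec.detection()
        scene1 = build_task_scene(spec, np.random.default_rng(4))
        scene2 = build_task_scene(spec, np.random.default_rng(4))
        a1, a2 = spawn_agent(scene1), spawn_agent(scene2)
        g1 = scene1.objects[0]
        g2 = scene2.objects[0]
        respawn_object(scene1, g1, a1, np.random.default_rng(8))
        respawn_object(scene2, g2, a2, np.random.default_rng(8))
        assert np.array_equal(g1.position, g2.position)
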