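"""Heritable encoding of an agent's visual system.

A genotype bundles three independently mutable gene clusters:

* **morphological** — how the environment is spatially sampled: number of
  eyes, the angular span they are placed over, per-eye field of view, and
  photoreceptor resolution;
* **optical** — how each eye interacts with light: a programmable 4x4 phase
  mask (a diffractive surface height map), refractive index, and pupil
  aperture fraction;
* **neural** — learning capacity: hidden-layer width of the policy network
  and the depth of the temporal frame-stacking memory.

Eyes sit on the equator of a fixed-radius spherical body, bilaterally
symmetric about the forward heading. Mutation is Gaussian for continuous
fields and unit-step for integer fields, always clamped to bounds. A codec
maps masked-in fields to a flat vector normalized to the unit cube for the
evolutionary optimizer; integers travel as continuous values and are rounded
on decode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "AGENT_RADIUS",
    "GENE_BOUNDS",
    "WorldConstants",
    "MorphologicalGene",
    "OpticalGene",
    "NeuralGene",
    "Genotype",
    "MutationMask",
    "compute_eye_placements",
    "eye_footprint_deg",
    "validate_genotype",
    "repair_genotype",
    "mutate",
    "GenotypeCodec",
    "primitive_genotype",
    "random_genotype",
    "save_genotypes",
    "load_genotypes",
]

AGENT_RADIUS = 0.2  # body radius, world units; fixed across all experiments

#: (low, high) bounds per gene field. Integer fields use inclusive integer
#: bounds. memory_frames has no stated upper bound; 16 is the configured cap.
GENE_BOUNDS = {
    "num_eyes": (1, 16),
    "placement_range_deg": (1.0, 180.0),
    "fov_deg": (1.0, 100.0),
    "res_w": (1, 16),
    "res_h": (1, 16),
    "phase_mask": (0.0, 1.0),
    "refractive_index": (1.0, 2.0),
    "aperture_fraction": (0.0, 1.0),
    "hidden_neurons": (1, 512),
    "memory_frames": (0, 16),
}

_INTEGER_FIELDS = {"num_eyes", "res_w", "res_h", "hidden_neurons", "memory_frames"}


@dataclass(frozen=True)
class WorldConstants:
    """Physical constants shared by validation and imaging.

    sensor_size is the side length L of each eye's sensor plane; together
    with the body radius it fixes the angular footprint one eye occupies on
    the equator, which drives the no-overlap placement rule.
    """

    sensor_size: float = 0.05
    agent_radius: float = AGENT_RADIUS


@dataclass
class MorphologicalGene:
    num_eyes: int = 1
    placement_range_deg: float = 90.0
    fov_deg: float = 45.0
    res_w: int = 1
    res_h: int = 1


@dataclass
class OpticalGene:
    phase_mask: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    refractive_index: float = 1.5
    aperture_fraction: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        self.phase_mask = np.asarray(self.phase_mask, dtype=float)
        if self.phase_mask.shape != (4, 4):
            raise ValueError("phase_mask must be 4x4")


@dataclass
class NeuralGene:
    hidden_neurons: int = 32
    memory_frames: int = 1


@dataclass
class Genotype:
    morph: MorphologicalGene = field(default_factory=MorphologicalGene)
    optics: OpticalGene = field(default_factory=OpticalGene)
    neural: NeuralGene = field(default_factory=NeuralGene)
    agent_radius: float = AGENT_RADIUS

    def copy(self) -> "Genotype":
        return Genotype(
            morph=replace(self.morph),
            optics=OpticalGene(
                phase_mask=self.optics.phase_mask.copy(),
                refractive_index=self.optics.refractive_index,
                aperture_fraction=self.optics.aperture_fraction,
                enabled=self.optics.enabled,
            ),
            neural=replace(self.neural),
            agent_radius=self.agent_radius,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optics"]["phase_mask"] = self.optics.phase_mask.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Genotype":
        return cls(
            morph=MorphologicalGene(**d["morph"]),
            optics=OpticalGene(
                phase_mask=np.asarray(d["optics"]["phase_mask"], dtype=float),
                refractive_index=d["optics"]["refractive_index"],
                aperture_fraction=d["optics"]["aperture_fraction"],
                enabled=d["optics"]["enabled"],
            ),
            neural=NeuralGene(**d["neural"]),
            agent_radius=d.get("agent_radius", AGENT_RADIUS),
        )


@dataclass(frozen=True)
class MutationMask:
    """Which gene fields an experiment is allowed to mutate.

    res_axis selects whether photoreceptor growth acts on the horizontal
    width only (the essentially two-dimensional navigation task) or on both
    axes together (square growth, as in detection).
    """

    allow_num_eyes: bool = False
    allow_res: bool = False
    allow_placement: bool = False
    allow_fov: bool = False
    allow_phase_mask: bool = False
    allow_aperture: bool = False
    allow_refractive_index: bool = False
    allow_neurons: bool = False
    allow_memory: bool = False
    res_axis: str = "both"  # "width-only" | "both"

    def __post_init__(self) -> None:
        if self.res_axis not in ("width-only", "both"):
            raise ValueError("res_axis must be 'width-only' or 'both'")

    def any_enabled(self) -> bool:
        return any(
            getattr(self, f)
            for f in (
                "allow_num_eyes", "allow_res", "allow_placement", "allow_fov",
                "allow_phase_mask", "allow_aperture", "allow_refractive_index",
                "allow_neurons", "allow_memory",
            )
        )

    @classmethod
    def morphology(cls, res_axis: str = "both") -> "MutationMask":
        return cls(allow_num_eyes=True, allow_res=True, allow_placement=True,
                   res_axis=res_axis)

    @classmethod
    def optics_only(cls) -> "MutationMask":
        return cls(allow_phase_mask=True, allow_aperture=True,
                   allow_refractive_index=True)

    @classmethod
    def aperture_only(cls) -> "MutationMask":
        return cls(allow_aperture=True)

    @classmethod
    def neural(cls) -> "MutationMask":
        return cls(allow_neurons=True, allow_memory=True)


def compute_eye_placements(num_eyes: int, placement_range_deg: float) -> list[float]:
    """Equatorial eye longitudes (degrees), bilaterally symmetric about 0.

    Eyes are uniformly distributed across the placement span centered on the
    forward heading: three eyes over a 90 degree range sit at -45, 0, +45; a
    20 degree range pulls them in to -10, 0, +10. A single eye looks dead
    ahead.
    """
    if num_eyes < 1:
        raise ValueError(f"num_eyes must be >= 1, got {num_eyes}")
    if not 0 < placement_range_deg <= 180:
        raise ValueError(
            f"placement_range_deg must be in (0, 180], got {placement_range_deg}")
    if num_eyes == 1:
        return [0.0]
    half = placement_range_deg / 2.0
    return list(np.linspace(-half, half, num_eyes))


def eye_footprint_deg(wc: WorldConstants) -> float:
    """Angular footprint (degrees) one eye occupies on the body equator.

    A sensor of side L mounted on a body of radius R subtends a chord of
    length L; adjacent eyes must be at least this far apart to not overlap.
    """
    ratio = min(1.0, wc.sensor_size / (2.0 * wc.agent_radius))
    return math.degrees(2.0 * math.asin(ratio))


def validate_genotype(
    g: Genotype, wc: WorldConstants | None = None
) -> tuple[bool, list[str]]:
    """Bound and geometry checks; returns (valid, violations)."""
    wc = wc or WorldConstants()
    v: list[str] = []
    m, o, n = g.morph, g.optics, g.neural

    def _chk(name: str, val: float) -> None:
        lo, hi = GENE_BOUNDS[name]
        if not lo <= val <= hi:
            op = "<" if val < lo else ">"
            bound = lo if val < lo else hi
            v.append(f"{name} {op} {bound}")

    _chk("num_eyes", m.num_eyes)
    _chk("placement_range_deg", m.placement_range_deg)
    _chk("fov_deg", m.fov_deg)
    _chk("res_w", m.res_w)
    _chk("res_h", m.res_h)
    for name, val in (("num_eyes", m.num_eyes), ("res_w", m.res_w),
                      ("res_h", m.res_h), ("hidden_neurons", n.hidden_neurons),
                      ("memory_frames", n.memory_frames)):
        if val != int(val):
            v.append(f"{name} not an integer")
    if np.any(o.phase_mask < 0) or np.any(o.phase_mask > 1):
        v.append("phase_mask entries outside [0, 1]")
    _chk("refractive_index", o.refractive_index)
    _chk("aperture_fraction", o.aperture_fraction)
    _chk("hidden_neurons", n.hidden_neurons)
    _chk("memory_frames", n.memory_frames)
    if g.agent_radius != AGENT_RADIUS:
        v.append(f"agent_radius != {AGENT_RADIUS}")

    # Adjacent-eye overlap: uniform spacing along the placement span must be
    # at least one eye footprint.
    if m.num_eyes >= 2 and 0 < m.placement_range_deg <= 180:
        spacing = m.placement_range_deg / (m.num_eyes - 1)
        if spacing < eye_footprint_deg(wc):
            v.append(
                f"eye overlap: spacing {spacing:.3g} deg < footprint "
                f"{eye_footprint_deg(wc):.3g} deg")
    return (len(v) == 0, v)


def repair_genotype(g: Genotype, wc: WorldConstants | None = None) -> Genotype:
    """Clamp all fields into bounds and shed eyes until placements fit."""
    wc = wc or WorldConstants()
    g = g.copy()
    m, o, n = g.morph, g.optics, g.neural

    def _clamp(name: str, val: float) -> float:
        lo, hi = GENE_BOUNDS[name]
        return min(max(val, lo), hi)

    m.num_eyes = int(round(_clamp("num_eyes", m.num_eyes)))
    m.placement_range_deg = _clamp("placement_range_deg", m.placement_range_deg)
    m.fov_deg = _clamp("fov_deg", m.fov_deg)
    m.res_w = int(round(_clamp("res_w", m.res_w)))
    m.res_h = int(round(_clamp("res_h", m.res_h)))
    o.phase_mask = np.clip(o.phase_mask, 0.0, 1.0)
    o.refractive_index = _clamp("refractive_index", o.refractive_index)
    o.aperture_fraction = _clamp("aperture_fraction", o.aperture_fraction)
    n.hidden_neurons = int(round(_clamp("hidden_neurons", n.hidden_neurons)))
    n.memory_frames = int(round(_clamp("memory_frames", n.memory_frames)))
    g.agent_radius = AGENT_RADIUS

    fp = eye_footprint_deg(wc)
    while m.num_eyes >= 2 and m.placement_range_deg / (m.num_eyes - 1) < fp:
        m.num_eyes -= 1
    return g


def mutate(
    g: Genotype,
    mask: MutationMask,
    rng: np.random.Generator,
    sigma_frac: float = 0.10,
    wc: WorldConstants | None = None,
) -> Genotype:
    """One mutation event.

    Continuous fields receive Gaussian perturbations with sigma equal to
    ``sigma_frac`` of the field's range, clamped at the bounds. Integer
    fields take a single +1/-1 step with equal probability, respecting
    bounds. Bilateral symmetry is structural (placements always derive from
    the placement range), and the result is repaired to validity.
    """
    wc = wc or WorldConstants()
    out = g.copy()
    m, o, n = out.morph, out.optics, out.neural

    def _gauss(name: str, val: float) -> float:
        lo, hi = GENE_BOUNDS[name]
        return float(np.clip(val + rng.normal(0.0, sigma_frac * (hi - lo)), lo, hi))

    def _step(name: str, val: int) -> int:
        lo, hi = GENE_BOUNDS[name]
        return int(np.clip(val + (1 if rng.random() < 0.5 else -1), lo, hi))

    if mask.allow_num_eyes:
        m.num_eyes = _step("num_eyes", m.num_eyes)
    if mask.allow_res:
        if mask.res_axis == "width-only":
            m.res_w = _step("res_w", m.res_w)
        else:
            delta = 1 if rng.random() < 0.5 else -1
            lo, hi = GENE_BOUNDS["res_w"]
            m.res_w = int(np.clip(m.res_w + delta, lo, hi))
            lo, hi = GENE_BOUNDS["res_h"]
            m.res_h = int(np.clip(m.res_h + delta, lo, hi))
    if mask.allow_placement:
        m.placement_range_deg = _gauss("placement_range_deg", m.placement_range_deg)
    if mask.allow_fov:
        m.fov_deg = _gauss("fov_deg", m.fov_deg)
    if mask.allow_phase_mask:
        lo, hi = GENE_BOUNDS["phase_mask"]
        o.phase_mask = np.clip(
            o.phase_mask + rng.normal(0.0, sigma_frac * (hi - lo), size=(4, 4)),
            lo, hi)
    if mask.allow_aperture:
        o.aperture_fraction = _gauss("aperture_fraction", o.aperture_fraction)
    if mask.allow_refractive_index:
        o.refractive_index = _gauss("refractive_index", o.refractive_index)
    if mask.allow_neurons:
        n.hidden_neurons = _step("hidden_neurons", n.hidden_neurons)
    if mask.allow_memory:
        n.memory_frames = _step("memory_frames", n.memory_frames)

    return repair_genotype(out, wc)


# ---------------------------------------------------------------------------
# Optimizer codec


class GenotypeCodec:
    """Maps masked-in gene fields to/from a flat vector on the unit cube.

    Field order is fixed per mask so that ``decode(encode(g)) == g`` for all
    valid genotypes: integers are normalized exactly and rounded back on
    decode. The vector is what the evolutionary optimizer sees; decoded
    genotypes are repaired (clamped, de-overlapped) before evaluation.
    """

    def __init__(self, mask: MutationMask, template: Genotype,
                 wc: WorldConstants | None = None):
        self.mask = mask
        self.template = template.copy()
        self.wc = wc or WorldConstants()
        self._fields: list[str] = []
        if mask.allow_num_eyes:
            self._fields.append("num_eyes")
        if mask.allow_res:
            self._fields.append("res_w")
            if mask.res_axis == "both":
                self._fields.append("res_h")
        if mask.allow_placement:
            self._fields.append("placement_range_deg")
        if mask.allow_fov:
            self._fields.append("fov_deg")
        if mask.allow_phase_mask:
            self._fields.extend(f"phase_{i}" for i in range(16))
        if mask.allow_refractive_index:
            self._fields.append("refractive_index")
        if mask.allow_aperture:
            self._fields.append("aperture_fraction")
        if mask.allow_neurons:
            self._fields.append("hidden_neurons")
        if mask.allow_memory:
            self._fields.append("memory_frames")

    @property
    def dim(self) -> int:
        return len(self._fields)

    @staticmethod
    def _bounds(name: str) -> tuple[float, float]:
        return GENE_BOUNDS["phase_mask" if name.startswith("phase_") else name]

    def _get(self, g: Genotype, name: str) -> float:
        if name.startswith("phase_"):
            return float(g.optics.phase_mask.flat[int(name[6:])])
        for cluster in (g.morph, g.optics, g.neural):
            if hasattr(cluster, name):
                return float(getattr(cluster, name))
        raise KeyError(name)

    def _set(self, g: Genotype, name: str, val: float) -> None:
        if name.startswith("phase_"):
            g.optics.phase_mask.flat[int(name[6:])] = val
            return
        for cluster in (g.morph, g.optics, g.neural):
            if hasattr(cluster, name):
                base = "phase_mask" if name.startswith("phase_") else name
                if base in _INTEGER_FIELDS:
                    val = int(round(val))
                setattr(cluster, name, val)
                return
        raise KeyError(name)

    def encode(self, g: Genotype) -> np.ndarray:
        x = np.empty(self.dim)
        for i, name in enumerate(self._fields):
            lo, hi = self._bounds(name)
            x[i] = (self._get(g, name) - lo) / (hi - lo)
        return x

    def decode(self, x: np.ndarray, repair: bool = True) -> Genotype:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(
                f"codec expects vector of length {self.dim}, got shape {x.shape}")
        g = self.template.copy()
        for i, name in enumerate(self._fields):
            lo, hi = self._bounds(name)
            self._set(g, name, lo + float(np.clip(x[i], 0.0, 1.0)) * (hi - lo))
        return repair_genotype(g, self.wc) if repair else g


# ---------------------------------------------------------------------------
# Convenience constructors and archive I/O


def primitive_genotype() -> Genotype:
    """The ancestral agent: one eye, one photoreceptor, 45-degree FOV."""
    return Genotype(
        morph=MorphologicalGene(num_eyes=1, placement_range_deg=90.0,
                                fov_deg=45.0, res_w=1, res_h=1),
        optics=OpticalGene(phase_mask=np.zeros((4, 4)), refractive_index=1.5,
                           aperture_fraction=1.0, enabled=True),
        neural=NeuralGene(hidden_neurons=32, memory_frames=1),
    )


def random_genotype(rng: np.random.Generator,
                    wc: WorldConstants | None = None) -> Genotype:
    """A random valid genotype, uniform over bounds then repaired."""
    def u(name):
        lo, hi = GENE_BOUNDS[name]
        return rng.uniform(lo, hi)

    def ui(name):
        lo, hi = GENE_BOUNDS[name]
        return int(rng.integers(lo, hi + 1))

    g = Genotype(
        morph=MorphologicalGene(
            num_eyes=ui("num_eyes"), placement_range_deg=u("placement_range_deg"),
            fov_deg=u("fov_deg"), res_w=ui("res_w"), res_h=ui("res_h")),
        optics=OpticalGene(
            phase_mask=rng.uniform(0, 1, size=(4, 4)),
            refractive_index=u("refractive_index"),
            aperture_fraction=u("aperture_fraction"), enabled=True),
        neural=NeuralGene(hidden_neurons=ui("hidden_neurons"),
                          memory_frames=ui("memory_frames")),
    )
    return repair_genotype(g, wc)


_SCHEMA_VERSION = 1


def save_genotypes(path, genotypes, provenance=None) -> None:
    """Write a JSON genotype archive (one record per genotype)."""
    provenance = provenance or [{}] * len(genotypes)
    records = [
        {"schema_version": _SCHEMA_VERSION, "genotype": g.to_dict(), **meta}
        for g, meta in zip(genotypes, provenance)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_genotypes(path) -> list[Genotype]:
    with open(path) as fh:
        records = json.load(fh)
    return [Genotype.from_dict(r["genotype"]) for r in records]
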