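"""Synthetic two-channel phantom volumes.

Generates the geometric test objects used to validate colocalisation
visualisation: solid spheres and finite cylinders whose intensity is maximal
at the centre (or on the axis) and falls off linearly towards the surface,
mimicking the intensity profile of fluorescently labelled vesicles and
filaments.  Three preset scenes cover the canonical cases: two perfectly
overlapping identical cylinders, two partially overlapping spheres, and a
slightly overlapping cylinder and sphere.

Coordinates are 0-based ``(z, y, x)`` array indices and distances are in
isotropic voxel units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import tifffile
import yaml

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "ChannelPair",
    "render_phantom",
    "build_scene",
    "preset_scenes",
    "scene_to_yaml",
    "scene_from_yaml",
    "write_scene_tiffs",
]


@dataclass
class ChannelPair:
    """Two aligned 3D intensity grids plus the intensity ceiling ``i_max``."""

    ch1: np.ndarray
    ch2: np.ndarray
    i_max: float

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1)
        self.ch2 = np.asarray(self.ch2)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ch1.shape


@dataclass
class PhantomSpec:
    """One geometric primitive: a solid sphere or a finite cylinder.

    Intensity is ``peak_intensity * (1 - r / radius)`` for ``r < radius``
    (``r`` = distance to the centre, or to the axis for cylinders) and zero
    outside.  Cylinders are additionally cut off beyond ``length / 2`` along
    the axis.
    """

    shape_kind: str  # "sphere" | "cylinder"
    center: tuple[float, float, float]  # (z, y, x), voxels
    radius: float
    peak_intensity: float
    axis: tuple[float, float, float] | None = None  # cylinders only, unit vector
    length: float | None = None  # cylinders only, voxels

    def __post_init__(self) -> None:
        if self.shape_kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.peak_intensity <= 0:
            raise ValueError("peak_intensity must be > 0")
        if self.shape_kind == "cylinder":
            if self.axis is None or self.length is None:
                raise ValueError("cylinders need an axis and a length")
            a = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(a)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError("axis must have unit norm")
            if self.length <= 0:
                raise ValueError("length must be > 0")


@dataclass
class PhantomScene:
    """A full two-channel scene: per-channel primitive lists plus noise."""

    grid_shape: tuple[int, int, int]  # (z, y, x)
    channel1_specs: list[PhantomSpec] = field(default_factory=list)
    channel2_specs: list[PhantomSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    bit_depth: int = 8  # 8 or 16

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def i_max(self) -> int:
        return (1 << self.bit_depth) - 1


def _extent_outside_grid(spec: PhantomSpec, grid_shape) -> bool:
    c = np.asarray(spec.center, dtype=float)
    if spec.shape_kind == "sphere":
        reach = np.full(3, spec.radius)
    else:
        a = np.abs(np.asarray(spec.axis, dtype=float))
        # Per-axis half-extent of a finite cylinder's bounding box.
        reach = a * spec.length / 2 + spec.radius * np.sqrt(np.clip(1 - a**2, 0, 1))
    return bool(np.any(c - reach < -0.5) or np.any(c + reach > np.asarray(grid_shape) - 0.5))


def render_phantom(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int],
    i_max: float = 255.0,
) -> np.ndarray:
    """Rasterise one primitive onto a float grid with linear radial falloff.

    Voxel value is ``peak * (1 - r/radius)`` inside the structure and 0
    outside; values are clipped to ``[0, i_max]``.  Structures extending past
    the grid edge are clipped silently (a warning is emitted).
    """
    if _extent_outside_grid(spec, grid_shape):
        warnings.warn(
            "phantom extends outside the grid and will be clipped at the edge",
            stacklevel=2,
        )
    zz, yy, xx = np.indices(grid_shape, dtype=float)
    c = np.asarray(spec.center, dtype=float)
    dv = np.stack([zz - c[0], yy - c[1], xx - c[2]])  # (3, z, y, x)

    if spec.shape_kind == "sphere":
        r = np.sqrt((dv**2).sum(axis=0))
        inside = r < spec.radius
    else:
        a = np.asarray(spec.axis, dtype=float)
        axial = np.tensordot(a, dv, axes=1)  # signed distance along the axis
        radial_vec = dv - a[:, None, None, None] * axial
        r = np.sqrt((radial_vec**2).sum(axis=0))
        inside = (r < spec.radius) & (np.abs(axial) <= spec.length / 2)

    vol = np.where(inside, spec.peak_intensity * (1.0 - r / spec.radius), 0.0)
    return np.clip(vol, 0.0, i_max)


def build_scene(scene: PhantomScene) -> ChannelPair:
    """Render a scene to a quantized two-channel volume.

    Each channel is the voxel-wise maximum over its primitives, optionally
    perturbed by seeded zero-mean Gaussian noise, clipped to ``[0, i_max]``
    and rounded to the scene's bit depth.
    """
    i_max = float(scene.i_max)
    channels = []
    rng = np.random.default_rng(scene.seed)
    for specs in (scene.channel1_specs, scene.channel2_specs):
        if specs:
            vol = np.maximum.reduce(
                [render_phantom(s, scene.grid_shape, i_max) for s in specs]
            )
        else:
            vol = np.zeros(scene.grid_shape, dtype=float)
        if scene.noise_sd > 0:
            vol = vol + rng.normal(0.0, scene.noise_sd, size=scene.grid_shape)
        vol = np.clip(vol, 0.0, i_max)
        dtype = np.uint8 if scene.bit_depth == 8 else np.uint16
        channels.append(np.rint(vol).astype(dtype))
    return ChannelPair(ch1=channels[0], ch2=channels[1], i_max=i_max)


def preset_scenes() -> dict[str, PhantomScene]:
    """The three canonical noise-free scenes on a 64x64x64 grid.

    ``overlapping_cylinders``
        Identical cylinder in both channels — perfect positive correlation;
        models two co-labelled filaments.
    ``partial_spheres``
        Two spheres of radius 16 whose centres are 8 voxels (half a radius)
        apart — a substantial lens-shaped overlap within which the joint
        intensities are positively correlated; models vesicle fusion.
    ``cylinder_sphere``
        A cylinder and a sphere that barely touch — only a small contact
        region is co-occupied; models a vesicle docking onto a filament.
    """
    grid = (64, 64, 64)
    cyl = PhantomSpec(
        shape_kind="cylinder",
        center=(32.0, 32.0, 32.0),
        radius=10.0,
        peak_intensity=255.0,
        axis=(0.0, 0.0, 1.0),
        length=48.0,
    )
    sphere_a = PhantomSpec("sphere", (32.0, 32.0, 28.0), 16.0, 255.0)
    sphere_b = PhantomSpec("sphere", (32.0, 32.0, 36.0), 16.0, 255.0)
    thin_cyl = PhantomSpec(
        shape_kind="cylinder",
        center=(32.0, 32.0, 20.0),
        radius=8.0,
        peak_intensity=255.0,
        axis=(0.0, 1.0, 0.0),
        length=48.0,
    )
    lone_sphere = PhantomSpec("sphere", (32.0, 32.0, 38.0), 12.0, 255.0)
    return {
        "overlapping_cylinders": PhantomScene(
            grid_shape=grid, channel1_specs=[cyl], channel2_specs=[replace(cyl)]
        ),
        "partial_spheres": PhantomScene(
            grid_shape=grid, channel1_specs=[sphere_a], channel2_specs=[sphere_b]
        ),
        "cylinder_sphere": PhantomScene(
            grid_shape=grid, channel1_specs=[thin_cyl], channel2_specs=[lone_sphere]
        ),
    }


# -- scene (de)serialisation --------------------------------------------------

def scene_to_dict(scene: PhantomScene) -> dict:
    d = asdict(scene)
    d["grid_shape"] = list(scene.grid_shape)
    return d


def scene_from_dict(d: dict) -> PhantomScene:
    def _spec(sd: dict) -> PhantomSpec:
        sd = dict(sd)
        sd["center"] = tuple(sd["center"])
        if sd.get("axis") is not None:
            sd["axis"] = tuple(sd["axis"])
        return PhantomSpec(**sd)

    return PhantomScene(
        grid_shape=tuple(d["grid_shape"]),
        channel1_specs=[_spec(s) for s in d.get("channel1_specs", [])],
        channel2_specs=[_spec(s) for s in d.get("channel2_specs", [])],
        noise_sd=d.get("noise_sd", 0.0),
        seed=d.get("seed", 0),
        bit_depth=d.get("bit_depth", 8),
    )


def scene_to_yaml(scene: PhantomScene, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh, sort_keys=False)


def scene_from_yaml(path) -> PhantomScene:
    with open(path) as fh:
        return scene_from_dict(yaml.safe_load(fh))


def write_scene_tiffs(scene: PhantomScene, out_dir, stem: str = "phantom") -> dict:
    """Write per-channel multi-page grayscale TIFFs plus a JSON manifest.

    Returns the manifest dict (also written to ``<stem>_manifest.json``).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = build_scene(scene)
    paths = {}
    for name, vol in (("ch1", pair.ch1), ("ch2", pair.ch2)):
        p = out / f"{stem}_{name}.tif"
        tifffile.imwrite(p, vol, photometric="minisblack")
        paths[name] = p.name
    manifest = {"scene": scene_to_dict(scene), "files": paths, "i_max": pair.i_max}
    with open(out / f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
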