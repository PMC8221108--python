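"""Seeded synthetic z-stacks with known ground truth.

Real acquisitions of cleared dorsal root ganglia (DRG) and sciatic nerve
contain three populations of bright structure on top of a diffuse
autofluorescent tissue envelope: the labeled immune cells of interest
(macrophage-scale, roughly ellipsoidal), much larger neuron somata that
also pick up signal, and sub-resolution speck artifacts.  This module
renders all four as solid geometry with Poisson/Gaussian noise so that
every downstream stage — segmentation, voxel-count filtering,
morphometry, group statistics — can be validated against exact ground
truth.

Cells are solid triaxial ellipsoids of uniform interior intensity.
Real macrophages are irregular, ramified bodies; the simplification is
deliberate, because the shape descriptors measured downstream
(sphericity, prolate and oblate ellipticity) are exactly the ellipsoid
family, so an ellipsoid phantom gives closed-form expected values for
every measurement.

None of the numeric defaults below (cell density, axis ranges,
intensities, noise level) are taken from any measured dataset; they are
chosen to be plausible for macrophages at multiphoton resolution and are
free parameters of the generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, SEXES, SIDES, ImageStack, SampleMetadata

__all__ = [
    "SceneSpec",
    "ObjectRecord",
    "GroundTruth",
    "GroupEffect",
    "CohortDesign",
    "CohortSample",
    "PlacementError",
    "ConfigError",
    "AXIS_RANGES_UM",
    "sample_cell_axes",
    "generate_stack",
    "generate_cohort",
    "ellipsoid_volume",
]


class PlacementError(RuntimeError):
    """Raised when a scene cannot be populated without overlaps."""


class ConfigError(ValueError):
    """Raised for an unknown group key or malformed cohort design."""


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Analytic volume (4/3)π·a·b·c of a solid ellipsoid, µm³."""
    return 4.0 / 3.0 * np.pi * a * b * c


#: Semi-axis sampling ranges in µm per shape mode, as ((a_lo, a_hi), (b..), (c..)).
#: "balanced" is near-spherical resting morphology; "prolate" is the
#: elongated (M2-like) morphology; "oblate" the flattened (M1-like) one.
AXIS_RANGES_UM = {
    "balanced": ((3.0, 5.0), (3.5, 5.5), (4.0, 6.0)),
    "prolate": ((2.0, 3.5), (2.0, 4.0), (8.0, 14.0)),
    "oblate": ((2.0, 3.0), (5.0, 7.0), (6.0, 9.0)),
}


def sample_cell_axes(rng: np.random.Generator, mode: str = "balanced") -> tuple[float, float, float]:
    """Draw one sorted semi-axis triple (a ≤ b ≤ c) in µm for a cell."""
    try:
        ranges = AXIS_RANGES_UM[mode]
    except KeyError:
        raise ConfigError(f"unknown shape mode {mode!r}; known: {sorted(AXIS_RANGES_UM)}")
    axes = sorted(rng.uniform(lo, hi) for lo, hi in ranges)
    return (axes[0], axes[1], axes[2])


@dataclass
class SceneSpec:
    """Complete, seed-deterministic description of one synthetic stack.

    ``stack_shape`` and ``voxel_size`` are (z, y, x).  The default grid is
    128×128 in-plane × 64 slices at (1.0, 0.5, 0.5) µm — the acquisition
    anisotropy of a 0.5 µm xy pixel and 1 µm z step — kept desk-scale;
    full 512×512×300+ stacks are supported, just not the default.
    """

    stack_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)
    n_cells: int = 15
    shape_mode: str = "balanced"
    cell_axes: Sequence[tuple[float, float, float]] | None = None
    cell_intensity: float = 150.0
    n_neuron_blobs: int = 0
    neuron_min_volume: float = 7000.0  # µm³; soma-scale, far above any cell
    n_artifacts: int = 0
    artifact_max_voxels: int = 10
    tissue_envelope: tuple[float, float, float] | None = None  # semi-axes µm, None = auto
    background_intensity: float = 20.0
    psf_sigma_um: float = 0.0  # optical blur; 0 keeps geometry oracles exact
    noise_sd: float = 4.0
    poisson_noise: bool = False
    seed: int = 0
    max_place_attempts: int = 1000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stack_shape):
            raise ValueError("stack_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.cell_axes is not None and len(self.cell_axes) != self.n_cells:
            raise ValueError("cell_axes, when given, must list one triple per cell")

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size of the stack per axis (z, y, x), µm."""
        return tuple(s * v for s, v in zip(self.stack_shape, self.voxel_size))

    def envelope_semi_axes(self) -> tuple[float, float, float]:
        """Tissue-envelope semi-axes; default 85% of the half-extent per axis."""
        if self.tissue_envelope is not None:
            return tuple(float(v) for v in self.tissue_envelope)
        return tuple(0.85 * e / 2 for e in self.physical_extent)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["cell_axes"] is not None:
            d["cell_axes"] = [list(t) for t in d["cell_axes"]]
        return d


@dataclass
class ObjectRecord:
    """Ground truth for one rendered object."""

    object_id: int
    klass: str  # "cell" | "neuron" | "artifact"
    centroid_um: tuple[float, float, float]  # (z, y, x)
    semi_axes_um: tuple[float, float, float]  # (a, b, c), a ≤ b ≤ c
    orientation: np.ndarray  # rows = principal axes in (z, y, x) coords
    volume_um3: float
    n_voxels: int


@dataclass
class GroundTruth:
    """All rendered objects plus the analytic tissue volume of the scene."""

    objects: list[ObjectRecord]
    tissue_volume_um3: float
    tissue_voxels: int

    def cells(self) -> list[ObjectRecord]:
        return [o for o in self.objects if o.klass == "cell"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.objects:
            row = {
                "object_id": o.object_id,
                "class": o.klass,
                "centroid_z_um": o.centroid_um[0],
                "centroid_y_um": o.centroid_um[1],
                "centroid_x_um": o.centroid_um[2],
                "axis_a_um": o.semi_axes_um[0],
                "axis_b_um": o.semi_axes_um[1],
                "axis_c_um": o.semi_axes_um[2],
                "volume_um3": o.volume_um3,
                "n_voxels": o.n_voxels,
            }
            for i in range(3):
                for j in range(3):
                    row[f"orient_{i}{j}"] = o.orientation[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3×3 rotation (QR of a Gaussian matrix, sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _rasterize_ellipsoid(
    grid: np.ndarray,
    voxel_size: Sequence[float],
    center_um: Sequence[float],
    semi_axes: Sequence[float],
    rotation: np.ndarray,
) -> np.ndarray:
    """Voxel indices (N×3 int) inside the ellipsoid, restricted to the grid.

    A voxel belongs to the ellipsoid when its centre, mapped into the
    ellipsoid frame, satisfies Σ (p_i/axis_i)² ≤ 1.  Only the bounding
    box of the ellipsoid is scanned.
    """
    vs = np.asarray(voxel_size, dtype=float)
    c = np.asarray(center_um, dtype=float)
    r_max = float(np.max(semi_axes))
    lo = np.maximum(np.floor((c - r_max) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((c + r_max) / vs).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    p = idx * vs - c  # voxel centres relative to ellipsoid centre, µm
    local = p @ rotation.T  # into principal frame
    q = np.sum((local / np.asarray(semi_axes)) ** 2, axis=1)
    return idx[q <= 1.0]


def _inside_envelope(point: np.ndarray, center: np.ndarray, env_axes: np.ndarray, margin_um: float) -> bool:
    """True if `point` lies in the envelope shrunk by `margin_um` per axis."""
    shrunk = np.maximum(env_axes - margin_um, 1e-6)
    return float(np.sum(((point - center) / shrunk) ** 2)) <= 1.0


def _place_objects(
    rng: np.random.Generator,
    spec: SceneSpec,
    geometries: list[tuple[str, tuple[float, float, float]]],
) -> list[tuple[str, np.ndarray, tuple[float, float, float], np.ndarray, np.ndarray]]:
    """Rejection-sample non-overlapping object placements inside the envelope.

    Overlap is tested exactly at voxel level against an occupancy grid
    whose stamped objects are dilated by one voxel, so accepted objects
    are never 26-adjacent and always label as distinct components.
    Centroids are drawn uniformly inside the tissue envelope; the whole
    object must also fit inside the stack.  Each object gets
    ``spec.max_place_attempts`` tries; an exhausted budget raises
    :class:`PlacementError` rather than silently rendering an
    overlapping scene.

    Returns tuples ``(class, centre, axes, rotation, voxel_indices)``.
    """
    env_axes = np.asarray(spec.envelope_semi_axes())
    env_center = np.asarray(spec.physical_extent) / 2
    extent = np.asarray(spec.physical_extent)
    blocked = np.zeros(spec.stack_shape, dtype=bool)
    placed = []
    for klass, axes in geometries:
        r = float(axes[2])
        rotation = _random_rotation(rng)
        for _ in range(spec.max_place_attempts):
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u**2) > 1.0:
                continue
            cand = env_center + u * env_axes
            if not _inside_envelope(cand, env_center, env_axes, margin_um=0.0):
                continue
            if np.any(cand - r < 0) or np.any(cand + r > extent):
                continue  # object would be clipped by the stack border
            idx = _rasterize_ellipsoid(blocked, spec.voxel_size, cand, axes, rotation)
            if len(idx) == 0 or blocked[idx[:, 0], idx[:, 1], idx[:, 2]].any():
                continue
            placed.append((klass, cand, axes, rotation, idx))
            _stamp_blocked(blocked, idx)
            break
        else:
            raise PlacementError(
                f"could not place {klass} (bounding radius {r:.1f} µm) after "
                f"{spec.max_place_attempts} attempts; scene too crowded"
            )
    return placed


def _stamp_blocked(blocked: np.ndarray, idx: np.ndarray, margin_vox: int = 1) -> None:
    """Mark object voxels plus a 1-voxel halo as occupied."""
    from scipy import ndimage as ndi

    lo = np.maximum(idx.min(axis=0) - margin_vox - 1, 0)
    hi = np.minimum(idx.max(axis=0) + margin_vox + 2, blocked.shape)
    local = np.zeros(tuple(hi - lo), dtype=bool)
    rel = idx - lo
    local[rel[:, 0], rel[:, 1], rel[:, 2]] = True
    local = ndi.binary_dilation(local, iterations=margin_vox, structure=np.ones((3, 3, 3), bool))
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    blocked[region] |= local


def generate_stack(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic stack and its exact ground truth.

    The tissue envelope is rendered at ``background_intensity`` over a
    zero outside-tissue floor; cells, neuron blobs and artifacts are
    rendered solid at ``cell_intensity``.  Optional Poisson noise is
    applied to the clean image, then Gaussian noise of sd ``noise_sd``;
    the result is clipped at zero.  The same spec (including seed) always
    yields the identical stack and ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size
    grid = np.zeros(spec.stack_shape, dtype=float)
    env_axes = spec.envelope_semi_axes()
    env_center = tuple(e / 2 for e in spec.physical_extent)

    env_idx = _rasterize_ellipsoid(grid, vs, env_center, env_axes, np.eye(3))
    grid[env_idx[:, 0], env_idx[:, 1], env_idx[:, 2]] = spec.background_intensity
    tissue_voxels = len(env_idx)

    geometries: list[tuple[str, tuple[float, float, float]]] = []
    if spec.cell_axes is not None:
        cell_axes = [tuple(sorted(float(v) for v in t)) for t in spec.cell_axes]
    else:
        cell_axes = [sample_cell_axes(rng, spec.shape_mode) for _ in range(spec.n_cells)]
    geometries += [("cell", a) for a in cell_axes]
    for _ in range(spec.n_neuron_blobs):
        r_min = (3 * spec.neuron_min_volume / (4 * np.pi)) ** (1 / 3)
        r = rng.uniform(r_min, 1.3 * r_min)
        geometries.append(("neuron", (r, r, r)))
    for _ in range(spec.n_artifacts):
        # speck radius tuned so rendered size stays at/below artifact_max_voxels
        vox_vol = float(np.prod(vs))
        r_hi = (3 * spec.artifact_max_voxels * vox_vol / (4 * np.pi)) ** (1 / 3)
        r = rng.uniform(0.3 * r_hi, 0.95 * r_hi)
        geometries.append(("artifact", (r, r, r)))

    placed = _place_objects(rng, spec, geometries)

    objects: list[ObjectRecord] = []
    for oid, (klass, center, axes, rotation, idx) in enumerate(placed, start=1):
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = spec.cell_intensity
        objects.append(
            ObjectRecord(
                object_id=oid,
                klass=klass,
                centroid_um=tuple(center),
                semi_axes_um=axes,
                orientation=rotation,
                volume_um3=ellipsoid_volume(*axes),
                n_voxels=len(idx),
            )
        )

    if spec.psf_sigma_um > 0:
        from scipy import ndimage as ndi

        grid = ndi.gaussian_filter(grid, sigma=[spec.psf_sigma_um / v for v in vs])
    if spec.poisson_noise:
        grid = rng.poisson(grid).astype(float)
    if spec.noise_sd > 0:
        grid = grid + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    grid = np.clip(grid, 0.0, None)

    stack = ImageStack(data=grid, voxel_size=vs, name=f"scene-seed{spec.seed}")
    truth = GroundTruth(
        objects=objects,
        tissue_volume_um3=ellipsoid_volume(*env_axes),
        tissue_voxels=tissue_voxels,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class GroupEffect:
    """Group-level modifiers applied on top of the base scene.

    ``density_multiplier`` scales the expected cell count (realized counts
    are Poisson around that expectation, emulating biological sampling
    noise).  ``shape_mode`` selects the morphology distribution for the
    group ("balanced", "prolate" or "oblate").
    """

    density_multiplier: float = 1.0
    shape_mode: str = "balanced"


@dataclass
class CohortSample:
    """One generated sample: stack, ground truth and its metadata."""

    stack: ImageStack
    truth: GroundTruth
    metadata: SampleMetadata
    spec: SceneSpec


@dataclass
class CohortDesign:
    """A 2×2×2 (sex × condition × side) design over one or more tissues.

    ``effects`` maps group keys ``(sex, condition, side, tissue)`` to
    :class:`GroupEffect`; groups not listed get the identity effect.
    """

    base_spec: SceneSpec = field(default_factory=SceneSpec)
    tissues: tuple[str, ...] = ("DRG",)
    effects: dict[tuple[str, str, str, str], GroupEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .io import TISSUES

        for key in self.effects:
            if len(key) != 4:
                raise ConfigError(f"group key must be (sex, condition, side, tissue); got {key}")
            sex, condition, side, tissue = key
            if (
                sex not in SEXES
                or condition not in CONDITIONS
                or side not in SIDES
                or tissue not in TISSUES
            ):
                raise ConfigError(f"unknown group key {key}")

    def effect_for(self, sex: str, condition: str, side: str, tissue: str) -> GroupEffect:
        return self.effects.get((sex, condition, side, tissue), GroupEffect())


def generate_cohort(
    design: CohortDesign,
    n_samples_per_group: int,
    base_seed: int,
) -> Iterator[CohortSample]:
    """Yield one sample per (sex, condition, side, tissue, animal) cell.

    Per-sample seeds are spawned deterministically from ``base_seed`` via
    ``numpy.random.SeedSequence`` so the whole cohort is reproducible and
    samples are independent.  Ipsilateral and contralateral stacks of the
    same (sex, condition, tissue, animal) share an animal id, which is
    what downstream paired ipsi/contra ratios key on.
    """
    if n_samples_per_group < 0:
        raise ConfigError("n_samples_per_group must be ≥ 0")
    ss = np.random.SeedSequence(base_seed)
    for sex in SEXES:
        for condition in CONDITIONS:
            for tissue in design.tissues:
                for k in range(n_samples_per_group):
                    animal = f"{sex[0]}{condition}{k + 1}"
                    for side in SIDES:
                        child = ss.spawn(1)[0]
                        rng = np.random.default_rng(child)
                        eff = design.effect_for(sex, condition, side, tissue)
                        lam = design.base_spec.n_cells * eff.density_multiplier
                        n_cells = int(rng.poisson(lam))
                        spec = dataclasses.replace(
                            design.base_spec,
                            n_cells=n_cells,
                            cell_axes=None,
                            shape_mode=eff.shape_mode,
                            seed=int(child.generate_state(1, np.uint32)[0] % (2**31)),
                        )
                        stack, truth = generate_stack(spec)
                        md = SampleMetadata(
                            sample_id=f"{sex}-{condition}-{tissue}-{animal}-{side}",
                            sex=sex,
                            condition=condition,
                            side=side,
                            tissue=tissue,
                            animal_id=animal,
                        )
                        stack.metadata = md
                        stack.name = md.sample_id
                        yield CohortSample(stack=stack, truth=truth, metadata=md, spec=spec)
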