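"""Anatomy volumes: slice-stack reading, gray-level tissue classes, and a
synthetic two-chamber ventricle phantom.

Anatomy is a 3D integer gray-level field in which each gray value encodes
one tissue class (the histo-anatomical slice-stack convention; cardiac
labels live in the 30-70 gray range). Axes are ordered (x, y, z) with z
the slice axis, 0-based voxel indices, and world position = index x
spacing.

The phantom substitutes for segmented cryosection data: two ellipsoidal
shells (a thick-walled LV and a thinner RV wrapped against it) open at the
base, apex pointing toward low z, inside a padded background box. Its
ground-truth region masks (apex, base, per-chamber endocardium) drive the
stimulation protocols and the propagation-ordering checks.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import volio

__all__ = [
    "TissueClassInfo", "AnatomyVolume", "PhantomSpec", "DEFAULT_CLASS_TABLE",
    "read_slice_stack", "write_slice_stack", "classify_tissue",
    "generate_phantom",
]


@dataclass(frozen=True)
class TissueClassInfo:
    """Render/simulation attributes of one gray-level tissue class."""
    name: str
    color: tuple[float, float, float]  # RGB in [0, 1]
    alpha: float
    is_excitable: bool


# Default organ palette (illustrative gray levels within the cardiac 30-70
# band): LV cyan, RV pale red, right atrium purple, left atrium tan,
# aorta yellow.
DEFAULT_CLASS_TABLE: dict[int, TissueClassInfo] = {
    40: TissueClassInfo("left_ventricle", (0.0, 0.85, 0.85), 0.9, True),
    50: TissueClassInfo("right_ventricle", (0.94, 0.55, 0.55), 0.9, True),
    45: TissueClassInfo("right_atrium", (0.55, 0.25, 0.65), 0.6, False),
    55: TissueClassInfo("left_atrium", (0.82, 0.70, 0.45), 0.6, False),
    60: TissueClassInfo("aorta", (0.95, 0.85, 0.15), 0.6, False),
}


@dataclass
class AnatomyVolume:
    """Labeled anatomy: integer gray levels + per-level class table."""
    labels: np.ndarray
    spacing: tuple[float, float, float] = (0.33, 0.33, 0.33)
    class_table: dict[int, TissueClassInfo] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TABLE))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        self.spacing = tuple(float(s) for s in np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)))
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")

    @property
    def dims(self):
        return self.labels.shape

    def unknown_labels(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(v) for v in present if v != 0 and int(v) not in self.class_table]

    def histogram(self):
        """(gray values, counts) over nonzero labels."""
        vals, counts = np.unique(self.labels[self.labels != 0], return_counts=True)
        return vals, counts

    def save_nrrd(self, path) -> None:
        volio.write_nrrd(path, self.labels.astype(np.int16), self.spacing,
                         content="anatomy labels")

    @classmethod
    def load_nrrd(cls, path, class_table=None) -> "AnatomyVolume":
        labels, spacing = volio.read_nrrd(path)
        return cls(labels=labels, spacing=spacing,
                   class_table=class_table or dict(DEFAULT_CLASS_TABLE))


def read_slice_stack(paths, spacing=(0.33, 0.33, 0.33),
                     class_table=None) -> AnatomyVolume:
    """Assemble ordered single-channel image slices into an AnatomyVolume.

    Slice k becomes labels[:, :, k]; image row/column map to y/x.
    """
    paths = [pathlib.Path(p) for p in paths]
    if not paths:
        raise ValueError("empty slice-path list")
    slices = []
    shape0 = None
    for p in paths:
        img = Image.open(p)
        arr = np.asarray(img)
        if arr.ndim != 2:
            raise ValueError(f"{p}: multi-channel image (expected single-channel)")
        if shape0 is None:
            shape0 = arr.shape
        elif arr.shape != shape0:
            raise ValueError(
                f"{p}: slice dimensions {arr.shape} differ from first slice {shape0}")
        slices.append(arr.T)  # (W, H) -> (x, y)
    labels = np.stack(slices, axis=2)
    return AnatomyVolume(labels=labels, spacing=spacing,
                         class_table=class_table or dict(DEFAULT_CLASS_TABLE))


def write_slice_stack(volume: AnatomyVolume, directory, prefix: str = "slice") -> list[pathlib.Path]:
    """Write labels as numbered grayscale PNGs (inverse of read_slice_stack)."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = volume.labels
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("labels must fit uint8 for PNG slice export")
    paths = []
    for k in range(labels.shape[2]):
        p = directory / f"{prefix}_{k:04d}.png"
        Image.fromarray(labels[:, :, k].T.astype(np.uint8), mode="L").save(p)
        paths.append(p)
    return paths


@dataclass
class ClassMasks:
    """Output of classify_tissue."""
    per_class: dict[str, np.ndarray]
    tissue_mask: np.ndarray      # any labeled voxel
    excitable_mask: np.ndarray   # union of is_excitable classes


def classify_tissue(volume: AnatomyVolume) -> ClassMasks:
    """Split the labeled volume into per-class masks by gray level."""
    if not volume.class_table:
        raise ValueError("class_table is empty")
    unknown = volume.unknown_labels()
    if unknown:
        raise ValueError(f"labels not in class_table: {unknown}")
    per_class = {}
    excitable = np.zeros(volume.dims, dtype=bool)
    for level, info in volume.class_table.items():
        m = volume.labels == level
        if m.any():
            per_class[info.name] = m
            if info.is_excitable:
                excitable |= m
    return ClassMasks(per_class=per_class, tissue_mask=volume.labels != 0,
                      excitable_mask=excitable)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberSpec:
    center: tuple[float, float, float]      # mm
    semi_axes: tuple[float, float, float]   # outer, mm
    wall_thickness: float                   # mm
    label: int


@dataclass(frozen=True)
class PhantomSpec:
    """Two-chamber ellipsoidal-shell ventricle phantom.

    The default 60 x 60 x 80 box at 0.33 mm spacing is a reduced-scale
    ventricle pair that runs the full simulate+render pipeline in minutes.
    """
    dims: tuple[int, int, int] = (60, 60, 80)
    spacing: float = 0.33
    lv: ChamberSpec = ChamberSpec(center=(8.6, 9.9, 14.5),
                                  semi_axes=(6.3, 6.3, 10.5),
                                  wall_thickness=2.2, label=40)
    rv: ChamberSpec = ChamberSpec(center=(13.3, 9.9, 15.5),
                                  semi_axes=(5.6, 6.6, 9.0),
                                  wall_thickness=1.2, label=50)
    base_fraction: float = 0.70   # chambers open above center_z + frac * sz
    jitter_amplitude: float = 0.02  # radial surface jitter (fraction of radius)
    seed: int = 0

    def __post_init__(self):
        for ch in (self.lv, self.rv):
            if ch.wall_thickness < 2 * self.spacing:
                raise ValueError(
                    f"wall thickness {ch.wall_thickness} mm is thinner than 2 "
                    f"voxels at spacing {self.spacing} mm")

    @classmethod
    def scaled(cls, dims, spacing: float = 0.33, seed: int = 0,
               jitter_amplitude: float = 0.02) -> "PhantomSpec":
        """Chamber geometry proportional to the box (any resolution).

        Reproduces the default phantom proportions at 60 x 60 x 80.
        """
        X, Y, Z = (d * spacing for d in dims)
        lv = ChamberSpec(center=(0.434 * X, 0.5 * Y, 0.55 * Z),
                         semi_axes=(0.318 * X, 0.318 * Y, 0.398 * Z),
                         wall_thickness=max(0.111 * X, 2 * spacing), label=40)
        rv = ChamberSpec(center=(0.672 * X, 0.5 * Y, 0.587 * Z),
                         semi_axes=(0.283 * X, 0.333 * Y, 0.341 * Z),
                         wall_thickness=max(0.061 * X, 2 * spacing), label=50)
        return cls(dims=tuple(dims), spacing=spacing, lv=lv, rv=rv,
                   seed=seed, jitter_amplitude=jitter_amplitude)


def _radial_field(coords, chamber: ChamberSpec):
    """Normalized ellipsoidal radius sqrt(sum((p-c)/s)^2) on the lattice."""
    x, y, z = coords
    cx, cy, cz = chamber.center
    sx, sy, sz = chamber.semi_axes
    return np.sqrt(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2)


def _inner_radial_field(coords, chamber: ChamberSpec):
    x, y, z = coords
    cx, cy, cz = chamber.center
    s_in = tuple(max(s - chamber.wall_thickness, 1e-6) for s in chamber.semi_axes)
    return np.sqrt(((x - cx) / s_in[0]) ** 2 + ((y - cy) / s_in[1]) ** 2
                   + ((z - cz) / s_in[2]) ** 2)


def _jitter_field(dims, amplitude, seed):
    if amplitude == 0.0:
        return np.zeros(dims)
    from scipy.ndimage import zoom
    rng = np.random.default_rng(seed)
    coarse = rng.uniform(-amplitude, amplitude, size=(6, 6, 8))
    factors = [d / c for d, c in zip(dims, coarse.shape)]
    return zoom(coarse, factors, order=1)[: dims[0], : dims[1], : dims[2]]


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build the phantom volume and its ground-truth region masks.

    Returns ``(AnatomyVolume, masks)`` with masks ``lv_wall``, ``rv_wall``,
    ``lv_cavity``, ``rv_cavity``, ``lv_endo``, ``rv_endo``, ``apex``,
    ``base``. Deterministic for a fixed seed.
    """
    nx, ny, nz = spec.dims
    sp = spec.spacing
    x = np.arange(nx)[:, None, None] * sp
    y = np.arange(ny)[None, :, None] * sp
    z = np.arange(nz)[None, None, :] * sp
    coords = (x, y, z)
    jit = _jitter_field(spec.dims, spec.jitter_amplitude, spec.seed)

    def shell_and_cavity(ch: ChamberSpec):
        r_out = _radial_field(coords, ch)
        r_in = _inner_radial_field(coords, ch)
        cut = z <= ch.center[2] + spec.base_fraction * ch.semi_axes[2]
        cut = np.broadcast_to(cut, spec.dims)
        shell = (r_out <= 1.0 + jit) & (r_in > 1.0 + jit) & cut
        cavity = (r_in <= 1.0 + jit) & cut
        return shell, cavity

    lv_shell, lv_cavity = shell_and_cavity(spec.lv)
    rv_shell, rv_cavity = shell_and_cavity(spec.rv)
    # the RV wraps against the LV: it yields to the LV wall and never
    # invades the LV cavity
    rv_shell = rv_shell & ~lv_shell & ~lv_cavity
    rv_cavity = rv_cavity & ~lv_shell & ~lv_cavity

    labels = np.zeros(spec.dims, dtype=np.int16)
    labels[rv_shell] = spec.rv.label
    labels[lv_shell] = spec.lv.label

    wall = lv_shell | rv_shell
    if not wall.any():
        raise ValueError("phantom spec produced no wall voxels")
    z_mm = np.broadcast_to(z, spec.dims)
    apex_z = z_mm[wall].min()
    cut_z = min(ch.center[2] + spec.base_fraction * ch.semi_axes[2]
                for ch in (spec.lv, spec.rv))
    masks = {
        "lv_wall": lv_shell,
        "rv_wall": rv_shell,
        "lv_cavity": lv_cavity,
        "rv_cavity": rv_cavity,
        "lv_endo": _surface_adjacent(lv_shell, lv_cavity),
        "rv_endo": _surface_adjacent(rv_shell, rv_cavity),
        "apex": wall & (z_mm <= apex_z + 1.5),
        "base": wall & (z_mm >= cut_z - 1.5),
    }
    table = {
        spec.lv.label: DEFAULT_CLASS_TABLE.get(
            spec.lv.label, TissueClassInfo("left_ventricle", (0.0, 0.85, 0.85), 0.9, True)),
        spec.rv.label: DEFAULT_CLASS_TABLE.get(
            spec.rv.label, TissueClassInfo("right_ventricle", (0.94, 0.55, 0.55), 0.9, True)),
    }
    vol = AnatomyVolume(labels=labels, spacing=(sp, sp, sp), class_table=table)
    return vol, masks


def _surface_adjacent(shell: np.ndarray, cavity: np.ndarray) -> np.ndarray:
    """Shell voxels 6-adjacent to a cavity voxel (endocardial surface)."""
    near = np.zeros_like(cavity)
    for axis in range(3):
        for shift in (1, -1):
            near |= np.roll(cavity, shift, axis=axis)
    # np.roll wraps around; the phantom keeps background padding at the box
    # faces so wrapped-in values are always False there
    return shell & near
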