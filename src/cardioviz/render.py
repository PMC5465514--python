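"""Software ray casting: emission-absorption light transport plus the
merging attenuation function that composites anatomy and action-potential
volumes in a single ray integral.

Model
-----
Each volume has a piecewise-linear transfer lookup (a "linear lookup
table"): anatomy gray value -> (alpha_a, L_a), membrane potential ->
(alpha_e, L_e). Along a ray sampled at uniform step ds, the merged
per-sample opacity is

    tau'(x) = alpha_a(x') * alpha_e(x) * mef,

where mef = 1 where electrophysiology data exists and a normalized anatomy
gradient magnitude min(1, |grad V_a| / g95) where it does not - so
homogeneous tissue interiors without potential data attenuate nothing and
become translucent, while anatomical boundaries remain visible. The merged
emission is the opacity-weighted blend

    L_merging = alpha_e/(alpha_e+alpha_a) * (L_e alpha_e)
              + alpha_a/(alpha_e+alpha_a) * (L_a alpha_a).

tau' is interpreted as opacity per sample interval (optical depth
increment -ln(1 - tau')), and rays are accumulated front-to-back with
early termination, the exact piecewise-constant solution of the continuous
attenuated-emission integral.

Where no electrophysiology volume is supplied at a sample, alpha_e is
taken as 1 (the anatomy alone attenuates) and the emission reduces to the
anatomy term. A fully transparent potential LUT disables the
electrophysiology volume entirely, reproducing the single-volume baseline
renderer pixel for pixel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .geometry_io import AnatomyVolume

__all__ = [
    "TransferLUT", "PotentialColorScale", "RaySample", "RenderConfig",
    "RenderMode", "lut_map", "merging_attenuation", "merged_emission",
    "composite_ray", "render_volume", "anatomy_lut", "colorbar_image",
    "save_png",
]

#: front-to-back early termination: stop when transmittance drops below this
TRANSMITTANCE_EPS = 1e-4


class RenderMode(enum.Enum):
    LTM_ANATOMY = "ltm_anatomy"
    LTM_POTENTIAL = "ltm_potential"
    MERGED = "merged"


@dataclass(frozen=True)
class TransferLUT:
    """Piecewise-linear map scalar value -> (opacity, emission RGB).

    Between control points both opacity and color interpolate linearly;
    outside the domain the nearest endpoint is used (clamping).
    """
    values: tuple[float, ...]
    alphas: tuple[float, ...]
    colors: tuple[tuple[float, float, float], ...]
    kind: str = "anatomy"  # "anatomy" (Theta_a) or "potential" (Theta_e)

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("empty LUT")
        if not (len(self.values) == len(self.alphas) == len(self.colors)):
            raise ValueError("values/alphas/colors length mismatch")
        if list(self.values) != sorted(self.values):
            raise ValueError("LUT control values must be sorted")
        if any(a < 0 or a > 1 for a in self.alphas):
            raise ValueError("opacities must lie in [0, 1]")

    @property
    def max_alpha(self) -> float:
        return max(self.alphas)

    def alpha_of(self, value):
        return np.interp(value, self.values, self.alphas)

    def color_of(self, value):
        value = np.asarray(value, dtype=np.float64)
        out = np.empty(value.shape + (3,))
        cols = np.asarray(self.colors, dtype=np.float64)
        for c in range(3):
            out[..., c] = np.interp(value, self.values, cols[:, c])
        return out


def lut_map(lut: TransferLUT, value: float):
    """(opacity, emission RGB) at ``value``; clamps outside the domain."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite sample value {value}")
    return float(lut.alpha_of(value)), tuple(lut.color_of(value))


@dataclass(frozen=True)
class PotentialColorScale:
    """Action-potential color bar: -86.0 mV (rest) blue to 45.0 mV (peak) red.

    Intermediate hues follow a blue-cyan-green-yellow-red path; opacity is
    constant by default.
    """
    v_min: float = -86.0
    v_max: float = 45.0
    alpha: float = 0.9

    def to_lut(self) -> TransferLUT:
        hues = ((0.0, 0.0, 1.0), (0.0, 1.0, 1.0), (0.0, 1.0, 0.0),
                (1.0, 1.0, 0.0), (1.0, 0.0, 0.0))
        vals = tuple(self.v_min + k * (self.v_max - self.v_min) / 4 for k in range(5))
        return TransferLUT(values=vals, alphas=(self.alpha,) * 5, colors=hues,
                           kind="potential")


def anatomy_lut(volume: AnatomyVolume, background_alpha: float = 0.0) -> TransferLUT:
    """Build the anatomy LUT from the volume's gray-level class table."""
    entries = sorted(volume.class_table.items())
    values = [0.0] + [float(lvl) for lvl, _ in entries]
    alphas = [background_alpha] + [info.alpha for _, info in entries]
    colors = [(0.0, 0.0, 0.0)] + [info.color for _, info in entries]
    return TransferLUT(values=tuple(values), alphas=tuple(alphas),
                       colors=tuple(colors), kind="anatomy")


# ---------------------------------------------------------------------------
# per-sample operations (scalar form)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaySample:
    """One sample along a viewing ray.

    ``potential_value`` is None exactly when the sample lies outside the
    electrophysiology volume's support (the paper's V_e = -1 sentinel is
    honoured only when importing volumes that use that convention).
    """
    position: float                      # distance along the ray, mm
    anatomy_value: float
    potential_value: float | None
    anatomy_gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def no_ep_data(self) -> bool:
        return self.potential_value is None


def merging_attenuation(sample: RaySample, lut_a: TransferLUT,
                        lut_e: TransferLUT, grad_scale: float = 1.0) -> float:
    """Merged attenuation tau' = alpha_a * alpha_e * mef (per sample).

    Where no EP data exists, alpha_e := 1 and mef is the normalized anatomy
    gradient magnitude (clamped to 1); elsewhere mef = 1.
    """
    alpha_a = float(lut_a.alpha_of(sample.anatomy_value))
    if sample.no_ep_data:
        g = float(np.linalg.norm(sample.anatomy_gradient))
        mef = min(1.0, g / grad_scale) if grad_scale > 0 else 0.0
        alpha_e = 1.0
    else:
        mef = 1.0
        alpha_e = float(lut_e.alpha_of(sample.potential_value))
    return alpha_a * alpha_e * mef


def merged_emission(sample: RaySample, lut_a: TransferLUT,
                    lut_e: TransferLUT) -> np.ndarray:
    """Opacity-weighted emission blend (premultiplied colors).

    The two weights alpha_e/(alpha_e+alpha_a) and alpha_a/(alpha_e+alpha_a)
    sum to 1; if both opacities vanish the emission is zero (background
    shows through).
    """
    alpha_a = float(lut_a.alpha_of(sample.anatomy_value))
    L_a = lut_a.color_of(sample.anatomy_value)
    if sample.no_ep_data:
        return L_a * alpha_a
    alpha_e = float(lut_e.alpha_of(sample.potential_value))
    L_e = lut_e.color_of(sample.potential_value)
    tot = alpha_e + alpha_a
    if tot <= 0.0:
        return np.zeros(3)
    w_e = alpha_e / tot
    w_a = alpha_a / tot
    return w_e * (L_e * alpha_e) + w_a * (L_a * alpha_a)


def composite_ray(samples, lut_a: TransferLUT, lut_e: TransferLUT,
                  mode: RenderMode = RenderMode.MERGED,
                  background=(0.0, 0.0, 0.0), grad_scale: float = 1.0) -> np.ndarray:
    """Front-to-back compositing of ordered samples into one pixel color.

    Per-sample opacity is tau' (merged mode) or the single volume's alpha
    (baseline modes); accumulation terminates early once transmittance
    falls below 1e-4.
    """
    positions = [s.position for s in samples]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("samples must be strictly front-to-back ordered")
    color = np.zeros(3)
    transmittance = 1.0
    for s in samples:
        if mode is RenderMode.MERGED:
            a = merging_attenuation(s, lut_a, lut_e, grad_scale)
            e = merged_emission(s, lut_a, lut_e)
        elif mode is RenderMode.LTM_ANATOMY:
            a = float(lut_a.alpha_of(s.anatomy_value))
            e = lut_a.color_of(s.anatomy_value) * a
        else:  # LTM_POTENTIAL
            if s.no_ep_data:
                a, e = 0.0, np.zeros(3)
            else:
                a = float(lut_e.alpha_of(s.potential_value))
                e = lut_e.color_of(s.potential_value) * a
        color = color + transmittance * e
        transmittance = transmittance * (1.0 - a)
        if transmittance < TRANSMITTANCE_EPS:
            break
    return color + transmittance * np.asarray(background, dtype=np.float64)


# ---------------------------------------------------------------------------
# whole-image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Orthographic camera and ray-march settings."""
    image_size: tuple[int, int] = (128, 128)        # (width, height) px
    view_dir: tuple[float, float, float] = (0.0, 1.0, 0.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    window: tuple[float, float] | None = None        # ortho extent (w, h), mm
    center: tuple[float, float, float] | None = None  # look-at point, mm
    step: float = 0.15                               # ray step, mm
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mode: RenderMode = RenderMode.MERGED

    def validate(self, spacing) -> None:
        if self.step > 0.5 * min(spacing) + 1e-12:
            raise ValueError(
                f"ray step {self.step} mm must be <= half the voxel "
                f"spacing ({0.5 * min(spacing)} mm)")


def _ray_grid(config: RenderConfig, extent):
    d = np.asarray(config.view_dir, dtype=np.float64)
    d = d / np.linalg.norm(d)
    up = np.asarray(config.up, dtype=np.float64)
    right = np.cross(d, up)
    if np.linalg.norm(right) == 0:
        raise ValueError("view_dir and up are collinear")
    right /= np.linalg.norm(right)
    true_up = np.cross(right, d)

    center = (np.asarray(config.center, dtype=np.float64)
              if config.center is not None else extent / 2.0)
    if config.window is not None:
        win_w, win_h = config.window
    else:
        win_w = win_h = float(np.linalg.norm(extent)) * 1.05
    W, H = config.image_size
    us = (np.arange(W) + 0.5) / W - 0.5
    vs = (np.arange(H) + 0.5) / H - 0.5
    uu, vv = np.meshgrid(us * win_w, vs * win_h)
    # image row 0 at the top (+up)
    origins = (center[None, None, :]
               + uu[..., None] * right[None, None, :]
               - vv[..., None] * true_up[None, None, :]
               - d[None, None, :] * (float(np.linalg.norm(extent)) + 1.0))
    return origins.reshape(-1, 3), d


def _box_span(origins, d, extent):
    """Entry/exit distances of each ray through [0, extent] (slab method)."""
    t0 = np.full(origins.shape[0], -np.inf)
    t1 = np.full(origins.shape[0], np.inf)
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            inside = (origins[:, ax] >= 0) & (origins[:, ax] <= extent[ax])
            t0 = np.where(inside, t0, np.inf)
            continue
        ta = (0.0 - origins[:, ax]) / d[ax]
        tb = (extent[ax] - origins[:, ax]) / d[ax]
        t0 = np.maximum(t0, np.minimum(ta, tb))
        t1 = np.minimum(t1, np.maximum(ta, tb))
    return t0, t1


def render_volume(anatomy: AnatomyVolume, potential: np.ndarray | None = None,
                  config: RenderConfig | None = None,
                  lut_a: TransferLUT | None = None,
                  lut_e: TransferLUT | None = None,
                  potential_support: np.ndarray | None = None,
                  sentinel_no_data: float | None = None) -> np.ndarray:
    """Ray-cast the anatomy (and optionally potential) volumes to an image.

    Parameters
    ----------
    anatomy : AnatomyVolume
    potential : ndarray or None
        Vm volume (mV) co-registered with the anatomy (same dims/spacing).
        Required shape check applies in merged/potential modes.
    potential_support : ndarray of bool, optional
        Where the potential volume carries data (default: tissue voxels of
        the anatomy's excitable classes if a potential is given).
    sentinel_no_data : float, optional
        In-band "no data" marker of imported third-party volumes (for
        example -1); voxels equal to it are removed from the support.
    config, lut_a, lut_e : optional overrides.

    Returns
    -------
    (H, W, 3) float image in [0, 1]. Deterministic for fixed inputs.
    """
    config = config or RenderConfig()
    spacing = np.asarray(anatomy.spacing, dtype=np.float64)
    config.validate(anatomy.spacing)
    lut_a = lut_a or anatomy_lut(anatomy)
    lut_e = lut_e or PotentialColorScale().to_lut()
    mode = config.mode

    labels = anatomy.labels.astype(np.float64)
    dims = np.asarray(labels.shape)
    extent = (dims - 1) * spacing

    if mode in (RenderMode.MERGED, RenderMode.LTM_POTENTIAL):
        if potential is not None:
            if potential.shape != labels.shape:
                raise ValueError(
                    f"potential dims {potential.shape} do not match anatomy "
                    f"dims {labels.shape}")
            if potential_support is None:
                from .geometry_io import classify_tissue
                potential_support = classify_tissue(anatomy).excitable_mask
            if sentinel_no_data is not None:
                potential_support = potential_support & (potential != sentinel_no_data)
        elif mode is RenderMode.LTM_POTENTIAL:
            raise ValueError("ltm_potential mode requires a potential volume")

    # a fully transparent potential LUT disables the EP volume: the merged
    # path degenerates to the single-volume baseline (mef = 1 everywhere)
    ep_enabled = potential is not None and lut_e.max_alpha > 0.0

    grads = np.gradient(labels, *spacing)
    grad_mag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
    nz = grad_mag[grad_mag > 0]
    g95 = float(np.percentile(nz, 95)) if nz.size else 1.0
    if g95 <= 0:
        g95 = 1.0

    origins, d = _ray_grid(config, extent)
    t0, t1 = _box_span(origins, d, extent)
    hit = t0 < t1
    ds = config.step
    n_rays = origins.shape[0]

    color = np.zeros((n_rays, 3))
    trans = np.ones(n_rays)
    max_steps = int(np.ceil(np.nanmax(np.where(hit, t1 - t0, 0.0)) / ds)) if hit.any() else 0

    sup_f = (potential_support.astype(np.float64)
             if potential_support is not None else None)

    for k in range(max_steps):
        t = t0 + (k + 0.5) * ds
        active = hit & (t < t1) & (trans >= TRANSMITTANCE_EPS)
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        pos = origins[idx] + t[idx, None] * d[None, :]
        ci = (pos / spacing[None, :]).T  # (3, n) index-space coords

        va = map_coordinates(labels, ci, order=1, mode="constant", cval=0.0)
        alpha_a = lut_a.alpha_of(va)
        L_a = lut_a.color_of(va)

        if mode is RenderMode.LTM_ANATOMY or (mode is RenderMode.MERGED and not ep_enabled):
            alpha = alpha_a
            emis = L_a * alpha_a[:, None]
        elif mode is RenderMode.LTM_POTENTIAL:
            sup = map_coordinates(sup_f, ci, order=1, mode="constant", cval=0.0) > 0.5
            ve = map_coordinates(potential, ci, order=1, mode="constant", cval=0.0)
            alpha_e = np.where(sup, lut_e.alpha_of(ve), 0.0)
            alpha = alpha_e
            emis = lut_e.color_of(ve) * alpha_e[:, None]
        else:  # merged with EP data
            sup = map_coordinates(sup_f, ci, order=1, mode="constant", cval=0.0) > 0.5
            ve = map_coordinates(potential, ci, order=1, mode="constant", cval=0.0)
            gm = map_coordinates(grad_mag, ci, order=1, mode="constant", cval=0.0)
            mef = np.minimum(1.0, gm / g95)
            alpha_e = lut_e.alpha_of(ve)
            L_e = lut_e.color_of(ve)
            alpha = np.where(sup, alpha_a * alpha_e * 1.0, alpha_a * 1.0 * mef)
            tot = alpha_e + alpha_a
            safe = np.where(tot > 0, tot, 1.0)
            w_e = alpha_e / safe
            w_a = alpha_a / safe
            blend = (w_e[:, None] * (L_e * alpha_e[:, None])
                     + w_a[:, None] * (L_a * alpha_a[:, None]))
            blend[tot <= 0] = 0.0
            emis = np.where(sup[:, None], blend, L_a * alpha_a[:, None])

        color[idx] += trans[idx, None] * emis
        trans[idx] *= 1.0 - alpha

    color += trans[:, None] * np.asarray(config.background, dtype=np.float64)
    W, H = config.image_size
    return np.clip(color.reshape(H, W, 3), 0.0, 1.0)


def colorbar_image(lut: TransferLUT, width: int = 16, height: int = 128) -> np.ndarray:
    """Vertical color-bar strip of a LUT (maximum value at the top)."""
    vals = np.linspace(lut.values[-1], lut.values[0], height)
    strip = lut.color_of(vals)  # (height, 3)
    return np.repeat(strip[:, None, :], width, axis=1)


def save_png(image: np.ndarray, path) -> None:
    """Save a float [0,1] (H, W, 3) image as 8-bit PNG (deterministic)."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(path)
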