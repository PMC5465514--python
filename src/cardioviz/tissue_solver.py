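"""3D monodomain excitation propagation on a voxel lattice.

The tissue model is the monodomain reaction-diffusion equation

    phi dVm/dt = -phi (I_ion + I_stim)/Cm + div(D_global phi grad Vm),

integrated with forward Euler in time and a 7-point finite-difference
stencil in space. ``phi`` is a phase field that is 1 deep inside
ventricular tissue and 0 outside; because the diffusive flux is
proportional to phi on cell faces, zero current flows across the tissue
boundary and the Neumann no-flux condition emerges without any explicit
boundary bookkeeping.

The divergence-form operator uses face-centred fluxes with phi averaged
arithmetically onto faces, which makes the discrete operator exactly
conservative: with the reaction switched off, sum(phi * Vm) over the
lattice is constant to roundoff. Voxels whose phi is below a small
threshold (default 0.01) are excluded from the dynamics entirely; fluxes
through their faces are zeroed so conservation is preserved exactly.

The explicit scheme is stable for dt <= dx^2 / (2 d D_global) (d = number
of spatial dimensions); the solver refuses to step beyond that bound.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import _tnnp06 as tp
from ._kernel import NPAR, PAR_IDX, step_cells
from .cell_model import (
    DEFAULT_DT, CellClass, CellParameters, VentricleSide, quiescent_state,
)

__all__ = [
    "DiffusionParams", "PhaseField", "StimulusEvent", "StimulusProtocol",
    "TissueGrid", "TissueRun", "stability_max_dt", "laplacian_3d",
    "double_well", "double_well_deriv", "relax_phase_field",
    "divergence_phi_flux", "step_tissue", "run_tissue_simulation",
]

#: phi below this is treated as "outside the medium" (no reaction, no flux)
PHI_THRESHOLD = 0.01

#: upward Vm crossing that defines local activation, mV
ACTIVATION_THRESHOLD = -20.0


# ---------------------------------------------------------------------------
# stability and stencils
# ---------------------------------------------------------------------------

def stability_max_dt(spacing: float, D_global: float, d: int = 3) -> float:
    """Maximum stable forward-Euler step dx^2/(2 d D), ms."""
    if spacing <= 0 or D_global <= 0:
        raise ValueError("spacing and D_global must be positive")
    if d not in (1, 2, 3):
        raise ValueError(f"spatial dimension d must be 1, 2 or 3, got {d}")
    return spacing ** 2 / (2.0 * d * D_global)


def laplacian_3d(field: np.ndarray, spacing) -> np.ndarray:
    """7-point second-difference Laplacian with zero-gradient edges.

    ``spacing`` is a scalar or per-axis triple (mm). Interior voxels get the
    exact second difference; edge voxels use zero-gradient clamping
    (replicated neighbours).
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3:
        raise ValueError("laplacian_3d expects a 3D field")
    if min(field.shape) < 3 and any(1 < n < 3 for n in field.shape):
        raise ValueError(f"dims must be >= 3 (or 1, for a lower-dimensional "
                         f"slab) along each axis, got {field.shape}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    out = np.zeros_like(field)
    for axis in range(3):
        if field.shape[axis] == 1:
            continue
        lo = np.concatenate([field.take([0], axis=axis),
                             field.take(range(field.shape[axis] - 1), axis=axis)], axis=axis)
        hi = np.concatenate([field.take(range(1, field.shape[axis]), axis=axis),
                             field.take([-1], axis=axis)], axis=axis)
        out += (lo - 2.0 * field + hi) / spacing[axis] ** 2
    return out


def divergence_phi_flux(V: np.ndarray, phi_eff: np.ndarray, D: float, spacing,
                        D_field: np.ndarray | None = None) -> np.ndarray:
    """div(D phi grad V) with face-averaged phi and masked faces.

    ``phi_eff`` must already be thresholded (exact zeros outside the
    medium). Faces touching a phi_eff == 0 voxel carry zero flux, so the
    operator telescopes exactly over the active set. Returned units:
    mV/ms scaled by phi (divide by phi_eff for the Vm tendency).

    ``D_field``, when given, is a per-voxel diffusion coefficient
    (mm^2/ms) replacing the scalar ``D``; the face coefficient is then the
    arithmetic mean of D*phi on the two sides, which keeps the exact
    telescoping conservation.
    """
    V = np.asarray(V, dtype=np.float64)
    phi_eff = np.asarray(phi_eff, dtype=np.float64)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (V.ndim,))
    cond = None if D_field is None else phi_eff * np.asarray(D_field, dtype=np.float64)
    out = np.zeros_like(V)
    for axis in range(V.ndim):
        n = V.shape[axis]
        if n == 1:
            continue
        sl_a = [slice(None)] * V.ndim
        sl_b = [slice(None)] * V.ndim
        sl_a[axis] = slice(0, n - 1)
        sl_b[axis] = slice(1, n)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        pa, pb = phi_eff[sl_a], phi_eff[sl_b]
        dead = (pa == 0.0) | (pb == 0.0)
        if cond is None:
            pf = np.where(dead, 0.0, 0.5 * (pa + pb))
            flux = pf * (V[sl_b] - V[sl_a]) * (D / spacing[axis] ** 2)
        else:
            cf = np.where(dead, 0.0, 0.5 * (cond[sl_a] + cond[sl_b]))
            flux = cf * (V[sl_b] - V[sl_a]) / spacing[axis] ** 2
        out[sl_a] += flux
        out[sl_b] -= flux
    return out


# ---------------------------------------------------------------------------
# phase field
# ---------------------------------------------------------------------------

def double_well(phi):
    """G(phi) = -(2 phi - 1)^2 / 2 + (2 phi - 1)^4 / 4 (equal minima at 0, 1)."""
    u = 2.0 * np.asarray(phi, dtype=np.float64) - 1.0
    return -u ** 2 / 2.0 + u ** 4 / 4.0

def double_well_deriv(phi):
    """dG/dphi = 2 (u^3 - u), u = 2 phi - 1."""
    u = 2.0 * np.asarray(phi, dtype=np.float64) - 1.0
    return 2.0 * (u ** 3 - u)


@dataclass
class PhaseField:
    """Smooth indicator of the tissue domain (1 inside, 0 outside)."""
    phi: np.ndarray
    xi: float = 0.33  # interface-width constant, mm

    @property
    def phi_eff(self) -> np.ndarray:
        """phi with sub-threshold voxels zeroed (the field the solver uses)."""
        return np.where(self.phi >= PHI_THRESHOLD, self.phi, 0.0)

    @property
    def active(self) -> np.ndarray:
        return self.phi >= PHI_THRESHOLD


def relax_phase_field(tissue_mask: np.ndarray, xi: float = 0.33,
                      spacing: float = 0.33, relax_dt: float | None = None,
                      n_iter: int | None = None,
                      total_time: float = 1.0) -> PhaseField:
    """Relax dphi/dt = xi^2 lap(phi) - G'(phi) from the binary mask.

    The double well pins phi to its plateaus, so far from the interface phi
    stays within ~1e-3 of the 0/1 mask values while the interface smooths
    over a width of order xi. The pseudo-time step defaults to a quarter of
    the diffusion-stability bound with xi^2 in place of D (also well below
    the reaction-rate limit).

    Relaxation is deliberately short (default pseudo-time 1.0, enough for
    the interface profile to form): the same equation also moves interfaces
    with curvature, so relaxing to equilibrium would erode - and for
    wall-thin structures eventually delete - the tissue domain. ``n_iter``,
    when given, overrides ``total_time``.
    """
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("tissue_mask must be 3D")
    if not mask.any():
        raise ValueError("tissue_mask is empty")
    d_eff = sum(1 for n in mask.shape if n > 1)
    if relax_dt is None:
        relax_dt = 0.25 * min(stability_max_dt(spacing, xi ** 2, max(d_eff, 1)), 0.5)
    if n_iter is None:
        n_iter = max(1, int(round(total_time / relax_dt)))
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    phi = mask.astype(np.float64)
    xi2 = xi * xi
    for it in range(n_iter):
        phi = phi + relax_dt * (xi2 * laplacian_3d(phi, spacing) - double_well_deriv(phi))
        if np.abs(phi).max() > 2.0:
            raise FloatingPointError(
                f"phase-field relaxation diverged at iteration {it}; "
                f"reduce relax_dt (= {relax_dt})")
    return PhaseField(phi=np.clip(phi, 0.0, 1.0), xi=xi)


# ---------------------------------------------------------------------------
# parameters, protocol, grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionParams:
    """Scalar diffusion coefficient, optionally derived as K/(R_m Cm)."""
    D_global: float = 0.154  # mm^2/ms
    K: float | None = None    # intracellular conductivity
    R_m: float | None = None  # surface-to-volume ratio
    Cm: float = 1.0

    def __post_init__(self):
        if self.D_global <= 0:
            raise ValueError("D_global must be > 0")
        if (self.K is None) != (self.R_m is None):
            raise ValueError("give both K and R_m or neither")
        if self.K is not None:
            derived = self.K / (self.R_m * self.Cm)
            if not np.isclose(derived, self.D_global, rtol=1e-9):
                raise ValueError(
                    f"D_global = {self.D_global} inconsistent with "
                    f"K/(R_m Cm) = {derived}")

    @classmethod
    def from_factors(cls, K: float, R_m: float, Cm: float = 1.0) -> "DiffusionParams":
        return cls(D_global=K / (R_m * Cm), K=K, R_m=R_m, Cm=Cm)


@dataclass(frozen=True)
class StimulusEvent:
    """One square current pulse applied over a voxel region.

    Negative amplitude depolarizes (dVm/dt = -(I_ion + I_stim)/Cm).
    """
    onset: float      # ms
    duration: float   # ms
    amplitude: float  # pA/pF
    region: np.ndarray  # 3D boolean mask

    def active_at(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


class ProtocolStyle(enum.Enum):
    SINGLE = "single"
    S1S2 = "S1S2"


@dataclass(frozen=True)
class StimulusProtocol:
    events: tuple[StimulusEvent, ...]
    style: ProtocolStyle = ProtocolStyle.SINGLE

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("stimulus events must be time-ordered")

    @classmethod
    def single(cls, region: np.ndarray, onset: float = 0.0, duration: float = 2.0,
               amplitude: float = -52.0) -> "StimulusProtocol":
        return cls((StimulusEvent(onset, duration, amplitude, region),),
                   ProtocolStyle.SINGLE)

    @classmethod
    def s1s2(cls, s1_region: np.ndarray, s2_region: np.ndarray,
             coupling_interval: float, s1_onset: float = 0.0,
             duration: float = 2.0, amplitude: float = -52.0) -> "StimulusProtocol":
        """Conditioning S1 followed by a premature S2 after the coupling interval."""
        return cls(
            (StimulusEvent(s1_onset, duration, amplitude, s1_region),
             StimulusEvent(s1_onset + coupling_interval, duration, amplitude, s2_region)),
            ProtocolStyle.S1S2,
        )

    def last_offset(self) -> float:
        return max((e.onset + e.duration for e in self.events), default=0.0)


class TissueGrid:
    """Voxel lattice of myocytes: Vm field, per-tissue-voxel cell states.

    Cell states exist only where ``tissue_mask`` is true; non-tissue voxels
    carry Vm (for the diffusive halo inside the phase-field interface) but
    no ionic state.
    """

    def __init__(self, tissue_mask: np.ndarray, spacing=0.33,
                 cell_class: CellClass | np.ndarray = CellClass.EPI,
                 ventricle_side: VentricleSide | np.ndarray = VentricleSide.LEFT,
                 params: CellParameters | None = None):
        self.tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if self.tissue_mask.ndim != 3:
            raise ValueError("tissue_mask must be 3D")
        self.dims = self.tissue_mask.shape
        self.spacing = tuple(np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)))
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        self.params = params or CellParameters.for_class(
            cell_class if isinstance(cell_class, CellClass) else CellClass.EPI)

        n = int(self.tissue_mask.sum())
        self.n_tissue = n
        self.tissue_idx = np.nonzero(self.tissue_mask.ravel())[0]

        # per-voxel class/side (arrays broadcast from scalars)
        def expand(val, enum_type, default):
            if isinstance(val, enum_type):
                return np.full(n, list(enum_type).index(val), dtype=np.uint8)
            arr = np.asarray(val)
            if arr.shape == self.dims:
                return arr.ravel()[self.tissue_idx].astype(np.uint8)
            raise ValueError(f"bad {enum_type.__name__} field shape {arr.shape}")

        self.class_codes = expand(cell_class, CellClass, 2)       # 0 endo, 1 mid, 2 epi
        self.side_codes = expand(ventricle_side, VentricleSide, 0)  # 0 left, 1 right

        # states: all classes start from their packaged quiescent state
        self.S = np.empty((tp.NVAR, n), dtype=np.float64)
        for code, cls in enumerate(CellClass):
            sel = self.class_codes == code
            if sel.any():
                self.S[:, sel] = quiescent_state(cls).to_array()

        # Per-cell conductances. g_to/g_Ks follow the transmural class tables,
        # rescaled by any global override in params (relative to the epi
        # defaults); everything else comes straight from params. RV-epi
        # scaling is folded in last.
        self.P = np.empty((NPAR, n), dtype=np.float64)
        for name in ("g_Na", "g_K1", "g_Kr", "g_CaL", "k_NaCa", "P_NaK",
                     "g_pCa", "g_pK", "g_bCa", "g_bNa"):
            self.P[PAR_IDX[name], :] = getattr(self.params, name)
        to_scale = self.params.g_to / tp.G_TO["epi"]
        ks_scale = self.params.g_Ks / tp.G_KS["epi"]
        for code, cls in enumerate(CellClass):
            sel = self.class_codes == code
            if sel.any():
                self.P[PAR_IDX["g_to"], sel] = tp.G_TO[cls.value] * to_scale
                self.P[PAR_IDX["g_Ks"], sel] = tp.G_KS[cls.value] * ks_scale
        rv_epi = (self.side_codes == 1) & (self.class_codes == 2)
        ks_fac, to_fac = self.params.rv_scaling
        self.P[PAR_IDX["g_Ks"], rv_epi] *= ks_fac
        self.P[PAR_IDX["g_to"], rv_epi] *= to_fac
        self.is_endo = (self.class_codes == 0).astype(np.uint8)

        # the whole field (including the diffusive halo inside the smoothed
        # boundary) starts at the resting potential, the V_r(s) initial
        # condition of the propagation model
        rest = float(self.S[tp.IDX["Vm"]].mean()) if n else 0.0
        self.vm_field = np.full(self.dims, rest, dtype=np.float64)
        self.vm_field.ravel()[self.tissue_idx] = self.S[tp.IDX["Vm"]]

    @property
    def state_fields(self) -> np.ndarray:
        """(NVAR, n_tissue) state array of the tissue voxels."""
        return self.S

    def effective_dimension(self) -> int:
        return sum(1 for n in self.dims if n > 1)

    def sync_vm(self) -> None:
        self.vm_field.ravel()[self.tissue_idx] = self.S[tp.IDX["Vm"]]


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def _check_dt(grid: TissueGrid, diffusion: DiffusionParams, dt: float,
              cell_dt: float = DEFAULT_DT,
              D_field: np.ndarray | None = None) -> None:
    d = grid.effective_dimension()
    D_max = diffusion.D_global if D_field is None else float(np.max(D_field))
    bound = stability_max_dt(min(grid.spacing), D_max, d)
    if dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt} ms violates the forward-Euler stability bound "
            f"dx^2/(2 d D) = {bound:.6g} ms (dx = {min(grid.spacing)} mm, "
            f"d = {d}, D = {D_max} mm^2/ms)")
    if dt > cell_dt + 1e-12:
        raise ValueError(
            f"dt = {dt} ms exceeds the cell-integration step {cell_dt} ms")


def step_tissue(grid: TissueGrid, phase: PhaseField, diffusion: DiffusionParams,
                protocol: StimulusProtocol | None, t: float, dt: float,
                reaction: bool = True, D_field: np.ndarray | None = None,
                _cache: dict | None = None) -> TissueGrid:
    """Advance the lattice one step of dt, in place; returns the grid.

    With ``reaction=False`` only the conservative diffusion operator acts
    (used by the no-flux conservation checks).
    """
    _check_dt(grid, diffusion, dt, D_field=D_field)
    cache = _cache if _cache is not None else {}
    if "phi_eff" not in cache:
        phi_eff = phase.phi_eff
        if phi_eff.shape != grid.dims:
            raise ValueError("phase field dims do not match grid dims")
        cache["phi_eff"] = phi_eff
        active = phi_eff > 0.0
        cache["halo_idx"] = np.nonzero((active & ~grid.tissue_mask).ravel())[0]
        cache["phi_tissue"] = phi_eff.ravel()[grid.tissue_idx]
        cache["phi_halo"] = phi_eff.ravel()[cache["halo_idx"]]
        # Tissue voxels whose phi fell below threshold (possible for
        # voxel-thin features under the curvature motion of the relaxation)
        # are frozen out of the diffusive coupling entirely.
        if reaction and np.any(cache["phi_tissue"] == 0.0):
            raise ValueError("tissue voxels with phi below threshold; "
                             "relax the phase field from the tissue mask "
                             "(or thicken sub-voxel tissue features)")
        cache["tissue_ok"] = cache["phi_tissue"] > 0.0
        cache["istim"] = np.zeros(grid.n_tissue)
        cache["ext"] = np.zeros(grid.n_tissue)

    phi_eff = cache["phi_eff"]
    term = divergence_phi_flux(grid.vm_field, phi_eff, diffusion.D_global,
                               grid.spacing, D_field=D_field)
    flat = term.ravel()

    ext = cache["ext"]
    ext[:] = 0.0
    np.divide(flat[grid.tissue_idx], cache["phi_tissue"], out=ext,
              where=cache["tissue_ok"])

    istim = cache["istim"]
    istim[:] = 0.0
    if protocol is not None:
        for ev in protocol.events:
            if ev.active_at(t):
                istim += ev.amplitude * ev.region.ravel()[grid.tissue_idx]

    if reaction:
        step_cells(grid.S, grid.P, grid.is_endo, istim, ext, dt, grid.params.Cm)
        vm_new = grid.S[tp.IDX["Vm"]]
        if not np.all(np.isfinite(vm_new)):
            bad = int(np.argmax(~np.isfinite(vm_new)))
            raise FloatingPointError(
                f"Vm became non-finite at t = {t} ms (tissue voxel {bad})")
        grid.vm_field.ravel()[grid.tissue_idx] = vm_new
    else:
        grid.vm_field.ravel()[grid.tissue_idx] += dt * ext
    halo = cache["halo_idx"]
    if halo.size:
        grid.vm_field.ravel()[halo] += dt * flat[halo] / cache["phi_halo"]
    return grid


@dataclass
class TissueRun:
    """Result of a tissue simulation."""
    times: np.ndarray                 # snapshot times, ms
    snapshots: list[np.ndarray]       # Vm volumes, mV
    activation_map: np.ndarray        # first -20 mV upward crossing, ms (nan = never)
    grid: TissueGrid
    dt: float
    stability_bound: float


def run_tissue_simulation(grid: TissueGrid, phase: PhaseField,
                          diffusion: DiffusionParams,
                          protocol: StimulusProtocol | None,
                          duration: float, snapshot_interval: float = 10.0,
                          dt: float = DEFAULT_DT, reaction: bool = True,
                          D_field: np.ndarray | None = None,
                          activation_threshold: float = ACTIVATION_THRESHOLD,
                          progress: bool = False) -> TissueRun:
    """Run the monodomain model, recording Vm volumes and activation times."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if protocol is not None:
        for ev in protocol.events:
            if not np.any(ev.region & grid.tissue_mask):
                raise ValueError("stimulus region does not intersect the tissue mask")
    _check_dt(grid, diffusion, dt, D_field=D_field)
    bound = stability_max_dt(
        min(grid.spacing),
        diffusion.D_global if D_field is None else float(np.max(D_field)),
        grid.effective_dimension())

    n_steps = int(round(duration / dt))
    snap_every = max(1, int(round(snapshot_interval / dt)))
    cache: dict = {}
    activation = np.full(grid.n_tissue, np.nan)
    vm_prev = grid.S[tp.IDX["Vm"]].copy()

    times = [0.0]
    snapshots = [grid.vm_field.copy()]
    for k in range(n_steps):
        t = k * dt
        step_tissue(grid, phase, diffusion, protocol, t, dt,
                    reaction=reaction, D_field=D_field, _cache=cache)
        vm_now = grid.S[tp.IDX["Vm"]]
        crossed = (vm_prev < activation_threshold) & (vm_now >= activation_threshold) \
            & np.isnan(activation)
        if crossed.any():
            activation[crossed] = (k + 1) * dt
        vm_prev[:] = vm_now
        if (k + 1) % snap_every == 0:
            times.append((k + 1) * dt)
            snapshots.append(grid.vm_field.copy())
        if progress and (k + 1) % 1000 == 0:
            print(f"  t = {(k + 1) * dt:8.1f} ms   Vm in "
                  f"[{vm_now.min():7.2f}, {vm_now.max():7.2f}] mV")

    act_map = np.full(grid.dims, np.nan)
    act_map.ravel()[grid.tissue_idx] = activation
    return TissueRun(times=np.asarray(times), snapshots=snapshots,
                     activation_map=act_map, grid=grid, dt=dt,
                     stability_bound=bound)
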