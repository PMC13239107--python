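"""Pencil-beam superposition of physical dose and voxel-wise mixed-field LQ.

Beams are axis-aligned.  Each spot deposits ``w * IDD(wed) * G2D(r; sigma(wed))``
where ``wed`` is the water-equivalent depth of the voxel along the beam axis,
IDD the laterally integrated depth dose (Gy mm^2 per primary) and G2D a unit
2-D Gaussian (1/mm^2).  Alongside the physical dose D the engine accumulates
the dose-weighted quality sums sum(D_i alpha_i) and sum(D_i sqrt(beta_i))
per RBE model, from which the voxel mixed-field coefficients -- and hence the
RBE-weighted and clinical dose -- are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .base_data import BeamEnergyEntry, MachineModel
from .rbe_models import ReferenceRadiation, ref_dose_from_effect


@dataclass
class DoseGrid:
    """Axis-aligned 3-D scalar field with voxel-center coordinates."""

    values: np.ndarray
    spacing_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * (np.arange(n) + 0.5)

    def like(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing_mm, self.origin_mm)


@dataclass
class Phantom:
    """Relative-stopping-power map plus named boolean structure masks."""

    rsp: np.ndarray
    spacing_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.rsp < 0):
            raise ValueError("relative stopping power must be non-negative")
        for name, m in self.masks.items():
            if m.shape != self.rsp.shape:
                raise ValueError(f"mask {name!r} shape differs from grid")

    def grid(self, values: np.ndarray | None = None) -> DoseGrid:
        if values is None:
            values = np.zeros_like(self.rsp, dtype=float)
        return DoseGrid(values, self.spacing_mm, self.origin_mm)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.rsp.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * (np.arange(n) + 0.5)


@dataclass(frozen=True)
class Spot:
    """One pencil beam: machine energy index, lateral position, weight."""

    energy_index: int
    u_mm: float
    v_mm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be non-negative")


@dataclass
class Beam:
    """Axis-aligned beam: axis in {0,1,2}, direction +1/-1, spot list.

    Spot lateral coordinates (u, v) live on the two transverse axes in
    ascending axis order.
    """

    axis: int
    direction: int
    spots: List[Spot]

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2) or self.direction not in (-1, 1):
            raise ValueError("beam must be axis-aligned: axis 0..2, direction +-1")
        if not self.spots:
            raise ValueError("beam has no spots")

    @property
    def transverse_axes(self) -> Tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axis)  # type: ignore[return-value]


@dataclass
class VoxelBioFields:
    """Physical dose plus the dose-weighted LQ accumulators per model."""

    dose: DoseGrid
    alpha_acc: Dict[str, np.ndarray]  # sum_i D_i * alpha_i
    sqrt_beta_acc: Dict[str, np.ndarray]  # sum_i D_i * sqrt(beta_i)

    def mixed_alpha(self, model: str) -> np.ndarray:
        d = self.dose.values
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alpha_acc[model] / np.where(d > 0, d, 1), 0.0)

    def mixed_beta(self, model: str) -> np.ndarray:
        d = self.dose.values
        with np.errstate(invalid="ignore", divide="ignore"):
            sb = np.where(d > 0, self.sqrt_beta_acc[model] / np.where(d > 0, d, 1), 0.0)
        return sb**2

    def effect(self, model: str) -> np.ndarray:
        """Voxel LQ effect alpha_mix*D + beta_mix*D^2 = sum(D a) + (sum(D sqrt b))^2."""
        return self.alpha_acc[model] + self.sqrt_beta_acc[model] ** 2


def water_equivalent_depth(phantom: Phantom, beam: Beam) -> np.ndarray:
    """WED (cm) of every voxel center along the (axis-aligned) beam.

    Cumulative RSP-weighted path length from the entry surface to the voxel
    center: the voxel's own slab contributes half its water-equivalent
    thickness.
    """
    rsp = phantom.rsp
    step_mm = phantom.spacing_mm[beam.axis]
    if beam.direction < 0:
        rsp = np.flip(rsp, axis=beam.axis)
    cum = np.cumsum(rsp, axis=beam.axis) - 0.5 * rsp
    wed_mm = cum * step_mm
    if beam.direction < 0:
        wed_mm = np.flip(wed_mm, axis=beam.axis)
    return wed_mm / 10.0  # mm water -> cm


def _spot_kernel(
    phantom: Phantom,
    beam: Beam,
    entry: BeamEnergyEntry,
    wed_cm: np.ndarray,
    spot: Spot,
    cutoff_sigmas: float = 4.5,
):
    """Indices and per-voxel (dose, alpha, sqrt_beta interpolants) of one spot."""
    t1, t2 = beam.transverse_axes
    u = phantom.axis_coords(t1)
    v = phantom.axis_coords(t2)
    depth = entry.depth_cm
    sigma_max = float(entry.sigma_mm.max())
    reach = cutoff_sigmas * sigma_max
    iu = np.nonzero(np.abs(u - spot.u_mm) <= reach)[0]
    iv = np.nonzero(np.abs(v - spot.v_mm) <= reach)[0]
    if iu.size == 0 or iv.size == 0:
        return None
    # open-mesh indices of the 3-D block: beam axis full, lateral window only
    grids = np.ix_(
        *[
            iu if ax == t1 else (iv if ax == t2 else np.arange(phantom.rsp.shape[ax]))
            for ax in range(3)
        ]
    )
    wed = wed_cm[grids]
    idd = np.interp(wed, depth, entry.idd, left=0.0, right=0.0)
    sigma = np.interp(wed, depth, entry.sigma_mm)
    du = (u[iu] - spot.u_mm).reshape([-1 if ax == t1 else 1 for ax in range(3)])
    dv = (v[iv] - spot.v_mm).reshape([-1 if ax == t2 else 1 for ax in range(3)])
    r2 = du**2 + dv**2
    gauss = np.exp(-0.5 * r2 / sigma**2) / (2.0 * np.pi * sigma**2)
    dose = idd * gauss  # Gy per primary
    return grids, wed, dose


def compute_fields(
    phantom: Phantom,
    beam: Beam,
    machine: MachineModel,
    weights: Sequence[float] | None = None,
    models: Sequence[str] | None = None,
) -> VoxelBioFields:
    """Superpose all spots of a beam into dose + LQ accumulators.

    ``weights`` overrides the per-spot weights (same order as ``beam.spots``);
    the superposition is linear in them.
    """
    if models is None:
        models = list(machine.entries[0].alpha.keys())
    shape = phantom.rsp.shape
    dose = np.zeros(shape)
    alpha_acc = {m: np.zeros(shape) for m in models}
    sqrt_beta_acc = {m: np.zeros(shape) for m in models}
    wed = water_equivalent_depth(phantom, beam)
    w_arr = (
        np.array([s.weight for s in beam.spots], dtype=float)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w_arr.shape != (len(beam.spots),):
        raise ValueError("weights length must match the spot list")
    for spot, w in zip(beam.spots, w_arr):
        if w == 0:
            continue
        if not 0 <= spot.energy_index < len(machine.entries):
            raise ValueError(f"energy index {spot.energy_index} not in machine")
        entry = machine.entries[spot.energy_index]
        kern = _spot_kernel(phantom, beam, entry, wed, spot)
        if kern is None:
            continue
        grids, wed_blk, dose_blk = kern
        d = w * dose_blk
        dose[grids] += d
        for m in models:
            a = np.interp(wed_blk, entry.depth_cm, entry.alpha[m])
            sb = np.interp(wed_blk, entry.depth_cm, entry.sqrt_beta[m])
            alpha_acc[m][grids] += d * a
            sqrt_beta_acc[m][grids] += d * sb
    return VoxelBioFields(phantom.grid(dose), alpha_acc, sqrt_beta_acc)


def influence_matrices(
    phantom: Phantom,
    beam: Beam,
    machine: MachineModel,
    model: str,
):
    """Sparse per-spot influence: (dose, dose*alpha, dose*sqrt_beta).

    Columns are spots, rows voxels (C-order raveled).  The optimizer uses
    these to evaluate voxel effect as a smooth function of spot weights.
    """
    from scipy.sparse import csc_array

    wed = water_equivalent_depth(phantom, beam)
    n_vox = int(np.prod(phantom.rsp.shape))
    data_d: List[np.ndarray] = []
    data_a: List[np.ndarray] = []
    data_b: List[np.ndarray] = []
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    flat_index = np.arange(n_vox).reshape(phantom.rsp.shape)
    for j, spot in enumerate(beam.spots):
        entry = machine.entries[spot.energy_index]
        kern = _spot_kernel(phantom, beam, entry, wed, spot)
        if kern is None:
            continue
        grids, wed_blk, dose_blk = kern
        a = np.interp(wed_blk, entry.depth_cm, entry.alpha[model])
        sb = np.interp(wed_blk, entry.depth_cm, entry.sqrt_beta[model])
        nz = dose_blk > 0
        rows.append(flat_index[grids][nz].ravel())
        cols.append(np.full(int(nz.sum()), j))
        data_d.append(dose_blk[nz].ravel())
        data_a.append((dose_blk * a)[nz].ravel())
        data_b.append((dose_blk * sb)[nz].ravel())
    r = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    shape = (n_vox, len(beam.spots))
    m_d = csc_array((np.concatenate(data_d) if rows else [], (r, c)), shape=shape)
    m_a = csc_array((np.concatenate(data_a) if rows else [], (r, c)), shape=shape)
    m_b = csc_array((np.concatenate(data_b) if rows else [], (r, c)), shape=shape)
    return m_d, m_a, m_b


def biological_dose(
    fields: VoxelBioFields, model: str, ref: ReferenceRadiation
) -> DoseGrid:
    """Clinical dose grid (Gy(RBE)) from the accumulated voxel fields.

    Per voxel the mixed-field LQ effect is converted to the iso-effective
    reference dose and scaled by the clinical factor; zero where D = 0.
    """
    effect = fields.effect(model)
    d_ref = ref_dose_from_effect(effect, ref)
    clinical = np.where(fields.dose.values > 0, d_ref * ref.clinical_factor, 0.0)
    return fields.dose.like(clinical)
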