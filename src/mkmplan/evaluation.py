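"""Model-comparison surface: recalculation, DVH metrics, difference maps,
and gamma-index analysis.

The comparison protocol mirrors clinical model studies: a plan is optimized
with model A, the physical dose (spot weights) is frozen, the clinical dose
is recalculated with model B, and the two distributions are compared through
DVH metrics, voxel-difference maps and a 3%/3 mm gamma analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .base_data import MachineModel
from .dose_engine import (
    Beam,
    DoseGrid,
    Phantom,
    VoxelBioFields,
    biological_dose,
    compute_fields,
)
from .rbe_models import ReferenceRadiation


def recalc(
    phantom: Phantom,
    beam: Beam,
    machine: MachineModel,
    weights,
    model: str,
    ref: ReferenceRadiation,
    fields: VoxelBioFields | None = None,
) -> Tuple[DoseGrid, VoxelBioFields]:
    """Clinical dose recalculated with ``model`` at frozen spot weights.

    The physical dose is identical to the original plan's by construction
    (same kernel, same weights); only the LQ accumulators are re-derived
    from the requested model's base-data tables.
    """
    if model not in machine.entries[0].alpha:
        raise ValueError(f"machine has no base data for model {model!r}")
    if fields is None:
        fields = compute_fields(phantom, beam, machine, weights)
    return biological_dose(fields, model, ref), fields


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose: np.ndarray
    volume: np.ndarray  # fraction of structure receiving >= dose
    structure: str


def dvh(dose: DoseGrid | np.ndarray, mask: np.ndarray, n_points: int = 401,
        structure: str = "") -> DVHCurve:
    """Cumulative DVH of ``dose`` within ``mask``."""
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    if not np.any(mask):
        raise ValueError("empty structure mask")
    d = values[mask]
    axis = np.linspace(0.0, max(float(d.max()), 1e-12) * 1.02, n_points)
    vol = np.array([(d >= x).mean() for x in axis])
    return DVHCurve(axis, vol, structure)


def dose_at_volume(dose, mask: np.ndarray, percent: float) -> float:
    """D_p%: minimum dose received by the hottest p% of the structure.

    Linear interpolation between adjacent sorted voxel doses (quantile at
    1 - p/100).
    """
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    if not np.any(mask):
        raise ValueError("empty structure mask")
    return float(np.quantile(values[mask], 1.0 - percent / 100.0, method="linear"))


def volume_at_dose(dose, mask: np.ndarray, threshold: float) -> float:
    """V_x: fraction of the structure receiving at least ``threshold``."""
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    if not np.any(mask):
        raise ValueError("empty structure mask")
    return float((values[mask] >= threshold).mean())


@dataclass(frozen=True)
class GammaParams:
    """3%/3 mm global-gamma configuration."""

    dose_percent: float = 3.0
    distance_mm: float = 3.0
    cutoff_percent: float = 10.0  # low-dose cutoff, % of global max
    subsample: int = 10  # search pitch = voxel / subsample
    search_factor: float = 3.0  # search radius = factor * distance criterion

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.distance_mm) <= 0:
            raise ValueError("gamma criteria must be positive")


def gamma_map(
    ref: DoseGrid, eval_: DoseGrid, params: GammaParams | None = None
) -> Tuple[np.ndarray, float]:
    """Per-voxel global gamma index and pass rate (%).

    For every reference voxel above the low-dose cutoff the evaluated dose
    is searched on a sub-voxel lattice (linear interpolation) within the
    search radius; gamma^2 = (dDose/delta_d)^2 + (dist/delta_r)^2 minimised
    over the search.  Shells of increasing shift distance allow early exit
    once no voxel can improve.
    """
    from scipy.ndimage import map_coordinates

    params = params or GammaParams()
    if ref.values.shape != eval_.values.shape or ref.spacing_mm != eval_.spacing_mm:
        raise ValueError("gamma analysis requires co-registered grids")
    norm = float(ref.values.max())
    if norm <= 0:
        raise ValueError("reference distribution has no dose")
    dd = params.dose_percent / 100.0 * norm
    dr = params.distance_mm
    include = ref.values >= params.cutoff_percent / 100.0 * norm

    spacing = np.asarray(ref.spacing_mm, dtype=float)
    pitch = spacing / params.subsample
    radius = params.search_factor * dr
    shift_idx = [
        np.arange(-int(radius / p), int(radius / p) + 1) for p in pitch
    ]
    ox, oy, oz = np.meshgrid(*shift_idx, indexing="ij")
    offsets_mm = np.stack(
        [ox * pitch[0], oy * pitch[1], oz * pitch[2]], axis=-1
    ).reshape(-1, 3)
    dist = np.linalg.norm(offsets_mm, axis=1)
    keep = dist <= radius
    offsets_mm, dist = offsets_mm[keep], dist[keep]
    order = np.argsort(dist)
    offsets_mm, dist = offsets_mm[order], dist[order]

    idx = np.argwhere(include).T.astype(float)  # 3 x N voxel indices
    ref_vals = ref.values[include]
    gamma2 = ((eval_.values[include] - ref_vals) / dd) ** 2  # zero-shift start
    active = np.ones(ref_vals.shape, dtype=bool)
    for off, r in zip(offsets_mm, dist):
        if r > 0:
            limit = (r / dr) ** 2
            active &= gamma2 > limit
            if not np.any(active):
                break
        coords = idx[:, active] + (off / spacing)[:, None]
        ev = map_coordinates(eval_.values, coords, order=1, mode="nearest")
        cand = ((ev - ref_vals[active]) / dd) ** 2 + (r / dr) ** 2
        gamma2[active] = np.minimum(gamma2[active], cand)
    gamma = np.full(ref.values.shape, np.nan)
    gamma[include] = np.sqrt(gamma2)
    pass_rate = float((gamma2 <= 1.0).mean() * 100.0)
    return gamma, pass_rate


@dataclass
class PlanReport:
    """Structure-metric comparison of two clinical dose distributions."""

    table: pd.DataFrame
    difference: DoseGrid  # B - A, Gy(RBE)
    gamma: np.ndarray
    gamma_pass_percent: float
    max_relative_difference_percent: float


def max_relative_difference(
    a: DoseGrid, b: DoseGrid, threshold_fraction: float = 0.1
) -> float:
    """Maximum voxel-wise |B-A|/A (%) over voxels above a dose threshold.

    The threshold (default 10% of the maximum of A) excludes near-zero
    denominators outside the irradiated volume.
    """
    ref = a.values
    sel = ref >= threshold_fraction * ref.max()
    return float(np.max(np.abs(b.values[sel] - ref[sel]) / ref[sel]) * 100.0)


def compare_report(
    plan_a: DoseGrid,
    recalc_b: DoseGrid,
    masks: Dict[str, np.ndarray],
    metrics: Sequence[Tuple[str, str, float]],
    gamma_params: GammaParams | None = None,
    low_dose_gy: float | None = None,
) -> PlanReport:
    """Tabulated DVH-metric comparison plus difference and gamma maps.

    ``metrics`` rows are (structure, kind, parameter) with kind "D" (D_p%,
    parameter = p) or "V" (V_x, parameter = dose threshold in Gy(RBE)).
    Percent differences 100*(B-A)/A are suppressed (NaN) when the model-A
    value falls below ``low_dose_gy`` (default 1% of the global maximum).
    """
    if plan_a.values.shape != recalc_b.values.shape:
        raise ValueError("co-registered grids required")
    if low_dose_gy is None:
        low_dose_gy = 0.01 * float(plan_a.values.max())
    rows = []
    for structure, kind, param in metrics:
        mask = masks[structure]
        if kind == "D":
            va = dose_at_volume(plan_a, mask, param)
            vb = dose_at_volume(recalc_b, mask, param)
            name = f"D{param:g}%"
        elif kind == "V":
            va = volume_at_dose(plan_a, mask, param) * 100.0
            vb = volume_at_dose(recalc_b, mask, param) * 100.0
            name = f"V{param:g}"
        else:
            raise ValueError(f"unknown metric kind {kind!r}")
        pct = 100.0 * (vb - va) / va if abs(va) > low_dose_gy else np.nan
        rows.append(
            {
                "structure": structure,
                "metric": name,
                "model_a": va,
                "model_b": vb,
                "difference": vb - va,
                "percent_difference": pct,
            }
        )
    gamma, pass_rate = gamma_map(plan_a, recalc_b, gamma_params)
    diff = plan_a.like(recalc_b.values - plan_a.values)
    return PlanReport(
        pd.DataFrame(rows),
        diff,
        gamma,
        pass_rate,
        max_relative_difference(plan_a, recalc_b),
    )
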