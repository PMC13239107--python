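"""End-to-end water-phantom model-comparison experiment.

Reproduces the validation protocol used before patient planning: a cubic
target in a homogeneous water box is optimized with the MCF MKM to a flat
clinical dose per fraction with parallel-opposed beams (each field optimized
independently to the per-port prescription), the physical dose is frozen,
the clinical dose is recalculated with the mMKM, and the two distributions
are compared (maximum voxel-wise relative difference, D95, gamma pass rate).

Both models' carbon reference radiations are calibrated from the midpoint of
a 6 cm SOBP at 21 cm range generated from the same synthetic machine, which
keeps each model's RBE convention internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import base_data as bd
from .dose_engine import Beam, DoseGrid, Phantom, Spot, biological_dose, compute_fields
from .evaluation import (
    GammaParams,
    dose_at_volume,
    gamma_map,
    max_relative_difference,
)
from .fixtures import FixtureSpec, water_box_phantom
from .optimizer import (
    ObjectiveSpec,
    Prescription,
    calibrate_reference,
    optimize_field,
)
from .rbe_models import ReferenceRadiation


def default_experiment_machine(seed: int = 0, tables=None) -> bd.MachineModel:
    """Mini machine: dense layers across the target depth window plus the
    layers needed for the 6 cm reference SOBP at 21 cm range."""
    ranges = np.concatenate(
        [np.arange(3.4, 8.8, 0.3), np.arange(14.6, 21.6, 0.25)]
    )
    return bd.generate_mini_machine(ranges_cm=ranges, seed=seed, tables=tables)


def opposed_beams_for_target(
    phantom: Phantom,
    machine: bd.MachineModel,
    target: str = "PTV",
    axis: int = 0,
    spot_pitch_mm: float = 5.0,
    lateral_margin_mm: float = 6.0,
    depth_margin_cm: float = 0.4,
) -> List[Beam]:
    """Parallel-opposed beams with energy layers covering the target depth."""
    mask = phantom.masks[target]
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) * np.asarray(phantom.spacing_mm)
    hi = (idx.max(axis=0) + 1) * np.asarray(phantom.spacing_mm)
    t1, t2 = [a for a in range(3) if a != axis]
    u_grid = np.arange(
        lo[t1] - lateral_margin_mm, hi[t1] + lateral_margin_mm + 1e-9, spot_pitch_mm
    )
    v_grid = np.arange(
        lo[t2] - lateral_margin_mm, hi[t2] + lateral_margin_mm + 1e-9, spot_pitch_mm
    )
    size_axis = phantom.rsp.shape[axis] * phantom.spacing_mm[axis]
    beams = []
    for direction in (+1, -1):
        if direction > 0:
            d_lo, d_hi = lo[axis] / 10.0, hi[axis] / 10.0
        else:
            d_lo, d_hi = (size_axis - hi[axis]) / 10.0, (size_axis - lo[axis]) / 10.0
        layers = [
            i
            for i, r in enumerate(machine.ranges_cm)
            if d_lo - depth_margin_cm <= r <= d_hi + depth_margin_cm
        ]
        if not layers:
            raise ValueError("machine has no layer reaching the target")
        spots = [
            Spot(i, float(u), float(v))
            for i in layers
            for u in u_grid
            for v in v_grid
        ]
        beams.append(Beam(axis, direction, spots))
    return beams


@dataclass
class AgreementResult:
    """Outcome of the water-phantom model-agreement experiment."""

    clinical_a: DoseGrid  # optimized model (MCF MKM), total plan
    clinical_b: DoseGrid  # recalculated model (mMKM), frozen physical dose
    physical: DoseGrid
    max_relative_difference_percent: float
    gamma_pass_percent: float
    d95_a: float
    d95_b: float
    refs: Dict[str, ReferenceRadiation]
    prescription_total: float


def water_phantom_model_agreement(
    seed: int = 0,
    machine: bd.MachineModel | None = None,
    clinical_per_fraction: float = 5.0,
    n_fractions: int = 1,
    optimize_model: str = "mcf_mkm",
    recalc_model: str = "mmkm",
    max_iter: int = 400,
) -> AgreementResult:
    """Run the parallel-opposed water-box comparison at 5 Gy(RBE)/fraction.

    Each field is optimized independently with ``optimize_model`` to the
    per-fraction clinical prescription; the spot weights are then frozen and
    the clinical dose recalculated with ``recalc_model``.  Per-field clinical
    doses are summed across beams and fractions for both models.
    """
    if machine is None:
        machine = default_experiment_machine(seed=seed)
    refs = {
        m: calibrate_reference(machine, m) for m in (optimize_model, recalc_model)
    }
    phantom = water_box_phantom(FixtureSpec())
    beams = opposed_beams_for_target(phantom, machine)

    prescription = Prescription(
        clinical_per_fraction=clinical_per_fraction,
        n_fractions=n_fractions,
        beams_per_fraction=len(beams),
        fractions_per_beam=tuple(n_fractions for _ in beams),
        ref=refs[optimize_model],
    )
    objective = ObjectiveSpec()

    total_a = phantom.grid()
    total_b = phantom.grid()
    physical = phantom.grid()
    for beam, n_frac in zip(beams, prescription.fractions_per_beam):
        result = optimize_field(
            phantom, beam, machine, optimize_model, prescription, objective,
            max_iter=max_iter,
        )
        fields = compute_fields(phantom, beam, machine, result.weights)
        clin_a = biological_dose(fields, optimize_model, refs[optimize_model])
        clin_b = biological_dose(fields, recalc_model, refs[recalc_model])
        total_a.values += n_frac * clin_a.values
        total_b.values += n_frac * clin_b.values
        physical.values += n_frac * fields.dose.values

    max_rel = max_relative_difference(total_a, total_b)
    _, pass_rate = gamma_map(total_a, total_b, GammaParams())
    ctv = phantom.masks["CTV"]
    total_rx = clinical_per_fraction * sum(prescription.fractions_per_beam)
    return AgreementResult(
        total_a,
        total_b,
        physical,
        max_rel,
        pass_rate,
        dose_at_volume(total_a, ctv, 95.0),
        dose_at_volume(total_b, ctv, 95.0),
        refs,
        total_rx,
    )
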