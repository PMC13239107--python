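"""End-to-end workflow: generate base data, plan, recalculate, compare.

Binds the stages of the model-comparison protocol into one reproducible run:
synthetic machine generation, reference calibration, per-field RBE-weighted
optimization with the planning model, recalculation with the comparison model
on the frozen physical dose, and the DVH / difference-map / gamma report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import base_data as bd
from . import io_formats as io
from .dose_engine import Phantom, biological_dose, compute_fields
from .evaluation import GammaParams, compare_report
from .experiments import opposed_beams_for_target
from .fixtures import FixtureSpec, water_box_phantom
from .optimizer import ObjectiveSpec, Prescription, calibrate_reference, optimize_field

log = logging.getLogger("mkmplan")


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    out_dir: str
    seed: int = 0
    optimize_model: str = "mcf_mkm"
    recalc_model: str = "mmkm"
    clinical_per_fraction: float = 5.0
    n_fractions: int = 1
    machine_file: Optional[str] = None  # regenerate if absent
    machine_ranges_cm: Optional[List[float]] = None
    phantom: FixtureSpec = field(default_factory=FixtureSpec)
    spot_pitch_mm: float = 5.0
    max_iter: int = 400
    log_level: str = "INFO"


def run_workflow(config: RunConfig):
    """Execute generate -> plan -> recalc -> compare; write all artifacts.

    Deterministic given (config, seed); every stage leaves a manifest next
    to its outputs.  Raises on any stage failure (callers map this to a
    non-zero exit status).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # -- stage 1: base data -------------------------------------------------
    if config.machine_file and Path(config.machine_file).exists():
        machine = bd.load_machine(config.machine_file)
        log.info("loaded machine with %d energies", len(machine.entries))
    else:
        ranges = config.machine_ranges_cm
        if ranges is None:
            ranges = np.concatenate(
                [np.arange(3.4, 8.8, 0.3), np.arange(14.6, 21.6, 0.25)]
            )
        machine = bd.generate_mini_machine(ranges_cm=ranges, seed=config.seed)
        mpath = out / "machine.h5"
        bd.save_machine(machine, str(mpath))
        log.info("generated machine (%d energies) in %.1f s",
                 len(machine.entries), time.time() - t0)
    io.write_manifest(out / "manifest_basedata.json", "generate-basedata",
                      machine.meta, config.seed, ["machine.h5"])

    # -- stage 2: references and plan --------------------------------------
    refs = {
        m: calibrate_reference(machine, m)
        for m in (config.optimize_model, config.recalc_model)
    }
    for m, r in refs.items():
        log.info("calibrated %s reference: alpha=%.4f beta=%.4f", m,
                 r.alpha_ref, r.beta_ref)

    phantom = water_box_phantom(config.phantom)
    beams = opposed_beams_for_target(
        phantom, machine, spot_pitch_mm=config.spot_pitch_mm
    )
    prescription = Prescription(
        clinical_per_fraction=config.clinical_per_fraction,
        n_fractions=config.n_fractions,
        beams_per_fraction=len(beams),
        fractions_per_beam=tuple(config.n_fractions for _ in beams),
        ref=refs[config.optimize_model],
    )
    objective = ObjectiveSpec()

    weights = []
    total_a = phantom.grid()
    total_b = phantom.grid()
    physical = phantom.grid()
    for i, beam in enumerate(beams):
        t1 = time.time()
        res = optimize_field(
            phantom, beam, machine, config.optimize_model, prescription,
            objective, max_iter=config.max_iter,
        )
        log.info("field %d: cost %.3e after %d iterations (%.1f s)",
                 i, res.cost, res.n_iterations, time.time() - t1)
        weights.append(res.weights)
        fields = compute_fields(phantom, beam, machine, res.weights)
        n_frac = prescription.fractions_per_beam[i]
        total_a.values += n_frac * biological_dose(
            fields, config.optimize_model, refs[config.optimize_model]
        ).values
        total_b.values += n_frac * biological_dose(
            fields, config.recalc_model, refs[config.recalc_model]
        ).values
        physical.values += n_frac * fields.dose.values

    io.save_plan(beams, weights, out / "plan.json",
                 meta={"model": config.optimize_model, "seed": config.seed})
    io.save_volume(physical, out / "physical_dose.nii")
    io.save_volume(total_a, out / f"clinical_{config.optimize_model}.nii")
    io.save_volume(total_b, out / f"clinical_{config.recalc_model}.nii")
    io.write_manifest(out / "manifest_plan.json", "plan",
                      {"prescription": prescription.total_clinical},
                      config.seed, ["plan.json", "physical_dose.nii"])

    # -- stage 3: comparison ------------------------------------------------
    total_rx = config.clinical_per_fraction * sum(prescription.fractions_per_beam)
    metrics = [
        ("CTV", "D", 95.0),
        ("CTV", "D", 2.0),
        ("PTV", "D", 95.0),
        ("PTV", "V", 0.95 * total_rx),
    ]
    report = compare_report(total_a, total_b, phantom.masks, metrics, GammaParams())
    report.table.to_csv(out / "metrics.csv", index=False)
    io.save_volume(report.difference, out / "difference.nii")
    io.save_volume(total_a.like(np.nan_to_num(report.gamma)), out / "gamma.nii")
    io.write_manifest(
        out / "manifest_compare.json", "compare",
        {"gamma_pass_percent": report.gamma_pass_percent,
         "max_relative_difference_percent": report.max_relative_difference_percent},
        config.seed, ["metrics.csv", "difference.nii", "gamma.nii"],
    )
    log.info("workflow complete in %.1f s (gamma pass %.1f%%)",
             time.time() - t0, report.gamma_pass_percent)
    return report
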