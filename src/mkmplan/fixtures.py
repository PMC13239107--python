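"""Deterministic synthetic phantoms, masks and prescription schedules.

Water-box phantoms with cubic targets emulate the validation geometry used
to commission RBE models before patient planning; the prescription table
carries the six clinical fractionation schedules (liver, lung, pancreas,
prostate, rectum, sarcoma) used for carbon-reference planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .dose_engine import Phantom
from .optimizer import Prescription
from .rbe_models import ReferenceRadiation


@dataclass(frozen=True)
class FixtureSpec:
    """Water-box phantom specification (sizes in mm)."""

    shape_mm: Tuple[float, float, float] = (120.0, 90.0, 90.0)
    spacing_mm: float = 3.0
    target_size_mm: float = 42.0
    target_center_mm: Optional[Tuple[float, float, float]] = None
    ptv_margin_mm: float = 3.0
    oar_shell: bool = False
    oar_gap_mm: float = 6.0
    oar_thickness_mm: float = 9.0
    seed: int = 0


def water_box_phantom(spec: FixtureSpec | None = None) -> Phantom:
    """Homogeneous water phantom with cubic CTV/PTV masks.

    The CTV is a centred cube (RSP = 1 everywhere); the PTV expands it by
    ``ptv_margin_mm``.  With ``oar_shell`` a hollow lateral shell OAR is
    added around the PTV, separated by ``oar_gap_mm`` and disjoint from it.
    """
    spec = spec or FixtureSpec()
    sp = spec.spacing_mm
    shape = tuple(int(round(s / sp)) for s in spec.shape_mm)
    rsp = np.ones(shape)
    center = (
        np.asarray(spec.target_center_mm)
        if spec.target_center_mm is not None
        else np.asarray(spec.shape_mm) / 2.0
    )
    half = spec.target_size_mm / 2.0
    if np.any(center - half < 0) or np.any(center + half > np.asarray(spec.shape_mm)):
        raise ValueError("target extends outside the phantom")
    coords = [sp * (np.arange(n) + 0.5) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")

    def box(half_width: float) -> np.ndarray:
        return (
            (np.abs(xx - center[0]) <= half_width)
            & (np.abs(yy - center[1]) <= half_width)
            & (np.abs(zz - center[2]) <= half_width)
        )

    ctv = box(half)
    ptv = box(half + spec.ptv_margin_mm)
    masks: Dict[str, np.ndarray] = {"CTV": ctv, "PTV": ptv}
    if spec.oar_shell:
        inner = half + spec.ptv_margin_mm + spec.oar_gap_mm
        outer = inner + spec.oar_thickness_mm
        masks["OAR_shell"] = box(outer) & ~box(inner)
    return Phantom(rsp, (sp, sp, sp), (0.0, 0.0, 0.0), masks)


#: Clinical schedule table: per-fraction Gy(RBE), fractions, number of beams,
#: beams per fraction, per-beam fraction counts.  The sarcoma row's
#: beams-per-fraction entry is absent in the source schedule and is stored
#: as 1.
TABLE1_SCHEDULES: Dict[str, Dict] = {
    "liver": dict(dose=15.0, fractions=4, beams=3, beams_per_fraction=2,
                  fractions_per_beam=(2, 2, 4)),
    "lung": dict(dose=15.0, fractions=4, beams=4, beams_per_fraction=2,
                 fractions_per_beam=(2, 2, 2, 2)),
    "pancreas": dict(dose=4.6, fractions=12, beams=4, beams_per_fraction=1,
                     fractions_per_beam=(3, 3, 3, 3)),
    "prostate": dict(dose=4.3, fractions=12, beams=2, beams_per_fraction=1,
                     fractions_per_beam=(6, 6)),
    "rectum": dict(dose=4.6, fractions=16, beams=3, beams_per_fraction=1,
                   fractions_per_beam=(7, 3, 6)),
    "sarcoma": dict(dose=4.4, fractions=16, beams=3, beams_per_fraction=1,
                    fractions_per_beam=(5, 5, 6)),
}


def table1_prescription(
    site: str, ref: ReferenceRadiation | None = None
) -> Prescription:
    """Prescription schedule for one of the six disease sites."""
    try:
        row = TABLE1_SCHEDULES[site.lower()]
    except KeyError:
        raise ValueError(
            f"unknown site {site!r}; choose from {sorted(TABLE1_SCHEDULES)}"
        ) from None
    if ref is None:
        ref = ReferenceRadiation.mcf_carbon()
    return Prescription(
        clinical_per_fraction=row["dose"],
        n_fractions=row["fractions"],
        beams_per_fraction=row["beams_per_fraction"],
        fractions_per_beam=tuple(row["fractions_per_beam"]),
        ref=ref,
        site=site.lower(),
    )
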