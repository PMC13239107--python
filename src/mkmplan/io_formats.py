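"""File formats: volumes (NIfTI), plans (JSON), configs (YAML), manifests.

Volumes are written as NIfTI-1 via nibabel with the voxel spacing encoded in
the affine; plans (beams + spot weights) and run manifests are plain JSON so
every artifact round-trips through its reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .dose_engine import Beam, DoseGrid, Phantom, Spot


def save_volume(grid: DoseGrid, path) -> None:
    """Write a scalar volume as NIfTI-1 (spacing in the affine diagonal)."""
    import nibabel as nib

    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    nib.save(nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), affine), str(path))


def load_volume(path) -> DoseGrid:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return DoseGrid(np.asarray(img.get_fdata()), spacing, origin)


def save_phantom(phantom: Phantom, path) -> None:
    """Phantom RSP volume plus one mask volume per structure (suffix files)."""
    base = Path(path)
    save_volume(DoseGrid(phantom.rsp, phantom.spacing_mm, phantom.origin_mm), base)
    sidecar = {"masks": sorted(phantom.masks)}
    for name, mask in phantom.masks.items():
        save_volume(
            DoseGrid(mask.astype(np.float64), phantom.spacing_mm, phantom.origin_mm),
            base.with_name(base.name.replace(".nii", f".mask_{name}.nii")),
        )
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path) -> Phantom:
    base = Path(path)
    vol = load_volume(base)
    names = json.loads(base.with_suffix(".json").read_text())["masks"]
    masks = {}
    for name in names:
        mpath = base.with_name(base.name.replace(".nii", f".mask_{name}.nii"))
        masks[name] = load_volume(mpath).values > 0.5
    return Phantom(vol.values, vol.spacing_mm, vol.origin_mm, masks)


def save_plan(beams: List[Beam], weights: List[np.ndarray], path, meta: Dict | None = None) -> None:
    """Plan JSON: per-beam geometry, spots and optimized weights."""
    doc = {
        "meta": meta or {},
        "beams": [
            {
                "axis": b.axis,
                "direction": b.direction,
                "spots": [
                    {
                        "energy_index": s.energy_index,
                        "u_mm": s.u_mm,
                        "v_mm": s.v_mm,
                        "weight": float(w_i),
                    }
                    for s, w_i in zip(b.spots, w)
                ],
            }
            for b, w in zip(beams, weights)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_plan(path) -> Tuple[List[Beam], List[np.ndarray], Dict]:
    doc = json.loads(Path(path).read_text())
    beams, weights = [], []
    for b in doc["beams"]:
        spots = [
            Spot(s["energy_index"], s["u_mm"], s["v_mm"], s["weight"])
            for s in b["spots"]
        ]
        beams.append(Beam(b["axis"], b["direction"], spots))
        weights.append(np.array([s["weight"] for s in b["spots"]]))
    return beams, weights, doc.get("meta", {})


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, stage: str, config, seed: int, outputs: List[str],
                   ok: bool = True) -> None:
    """Run manifest written next to each stage's outputs."""
    from . import __version__

    doc = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "outputs": outputs,
        "complete": ok,
    }
    Path(path).write_text(json.dumps(doc, indent=2))
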