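"""Synthetic machine base data for a scanned carbon-ion beamline.

For each nominal beam energy the generator produces, on a three-region depth
grid (entrance / Bragg peak / fragmentation tail):

* integrated depth dose (IDD, Gy mm^2 per primary),
* dose-averaged unrestricted LET,
* lateral Gaussian width sigma(z) from multiple-Coulomb-scattering growth on
  top of the nozzle spot size,
* per-depth mixed-field LQ tables alpha(z) and sqrt(beta)(z) for each RBE
  model, and
* per-species fragment dose fractions.

The depth dose is an analytic Bragg curve: stopping power of the slowing
primary, attenuated by nuclear interactions, convolved with Gaussian range
straggling, plus a parameterized charged-fragment build-up whose total energy
closes the nuclear-loss bookkeeping.  The fragment channel coefficients are
plumbing, not physics output of the package: they exist so the mixed-field
machinery is exercised with plausible compositions, and they are serialized
with the machine model so results reproduce exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .constants import X0_WATER_CM
from . import track_physics as tp
from .microdosimetry import SaturationParams, kc_track, single_event_spectrum, zd_star
from .rbe_models import ModelParams, mcf_alpha_beta

#: Machine energy window (MeV/u) and number of nominal energies.
E_MACHINE_MIN = 100.0
E_MACHINE_MAX = 430.0
N_MACHINE_ENERGIES = 161

#: Depth-grid conventions (cm).
BRAGG_REGION_CM = 4.0  # fixed window straddling the peak
BRAGG_RES_CM = 0.05
TAIL_REGION_CM = 8.0  # distal tail, ends 10 cm beyond the peak
TAIL_RES_CM = 1.0
N_ENTRANCE_BINS = 42  # constant bin count => 0.012 cm at 100 MeV/u, 0.68 at 430


@dataclass(frozen=True)
class DepthGrid:
    """Three-region depth binning: entrance / Bragg peak / distal tail."""

    edges_cm: np.ndarray
    n_entrance: int
    n_bragg: int

    @property
    def midpoints_cm(self) -> np.ndarray:
        return 0.5 * (self.edges_cm[:-1] + self.edges_cm[1:])

    @property
    def entrance_resolution_cm(self) -> float:
        return float(self.edges_cm[1] - self.edges_cm[0])

    @property
    def n_bins(self) -> int:
        return len(self.edges_cm) - 1


def make_depth_grid(e0_mev_u: float) -> DepthGrid:
    """Build the three-region grid for nominal energy ``e0_mev_u``.

    The entrance region ends 2 cm proximal to the Bragg peak (nominal CSDA
    range), the peak region is 4 cm at 0.05 cm resolution, and the tail
    extends 10 cm beyond the peak at 1 cm resolution.
    """
    if not (E_MACHINE_MIN <= e0_mev_u <= E_MACHINE_MAX):
        raise ValueError(
            f"nominal energy {e0_mev_u} outside machine range "
            f"[{E_MACHINE_MIN}, {E_MACHINE_MAX}] MeV/u"
        )
    r = tp.csda_range(tp.CARBON, e0_mev_u)
    entrance_end = r - BRAGG_REGION_CM / 2.0
    entrance = np.linspace(0.0, entrance_end, N_ENTRANCE_BINS + 1)
    n_bragg = int(round(BRAGG_REGION_CM / BRAGG_RES_CM))
    bragg = entrance_end + BRAGG_RES_CM * np.arange(1, n_bragg + 1)
    n_tail = int(round(TAIL_REGION_CM / TAIL_RES_CM))
    tail = bragg[-1] + TAIL_RES_CM * np.arange(1, n_tail + 1)
    edges = np.concatenate([entrance, bragg, tail])
    return DepthGrid(edges, N_ENTRANCE_BINS, n_bragg)


@dataclass(frozen=True)
class FragmentChannel:
    """One projectile-fragment species channel of the build-up model."""

    z: int
    energy_share: float  # share of the redistributed nuclear-loss energy
    buildup_power: float  # dose fraction grows as (z/R)^p up to the peak
    tail_length_cm: float  # exponential decay length beyond the peak


@dataclass(frozen=True)
class FragmentModel:
    """Charged-fragment dose build-up stand-in (serialized with the machine).

    A fraction ``eta`` of the energy removed from the primary beam by nuclear
    interactions reappears as charged-fragment dose distributed over the
    species channels; the remainder escapes (neutrals, large-angle products).
    """

    channels: Sequence[FragmentChannel] = (
        FragmentChannel(1, 0.30, 0.7, 5.0),
        FragmentChannel(2, 0.30, 0.8, 4.0),
        FragmentChannel(3, 0.13, 1.0, 2.0),
        FragmentChannel(4, 0.12, 1.2, 1.5),
        FragmentChannel(5, 0.15, 1.5, 1.0),
    )
    eta: float = 0.8

    def __post_init__(self) -> None:
        shares = sum(c.energy_share for c in self.channels)
        if self.channels and abs(shares - 1.0) > 1e-9:
            raise ValueError("fragment energy shares must sum to 1")

    @classmethod
    def disabled(cls) -> "FragmentModel":
        return cls(channels=(), eta=0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic base-data generator."""

    e_min: float = E_MACHINE_MIN
    e_max: float = E_MACHINE_MAX
    n_energies: int = N_MACHINE_ENERGIES
    spot_sigma_mm: float = 3.0  # nozzle spot size (config placeholder)
    straggling_frac: float = 0.0045  # sigma_R / R: straggling + energy spread
    min_range_sigma_cm: float = 0.12  # ripple-filter-equivalent peak broadening
    nuclear_mfp_cm: float = 25.5  # carbon nuclear mean free path in water
    fragments: FragmentModel = field(default_factory=FragmentModel)
    y0_kev_um: float = 150.0  # mMKM saturation parameter
    n_quality_energies: int = 48
    seed: int = 0


@dataclass
class BeamEnergyEntry:
    """Base data of one nominal beam energy."""

    energy_mev_u: float
    grid: DepthGrid
    idd: np.ndarray  # Gy mm^2 per primary, at bin midpoints
    let_kev_um: np.ndarray
    sigma_mm: np.ndarray
    alpha: Dict[str, np.ndarray]  # per model, Gy^-1
    sqrt_beta: Dict[str, np.ndarray]  # per model, Gy^-1
    fractions: Dict[int, np.ndarray]  # per species Z (6 = primary)
    peak_depth_cm: float

    @property
    def depth_cm(self) -> np.ndarray:
        return self.grid.midpoints_cm


@dataclass
class MachineModel:
    """Full set of per-energy base data plus generator provenance."""

    entries: List[BeamEnergyEntry]
    meta: Dict

    def __post_init__(self) -> None:
        e = self.energies
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")

    @property
    def energies(self) -> np.ndarray:
        return np.array([en.energy_mev_u for en in self.entries])

    @property
    def ranges_cm(self) -> np.ndarray:
        return np.array([en.peak_depth_cm for en in self.entries])

    def entry_for_range(self, range_cm: float) -> BeamEnergyEntry:
        """Entry whose Bragg peak is closest to the requested depth."""
        return self.entries[int(np.argmin(np.abs(self.ranges_cm - range_cm)))]


# ---------------------------------------------------------------------------
# radiation-quality tables (per species, per model)
# ---------------------------------------------------------------------------


@dataclass
class QualityTable:
    """Per-species LQ coefficients versus kinetic energy for one model."""

    model: str
    energies: np.ndarray
    alpha: Dict[int, np.ndarray]
    sqrt_beta: Dict[int, np.ndarray]
    zd_star: Dict[int, np.ndarray]  # populated for the mMKM

    def interp(self, z: int, e):
        """(alpha, sqrt_beta) interpolated at energy ``e`` for species Z."""
        le = np.log(np.clip(e, self.energies[0], self.energies[-1]))
        lg = np.log(self.energies)
        return np.interp(le, lg, self.alpha[z]), np.interp(le, lg, self.sqrt_beta[z])


def build_quality_tables(
    models: Dict[str, ModelParams],
    config: GeneratorConfig | None = None,
) -> Dict[str, QualityTable]:
    """Tabulate per-ion LQ coefficients on a log energy grid for each model.

    mMKM: alpha = alpha0 + beta0 * z*_D(E) with z*_D from the KC single-event
    machinery; beta = beta0.  MCF MKM: alpha, beta from the lineal-energy
    spectrum integrals.
    """
    config = config or GeneratorConfig()
    energies = np.geomspace(1.0, 450.0, config.n_quality_energies)
    sat = SaturationParams(config.y0_kev_um)
    tables: Dict[str, QualityTable] = {}
    for name, params in models.items():
        geom = params.geometry
        alpha: Dict[int, np.ndarray] = {}
        sqrt_beta: Dict[int, np.ndarray] = {}
        zds: Dict[int, np.ndarray] = {}
        for z, species in tp.SPECIES_BY_Z.items():
            a = np.empty_like(energies)
            sb = np.empty_like(energies)
            zd = np.empty_like(energies)
            for i, e in enumerate(energies):
                track = kc_track(species, e)
                if name == "mmkm":
                    zd[i] = zd_star(track, geom, sat)
                    a[i] = params.alpha0 + params.beta0 * zd[i]
                    sb[i] = np.sqrt(params.beta0)
                else:
                    spec = single_event_spectrum(track, geom)
                    q = mcf_alpha_beta(spec, params)
                    a[i] = q.alpha
                    sb[i] = np.sqrt(q.beta)
                    zd[i] = np.nan
            alpha[z] = a
            sqrt_beta[z] = sb
            zds[z] = zd
        tables[name] = QualityTable(name, energies, alpha, sqrt_beta, zds)
    return tables


# ---------------------------------------------------------------------------
# depth-dose, fragments, lateral spread
# ---------------------------------------------------------------------------

_FINE_DZ_CM = 0.01
_MEV_PER_CM_TO_GY_MM2 = 1.602e-8  # 1 MeV/cm deposited in water, per primary


def _fine_depth_curves(e0: float, config: GeneratorConfig):
    """Primary/fragment linear energy deposition (MeV/cm) on a fine grid."""
    r0 = tp.csda_range(tp.CARBON, e0)
    z = np.arange(0.0, r0 + TAIL_REGION_CM / TAIL_RES_CM * TAIL_RES_CM + 2.2, _FINE_DZ_CM)
    residual = np.clip(r0 - z, 0.0, None)
    e_z = tp.range_to_energy(tp.CARBON, residual)
    primary_alive = z < r0
    survival = np.exp(-z / config.nuclear_mfp_cm)

    s = np.zeros_like(z)
    mask = primary_alive & (e_z > tp.E_MIN_MEV_U)
    s[mask] = tp.stopping_power(tp.CARBON, e_z[mask])
    primary = s * survival  # MeV/cm per incident primary at rho=1

    # straggling, source energy spread and ripple filter as range smearing
    sigma_cm = max(config.straggling_frac * r0, config.min_range_sigma_cm, _FINE_DZ_CM)
    half = int(np.ceil(4.0 * sigma_cm / _FINE_DZ_CM))
    kern_x = np.arange(-half, half + 1) * _FINE_DZ_CM
    kern = np.exp(-0.5 * (kern_x / sigma_cm) ** 2)
    kern /= kern.sum()
    primary_conv = np.convolve(primary, kern, mode="same")

    # nuclear bookkeeping: energy removed with absorbed primaries
    removal_rate = survival / config.nuclear_mfp_cm * tp.CARBON.a * e_z
    removal_rate[~primary_alive] = 0.0
    e_removed = np.trapezoid(removal_rate, z)

    frag_doses: Dict[int, np.ndarray] = {}
    fm = config.fragments
    if fm.channels and fm.eta > 0 and e_removed > 0:
        for ch in fm.channels:
            shape = np.where(
                z <= r0,
                (np.clip(z, 0, r0) / r0) ** ch.buildup_power,
                np.exp(-(z - r0) / ch.tail_length_cm),
            )
            norm = np.trapezoid(shape, z)
            frag_doses[ch.z] = fm.eta * e_removed * ch.energy_share * shape / norm
    total = primary_conv + sum(frag_doses.values(), np.zeros_like(z))
    return z, e_z, primary_conv, frag_doses, total, r0


def generate_idd(e0: float, config: GeneratorConfig | None = None):
    """Analytic IDD and fragment dose fractions on the three-region grid.

    Returns (grid, idd, fractions) with ``idd`` in Gy mm^2 per primary and
    ``fractions`` a dict Z -> dose fraction per depth bin (Z=6 is the
    primary; fractions sum to 1 wherever there is dose).
    """
    config = config or GeneratorConfig()
    grid = make_depth_grid(e0)
    z, _, primary, frag_doses, total, _ = _fine_depth_curves(e0, config)

    def bin_mean(curve: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(grid.edges_cm, z, side="right") - 1, 0, grid.n_bins - 1)
        sums = np.bincount(idx, weights=curve, minlength=grid.n_bins)
        counts = np.bincount(idx, minlength=grid.n_bins)
        return sums / np.maximum(counts, 1)

    total_b = bin_mean(total)
    idd = total_b * _MEV_PER_CM_TO_GY_MM2
    fractions: Dict[int, np.ndarray] = {}
    denom = np.maximum(total_b, 1e-300)
    for zq, curve in frag_doses.items():
        fractions[zq] = bin_mean(curve) / denom
    fractions[tp.CARBON.z] = bin_mean(primary) / denom
    return grid, idd, fractions


def generate_lateral_sigma(
    e0: float, grid: DepthGrid, config: GeneratorConfig | None = None
) -> np.ndarray:
    """Lateral Gaussian width sigma(z) in mm on the depth grid.

    Quadrature sum of the nozzle spot size and the multiple-Coulomb-
    scattering envelope from Fermi-Eyges transport of the Highland
    scattering power; frozen beyond the primary range.
    """
    config = config or GeneratorConfig()
    r0 = tp.csda_range(tp.CARBON, e0)
    z = np.arange(0.0, grid.edges_cm[-1] + _FINE_DZ_CM, _FINE_DZ_CM)
    residual = np.clip(r0 - z, 0.0, None)
    e_z = np.maximum(tp.range_to_energy(tp.CARBON, residual), 1.0)
    # pv (MeV): A * E(E + 2 m_u) / (E + m_u) per the relativistic identity
    from .constants import AMU_MEV

    pv = tp.CARBON.a * e_z * (e_z + 2 * AMU_MEV) / (e_z + AMU_MEV)
    t_power = np.where(z < r0, (14.1 * tp.CARBON.z / pv) ** 2 / X0_WATER_CM, 0.0)
    # sigma^2(d) = int_0^d T(z)(d - z)^2 dz expanded into running moments
    c0 = np.cumsum(t_power) * _FINE_DZ_CM
    c1 = np.cumsum(t_power * z) * _FINE_DZ_CM
    c2 = np.cumsum(t_power * z**2) * _FINE_DZ_CM
    var_cm2 = z**2 * c0 - 2 * z * c1 + c2
    var_frozen = np.where(z < r0, var_cm2, np.interp(r0, z, var_cm2))
    sigma_mm = np.sqrt(config.spot_sigma_mm**2 + var_frozen * 100.0)
    return np.interp(grid.midpoints_cm, z, sigma_mm)


def generate_bio_tables(
    e0: float,
    grid: DepthGrid,
    fractions: Dict[int, np.ndarray],
    tables: Dict[str, QualityTable],
    config: GeneratorConfig | None = None,
):
    """Mixed-field alpha(z) and sqrt(beta)(z) per model on the depth grid.

    At each depth the residual energy of every species present is converted
    to its LQ coefficients via the quality tables, then combined with the
    fragment dose fractions by dose weighting (alpha linearly, sqrt(beta)
    linearly).
    """
    config = config or GeneratorConfig()
    r0 = tp.csda_range(tp.CARBON, e0)
    depth = grid.midpoints_cm
    e_primary = np.maximum(
        tp.range_to_energy(tp.CARBON, np.clip(r0 - depth, 1e-4, None)), 1.0
    )
    frag_cfg = {c.z: c for c in config.fragments.channels}

    energies: Dict[int, np.ndarray] = {tp.CARBON.z: e_primary}
    for zq in fractions:
        if zq == tp.CARBON.z:
            continue
        ch = frag_cfg.get(zq)
        stop_depth = r0 + 3.0 * (ch.tail_length_cm if ch else 1.0)
        species = tp.SPECIES_BY_Z[zq]
        energies[zq] = np.maximum(
            tp.range_to_energy(species, np.clip(stop_depth - depth, 1e-4, None)), 1.0
        )

    alpha: Dict[str, np.ndarray] = {}
    sqrt_beta: Dict[str, np.ndarray] = {}
    for name, table in tables.items():
        num_a = np.zeros_like(depth)
        num_sb = np.zeros_like(depth)
        denom = np.zeros_like(depth)
        for zq, frac in fractions.items():
            a_i, sb_i = table.interp(zq, energies[zq])
            num_a += frac * a_i
            num_sb += frac * sb_i
            denom += frac
        denom = np.maximum(denom, 1e-12)
        alpha[name] = num_a / denom
        sqrt_beta[name] = num_sb / denom
    return alpha, sqrt_beta


def generate_entry(
    e0: float, tables: Dict[str, QualityTable], config: GeneratorConfig | None = None
) -> BeamEnergyEntry:
    """Full base-data entry for one nominal energy."""
    config = config or GeneratorConfig()
    grid, idd, fractions = generate_idd(e0, config)
    sigma = generate_lateral_sigma(e0, grid, config)
    alpha, sqrt_beta = generate_bio_tables(e0, grid, fractions, tables, config)

    depth = grid.midpoints_cm
    r0 = tp.csda_range(tp.CARBON, e0)
    e_primary = np.maximum(
        tp.range_to_energy(tp.CARBON, np.clip(r0 - depth, 1e-4, None)), 1.0
    )
    let = np.zeros_like(depth)
    let_primary = tp.unrestricted_let(tp.CARBON, e_primary)
    frag_cfg = {c.z: c for c in config.fragments.channels}
    for zq, frac in fractions.items():
        if zq == tp.CARBON.z:
            let += frac * let_primary
        else:
            ch = frag_cfg.get(zq)
            stop_depth = r0 + 3.0 * (ch.tail_length_cm if ch else 1.0)
            sp = tp.SPECIES_BY_Z[zq]
            e_f = np.maximum(
                tp.range_to_energy(sp, np.clip(stop_depth - depth, 1e-4, None)), 1.0
            )
            let += frac * tp.unrestricted_let(sp, e_f)

    peak = float(depth[int(np.argmax(idd))])
    return BeamEnergyEntry(
        float(e0), grid, idd, let, sigma, alpha, sqrt_beta, fractions, peak
    )


def generate_machine(
    config: GeneratorConfig | None = None,
    models: Dict[str, ModelParams] | None = None,
    tables: Dict[str, QualityTable] | None = None,
) -> MachineModel:
    """Generate the full machine model (deterministic given the config).

    ``tables`` may be passed to reuse precomputed radiation-quality tables.
    """
    config = config or GeneratorConfig()
    if models is None:
        models = {"mmkm": ModelParams.mmkm_hsg(), "mcf_mkm": ModelParams.mcf_hsg()}
    if tables is None:
        tables = build_quality_tables(models, config)
    energies = np.linspace(config.e_min, config.e_max, config.n_energies)
    entries = [generate_entry(e, tables, config) for e in energies]
    meta = {
        "generator": "mkmplan-synthetic",
        "version": 1,
        "seed": config.seed,
        "config": _config_dict(config),
        "models": {k: asdict(v) for k, v in models.items()},
    }
    return MachineModel(entries, meta)


def mini_machine_config(
    ranges_cm: Sequence[float] | None = None, seed: int = 0
) -> GeneratorConfig:
    """Small machine (desk-scale) covering the given Bragg-peak ranges."""
    if ranges_cm is None:
        ranges_cm = np.geomspace(3.0, 22.0, 16)
    energies = np.sort(
        [float(tp.range_to_energy(tp.CARBON, r)) for r in np.atleast_1d(ranges_cm)]
    )
    return GeneratorConfig(
        e_min=float(energies[0]), e_max=float(energies[-1]), n_energies=len(energies),
        seed=seed,
    )


def generate_mini_machine(
    ranges_cm: Sequence[float] | None = None,
    models: Dict[str, ModelParams] | None = None,
    seed: int = 0,
    tables: Dict[str, QualityTable] | None = None,
) -> MachineModel:
    """Convenience: generate a small machine at the requested ranges."""
    if ranges_cm is None:
        ranges_cm = np.geomspace(3.0, 22.0, 16)
    energies = np.sort(
        [float(tp.range_to_energy(tp.CARBON, r)) for r in np.atleast_1d(ranges_cm)]
    )
    cfg = GeneratorConfig(
        e_min=float(energies[0]), e_max=float(energies[-1]), n_energies=len(energies),
        seed=seed,
    )
    if models is None:
        models = {"mmkm": ModelParams.mmkm_hsg(), "mcf_mkm": ModelParams.mcf_hsg()}
    if tables is None:
        tables = build_quality_tables(models, cfg)
    entries = [generate_entry(e, tables, cfg) for e in energies]
    meta = {
        "generator": "mkmplan-synthetic-mini",
        "version": 1,
        "seed": seed,
        "config": _config_dict(cfg),
        "models": {k: asdict(v) for k, v in models.items()},
    }
    return MachineModel(entries, meta)


def _config_dict(config: GeneratorConfig) -> Dict:
    d = asdict(config)
    d["fragments"] = {
        "eta": config.fragments.eta,
        "channels": [asdict(c) for c in config.fragments.channels],
    }
    return d


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------


def save_machine(machine: MachineModel, path: str) -> None:
    """Write the machine model to HDF5 with a JSON sidecar of the config."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps(machine.meta)
        for i, entry in enumerate(machine.entries):
            g = f.create_group(f"beam_{i:03d}")
            g.attrs["energy_mev_u"] = entry.energy_mev_u
            g.attrs["peak_depth_cm"] = entry.peak_depth_cm
            g.attrs["n_entrance"] = entry.grid.n_entrance
            g.attrs["n_bragg"] = entry.grid.n_bragg
            g.create_dataset("depth_edges_cm", data=entry.grid.edges_cm)
            g.create_dataset("idd_gy_mm2", data=entry.idd)
            g.create_dataset("let_kev_um", data=entry.let_kev_um)
            g.create_dataset("sigma_mm", data=entry.sigma_mm)
            for model, arr in entry.alpha.items():
                g.create_dataset(f"alpha/{model}", data=arr)
            for model, arr in entry.sqrt_beta.items():
                g.create_dataset(f"sqrt_beta/{model}", data=arr)
            for z, arr in entry.fractions.items():
                g.create_dataset(f"fractions/{z}", data=arr)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(machine.meta, fh, indent=2)


def load_machine(path: str) -> MachineModel:
    """Read a machine model written by :func:`save_machine`."""
    import h5py

    entries: List[BeamEnergyEntry] = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        for key in sorted(k for k in f.keys() if k.startswith("beam_")):
            g = f[key]
            grid = DepthGrid(
                g["depth_edges_cm"][()],
                int(g.attrs["n_entrance"]),
                int(g.attrs["n_bragg"]),
            )
            entries.append(
                BeamEnergyEntry(
                    float(g.attrs["energy_mev_u"]),
                    grid,
                    g["idd_gy_mm2"][()],
                    g["let_kev_um"][()],
                    g["sigma_mm"][()],
                    {m: g[f"alpha/{m}"][()] for m in g["alpha"]},
                    {m: g[f"sqrt_beta/{m}"][()] for m in g["sqrt_beta"]},
                    {int(z): g[f"fractions/{z}"][()] for z in g["fractions"]},
                    float(g.attrs["peak_depth_cm"]),
                )
            )
    return MachineModel(entries, meta)
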