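"""Amorphous-track microdosimetry: radial dose, spectra and z*_D.

Builds Kiefer-Chatterjee track structures for carbon at several energies,
computes the single-event lineal-energy spectrum in a cylindrical sub-
nuclear domain (r_d = 0.32 um, length = diameter), and prints the
saturation-corrected dose-mean specific energy z*_D -- the radiation-quality
input of the mMKM.  The non-monotonic z*_D(E) is the overkill effect: below
~10 MeV/u the energy deposition is so dense that extra local dose kills no
additional cells, so the saturation correction caps the effectiveness.
"""

from mkmplan import (
    CARBON,
    DomainGeometry,
    SaturationParams,
    kc_track,
    single_event_spectrum,
    zd_star,
)

geom = DomainGeometry(radius_um=0.32, nucleus_radius_um=3.9)
sat = SaturationParams(y0_kev_um=150.0)

print("Carbon tracks in a 0.32 um domain (y0 = 150 keV/um)")
print(f"{'E (MeV/u)':>10} {'LET':>8} {'r_p (um)':>9} {'y_D':>8} {'z_D':>8} {'z*_D':>8}")
for e in [3, 10, 30, 100, 430]:
    track = kc_track(CARBON, e)
    spec = single_event_spectrum(track, geom)
    z_d = zd_star(track, geom, None)  # unsaturated dose mean
    z_star = zd_star(track, geom, sat)
    print(
        f"{e:>10} {track.let_kev_um:>8.1f} {track.r_penumbra_um:>9.2f}"
        f" {spec.dose_mean_y():>8.2f} {z_d:>8.2f} {z_star:>8.2f}"
    )

print(
    "\nz*_D rises as the ions slow down, peaks near 10 MeV/u and is then\n"
    "clamped by saturation (overkill) despite the still-increasing LET;\n"
    "the unsaturated z_D keeps growing."
)
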