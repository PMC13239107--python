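"""The two RBE models side by side: alpha(E), beta(E), RBE and clinical dose.

Computes the LQ coefficients of the mMKM (alpha = alpha0 + beta0 z*_D,
constant beta) and the MCF MKM (spectrum integrals with the saturation
factor c(y); both alpha and beta vary) for carbon at several energies, then
converts a 2 Gy absorbed dose to RBE-weighted and clinical dose against the
published carbon reference radiations.
"""

from mkmplan import (
    CARBON,
    ModelParams,
    QualityPoint,
    ReferenceRadiation,
    SaturationParams,
    alpha_mmkm,
    clinical_dose,
    kc_track,
    mcf_alpha_beta,
    rbe_d,
    single_event_spectrum,
    zd_star,
)

mmkm = ModelParams.mmkm_hsg()
mcf = ModelParams.mcf_hsg()
sat = SaturationParams(150.0)

print("Carbon radiation quality (HSG cell line)")
print(f"{'E (MeV/u)':>10} {'a_mMKM':>8} {'a_MCF':>8} {'b_mMKM':>8} {'b_MCF':>8}")
quality = {}
for e in [10, 50, 150, 430]:
    track = kc_track(CARBON, e)
    a_m = alpha_mmkm(zd_star(track, mmkm.geometry, sat), mmkm)
    q_mcf = mcf_alpha_beta(single_event_spectrum(track, mcf.geometry), mcf)
    quality[e] = (QualityPoint(a_m, mmkm.beta0), q_mcf)
    print(
        f"{e:>10} {a_m:>8.3f} {q_mcf.alpha:>8.3f}"
        f" {mmkm.beta0:>8.4f} {q_mcf.beta:>8.4f}"
    )

print("\n2 Gy absorbed dose at 50 MeV/u, referenced to the carbon SOBP midpoint:")
for name, q, ref in [
    ("mMKM", quality[50][0], ReferenceRadiation.mmkm_carbon()),
    ("MCF MKM", quality[50][1], ReferenceRadiation.mcf_carbon()),
]:
    rbe = rbe_d(2.0, q, ref)
    clin = clinical_dose(2.0, rbe, ref)
    print(f"  {name:8s} RBE = {rbe:.3f}  clinical dose = {clin:.2f} Gy(RBE)")

print(
    "\nRBE here is relative to the carbon reference radiation (mid-SOBP),"
    "\nand the clinical dose applies the carbon-reference scaling factor 2.41."
)
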