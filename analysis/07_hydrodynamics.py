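"""Stokes-Einstein calculations for the riboflavin-synthase assemblies.

From the measured diffusion coefficient of the encapsulated synthase
(0.51 um^2/s) and the published capsid radius (7.8 nm) the effective
cytoplasmic viscosity follows; inverting with the capsid-with-FP
coefficient (0.38 um^2/s) gives that assembly's hydrodynamic radius and,
by subtraction, the fluorescent-tag contribution.  Mass-scaling ratios
predict the labelled capsid's D from the unlabelled one.
"""

import json
from pathlib import Path

from sptconfine import hydro

RESULTS = Path(__file__).resolve().parents[1] / "results"

# subunit masses (Da): native RibH, RibH-mV fusion, RibE-mV fusion, native RibE
RIBH, RIBH_MV, RIBE_MV, RIBE = 16_286, 43_403, 50_998, 23_812


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    eta = hydro.invert_viscosity(hydro.um2s_to_m2s(0.51), 7.8e-9)
    r_capsid_mv = hydro.invert_radius(
        hydro.um2s_to_m2s(0.38), hydro.PhysicalConditions(viscosity=eta))
    linker = r_capsid_mv - 7.8e-9

    heavy_native_mv_tag = hydro.OligomerMass(((RIBH, 60), (RIBE_MV, 3)))
    heavy_fluorescent = hydro.OligomerMass(((RIBH_MV, 60), (RIBE, 3)))
    ratio3 = hydro.mass_scaling_ratio(heavy_native_mv_tag, heavy_fluorescent, 3)
    ratio2 = hydro.mass_scaling_ratio(heavy_native_mv_tag, heavy_fluorescent, 2)

    d_water = hydro.m2s_to_um2s(
        hydro.stokes_einstein_D(7.8e-9, hydro.PhysicalConditions()))
    eta_check = hydro.viscosity_from_logratio(d_water, 0.51)

    out = {
        "cytoplasm_viscosity_Pa_s": eta,
        "capsid_mV_radius_nm": r_capsid_mv * 1e9,
        "linker_mV_contribution_nm": linker * 1e9,
        "mass_ratio_cubic": ratio3,
        "mass_ratio_squared": ratio2,
        "predicted_D_capsid_mV_um2_s": 0.51 * ratio3,
        "D_water_7p8nm_um2_s": d_water,
        "viscosity_from_logratio_Pa_s": eta_check,
    }
    (RESULTS / "hydro.json").write_text(json.dumps(out, indent=2))

    print(f"cytoplasmic viscosity: {eta:.4f} Pa s")
    print(f"hydrodynamic radius of the labelled capsid: {r_capsid_mv * 1e9:.3f} nm "
          f"-> tag contribution {linker * 1e9:.3f} nm")
    print(f"cubic mass-scaling ratio {ratio3:.4f} -> predicted D "
          f"{0.51 * ratio3:.3f} um^2/s (squared relation: {ratio2:.4f})")
    print(f"log-ratio viscosity check: {eta_check:.4f} Pa s")
    print("wrote hydro.json")


if __name__ == "__main__":
    main()
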