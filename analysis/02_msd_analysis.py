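"""MSD analysis of the simulated dataset.

Computes the ensemble-averaged MSD with a five-lag linear fit (overall D),
and estimates the mean localization error from per-track TAMSD intercepts
(the quantity that later sets the confinement radius).  Writes the EAMSD
curve and a fit summary under results/.

Run analysis/01_simulate_tracks.py first.
"""

import json
from pathlib import Path

import pandas as pd

import sptconfine as spt
from sptconfine.msd import eamsd, estimate_localization_error, fit_linear_msd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = spt.read_trajectories(RESULTS / "tracks.csv")
    ds5 = spt.filter_min_steps(ds, 5)
    print(f"{len(ds)} tracks read, {len(ds5)} with >= 5 steps")

    curve = eamsd(ds5, max_lag=10)
    fit = fit_linear_msd(curve, n_lags=5)
    pd.DataFrame({"lag_s": curve.lags, "msd_um2": curve.msd,
                  "sd_um2": curve.sd, "n_pairs": curve.n_pairs}) \
        .to_csv(RESULTS / "eamsd.tsv", sep="\t", index=False)

    loc = estimate_localization_error(ds5)
    summary = {
        "D_eamsd_um2_s": fit.D,
        "intercept_um2": fit.intercept,
        "r_value": fit.r_value,
        "mean_localization_error_um": loc.mean_sigma,
        "n_tracks_sigma": len(loc.per_track_sigma),
    }
    (RESULTS / "msd_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"EAMSD 5-lag fit: D = {fit.D:.3f} um^2/s (R = {fit.r_value:.4f}), "
          f"intercept {fit.intercept:.4f} um^2")
    print(f"mean localization error sigma = {loc.mean_sigma * 1000:.1f} nm "
          f"(injected: 50 nm; intercept also absorbs wall effects)")
    print("wrote eamsd.tsv, msd_summary.json")


if __name__ == "__main__":
    main()
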