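#!/usr/bin/env python
"""Fit the space-to-event and time-to-event models across all scenarios.

Reads the simulated study from results/study_sim/, runs STE under the three
viewshed scenarios and TTE under three movement rates × three scenarios for
the grouped species (and one STE fit for the solitary species), and writes
results/event_models.csv.  Expect the TTE estimates to be far above the STE
ones: the simulated cameras sit on trails the animals preferentially use,
which inflates the encounter hazard that TTE converts into density.
"""

from pathlib import Path

from camdensity import run_matrix

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "study_sim"

CONFIG = {
    "deployments": str(SIM / "deployments.csv"),
    "detections": str(SIM / "detections.csv"),
    "study_area_km2": 351.0,
    "seed": 42,
    "species": {
        "dhole": {
            "methods": ["ste", "tte"],
            "viewsheds": ["largest", "largest+10%", "largest+20%"],
            "movement_rates_m_per_hr": [266.0, 424.0, 791.7],
        },
        "leopard": {
            "methods": ["ste"],
            "viewsheds": ["largest", "largest+10%", "largest+20%"],
        },
    },
}


def main() -> None:
    table = run_matrix(CONFIG)
    out = ROOT / "results" / "event_models.csv"
    table.to_csv(out)
    df = table.table
    print(f"wrote {out} ({len(df)} rows)")
    ste = df[(df.method == "STE") & (df.species == "dhole")]
    tte = df[df.method == "TTE"]
    print("grouped species, STE by scenario:")
    for _, r in ste.iterrows():
        print(f"  {r.viewshed:>13}: N = {r.N_hat:7.1f} ± {r.SE_N:5.1f}  "
              f"D = {r.density_100km2:6.2f}/100 km²")
    print(f"TTE spread across rates/scenarios: N {tte.N_hat.min():.0f}–{tte.N_hat.max():.0f} "
          "(trail-biased, inflated as expected)")


if __name__ == "__main__":
    main()
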