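"""Generate the synthetic study inputs for the downstream analyses.

Writes one bundle per region under scratch/data/: the two incidence
registries (inner-London catchment with fractional postcode-sector
weights, and the suburban/rural register), the survival register, and the
UK-scale standard population, population projection, and period life
table.  Everything downstream (02-04) reads these files.
"""

import argparse
import json
from pathlib import Path

import als_epi as ae

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "data")
    args = parser.parse_args()

    for preset in ("lsl", "canterbury", "seals"):
        out = args.out / preset
        out.mkdir(parents=True, exist_ok=True)
        config = ae.GeneratorConfig.preset(preset, seed=args.seed)
        frame, truth = ae.gen_registry(config)
        frame.to_csv(out / "registry.csv", index=False)
        ae.gen_sector_overlaps(config).to_csv(out / "sector_overlaps.csv", index=False)
        ae.gen_population(config).to_csv(out / "population.csv", index=False)
        (out / "truth.json").write_text(json.dumps(
            {k: v for k, v in truth.items() if isinstance(v, (int, float, str, dict))},
            indent=2, default=str,
        ))
        print(f"{preset}: {len(frame)} registry rows "
              f"({truth['kept_incidence']} kept for incidence, "
              f"{truth['kept_survival']} for survival)")

    out = args.out / "uk"
    out.mkdir(parents=True, exist_ok=True)
    config = ae.GeneratorConfig.preset("uk", seed=args.seed)
    ae.gen_standard_population(config).to_csv(out / "standard_population.csv", index=False)
    projection, truth = ae.gen_projection(config)
    projection.to_csv(out / "projection.csv", index=False)
    ae.gen_life_table(config).to_csv(out / "life_table.csv", index=False)
    print(f"uk: projection calibrated to {truth['incident_2020']:.0f} incident "
          f"cases and {truth['prevalence_2020']} per 100,000 prevalence in 2020")


if __name__ == "__main__":
    main()
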