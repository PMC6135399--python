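"""Simulate both field trials: site weather and replicated plant harvests.

Writes weather.csv and plants.csv per trial.  The sowing-date trial has
2 treatments x 5 replicates x 10 plants per harvest from 24 DAS; the
irrigation trial 2 x 6 x 10 from 54 DAS.  Noise magnitudes equal the
published fit RMSEs, so downstream fits should reach the published
determination levels.
"""

from _common import DESIGNS, SEED, outdir, trial_thermal, trial_weather

from chiagrow import generate_plant_data
from chiagrow.weather import weather_to_frame


def main() -> None:
    for trial, make_design in DESIGNS.items():
        design = make_design()
        out = outdir(trial)
        weather = trial_weather(design)
        weather_to_frame(weather).to_csv(out / "weather.csv", index=False)
        thermal = trial_thermal(design, weather)
        plants = generate_plant_data(design, thermal, seed=SEED)
        plants.to_csv(out / "plants.csv", index=False)
        n_harvests = len(design.harvest_das())
        print(
            f"{trial}: {len(weather)} weather days at {design.site.name}; "
            f"{len(plants)} plant records "
            f"({len(design.treatments)} treatments x {design.n_blocks} blocks x "
            f"{design.n_plants_per_harvest} plants x {n_harvests} harvests)"
        )


if __name__ == "__main__":
    main()
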