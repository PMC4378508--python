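#!/usr/bin/env python
"""Generate the synthetic inputs every later analysis step consumes.

Writes to results/inputs/:
  climate_reference.csv  — 365-day climatology of a 10-year synthetic
                           temperate record (mean 9 degC, seasonal
                           amplitude 8 degC, diurnal range 6 degC, AR(1)
                           day-to-day noise); the 10-year daily record is
                           generated in memory and reduced on the spot
  assays_training.csv    — binomial germination assays over the training
                           design (6 T_m x 5 T_i x 7 times x 5 reps, n=50)
  assays_exact.csv       — the same design, noise-free model fractions
  seedset_obs.csv        — constant-regime bolting-to-seed-set durations
"""

import csv
from pathlib import Path

from seedlife import DEFAULT_GERMINATION_PARAMS, DEFAULT_SEED_SET_PARAMS
from seedlife.climate import build_climatology
from seedlife.io import metadata_header, write_assay_table, write_climate_table
from seedlife.synthetic import (
    SyntheticAssaySpec,
    SyntheticClimateSpec,
    synth_climate,
    synth_germination_assays,
    synth_seed_set_obs,
)

SEED = 20260918
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    decade = synth_climate(
        SyntheticClimateSpec(mean=9.0, amplitude=8.0, diurnal_range=6.0,
                             noise_sd=1.5, ar_coeff=0.6, n_years=10, seed=SEED,
                             label="reference temperate")
    )
    climatology = build_climatology(decade, label="reference temperate climatology")
    write_climate_table(climatology, OUT / "climate_reference.csv", seed=SEED)

    noisy = synth_germination_assays(
        SyntheticAssaySpec(params=DEFAULT_GERMINATION_PARAMS, seed=SEED)
    )
    write_assay_table(noisy, OUT / "assays_training.csv", seed=SEED)
    exact = synth_germination_assays(
        SyntheticAssaySpec(params=DEFAULT_GERMINATION_PARAMS, noise=False)
    )
    write_assay_table(exact, OUT / "assays_exact.csv")

    obs = synth_seed_set_obs(
        DEFAULT_SEED_SET_PARAMS.t_b, DEFAULT_SEED_SET_PARAMS.threshold,
        [8, 10, 14, 18, 22, 25], noise_sd=0.5, replicates=5, seed=SEED,
    )
    with open(OUT / "seedset_obs.csv", "w", newline="") as fh:
        for line in metadata_header(SEED):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(["temperature", "photoperiod", "days"])
        for o in obs:
            w.writerow([o.temperature, o.photoperiod, repr(o.days)])

    print(f"wrote {len(climatology)}-day climatology of a 10-year record, "
          f"{len(noisy)} noisy + {len(exact)} exact assay series, "
          f"{len(obs)} seed-set observations -> {OUT}")


if __name__ == "__main__":
    main()
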