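"""Build the per-recipient transfer table and the deposition summary.

For each scenario the dye observations are folded into one row per
recipient x dye color (distance to the source-group centroid, mean and
summed counts), then summarised per source x recipient population pair:
percentage of individuals with dye and mean +/- SE percentage of flowers
with dye — the layout of the study's population-level dispersal table.
"""

from pathlib import Path

from pollenflow import io as pio
from pollenflow.synthetic import default_source_map, simulate_landscape
from pollenflow.transfers import build_transfer_table, transfer_summary

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "simulate_step", Path(__file__).with_name("01_simulate.py"))
_sim = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sim)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name, cfg in _sim.SCENARIOS.items():
        data = RESULTS / "synthetic" / name
        plants = pio.read_plants(data / "plants.csv")
        dye = pio.read_dye_observations(data / "dye_observations.csv")
        src = default_source_map(cfg, simulate_landscape(cfg))
        transfers = build_transfer_table(plants, dye, src)
        transfers.to_csv(data / "transfer_table.csv", index=False)
        summ = transfer_summary(transfers)
        summ.to_csv(RESULTS / f"transfer_summary_{name}.csv", index=False)
        intra = summ[summ.transfer_class == "intrapopulation"]
        inter = summ[summ.transfer_class != "intrapopulation"]
        print(f"[{name}] intrapopulation: {intra.pct_individuals_with_dye.min():.0f}-"
              f"{intra.pct_individuals_with_dye.max():.0f}% of individuals with dye; "
              f"interpopulation: {inter.pct_individuals_with_dye.min():.0f}-"
              f"{inter.pct_individuals_with_dye.max():.0f}%")


if __name__ == "__main__":
    main()
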