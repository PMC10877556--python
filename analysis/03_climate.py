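"""Extract climate at cell centroids and compute Last Glacial Maximum anomalies.

Reads the ASCII-grid rasters written by 01_simulate.py, samples each at the
analysis-grid centroids (nearest-cell lookup), and forms signed anomalies
(current - LGM).  Writes the per-cell climate table under results/.
"""

import json
from pathlib import Path

from tetraclim.climate import build_climate_table, read_ascii_grid
from tetraclim.gridding import GridSpec, build_grid

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    layers = {
        (var, era): read_ascii_grid(IN / f"{var}_{era}.asc", var, era)
        for var in ("temperature", "precipitation")
        for era in ("current", "lgm")
    }
    cfg = json.loads((IN / "truth.json").read_text())["config"]
    grid = build_grid(
        GridSpec(resolution=1.0, extent=(0, 0, cfg["grid_nx"], cfg["grid_ny"]), projection="synthetic")
    )
    centroids = grid.cells.set_index("cell")[["cx", "cy"]]
    table = build_climate_table(layers, centroids, anomaly_mode="signed")
    table.to_csv(OUT / "climate.csv")
    print(f"climate table for {len(table)} cells -> {OUT}/climate.csv")
    for col in table.columns:
        print(f"  {col:<15} mean {table[col].mean():9.2f}  sd {table[col].std():8.2f}")


if __name__ == "__main__":
    main()
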