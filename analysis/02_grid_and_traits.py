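"""Grid the synthetic ranges, filter richness, and aggregate community traits.

Reads the bundle written by 01_simulate.py, rasterizes every species range by
centroid membership, applies the <3-species filter per group, and reduces the
species traits to the three community-wide summaries (log10 median mass,
variance of log10 mass, trophic-structure index).  Writes richness and
assemblage tables under results/.
"""

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import shape

from tetraclim.gridding import GridSpec, build_grid, rasterize_ranges, richness_and_filter
from tetraclim.traits import aggregate_assemblage_traits

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    features = json.loads((IN / "ranges.geojson").read_text())["features"]
    ranges = {f["properties"]["species"]: shape(f["geometry"]) for f in features}
    traits = pd.read_csv(IN / "traits.csv")
    truth = json.loads((IN / "truth.json").read_text())["config"]
    nx_, ny_ = truth["grid_nx"], truth["grid_ny"]

    grid = build_grid(GridSpec(resolution=1.0, extent=(0, 0, nx_, ny_), projection="synthetic"))
    presence = rasterize_ranges(ranges, grid)
    group_of = pd.Series(traits["group"].to_numpy(), index=traits["species"])
    richness, retained = richness_and_filter(presence, min_species=3, groups=group_of)
    assemblage = aggregate_assemblage_traits(presence.matrix, traits)

    richness.to_csv(OUT / "richness.csv")
    assemblage.to_csv(OUT / "assemblage.csv", index=False)
    print(f"{len(ranges)} ranges rasterized onto {len(presence.matrix)} cells")
    for group in sorted(retained):
        n = len(retained[group])
        print(f"  {group:<10} mean richness {richness[group].mean():5.1f}; "
              f"{n}/{len(richness)} cells pass the >=3-species filter")
    print(f"assemblage table: {len(assemblage)} (cell x group) rows -> {OUT}/assemblage.csv")


if __name__ == "__main__":
    main()
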