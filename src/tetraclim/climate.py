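"""Climate layers, centroid extraction, and Last Glacial Maximum anomalies.

Contemporary climate is summarized by annual mean temperature (Bio1, degrees
Celsius) and annual precipitation (Bio12, millimeters).  Climate instability
is the anomaly between the contemporary value and its Last Glacial Maximum
(~21 ka BP) counterpart at the same location; an anomaly near zero marks a
climatically stable region.  Values are sampled at grid-cell centroids by
nearest-cell lookup of the source raster.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateLayer",
    "extract_at_centroids",
    "compute_anomaly",
    "build_climate_table",
    "read_ascii_grid",
    "write_ascii_grid",
]

VARIABLES = ("temperature", "precipitation")
ERAS = ("current", "lgm")


@dataclasses.dataclass(frozen=True)
class ClimateLayer:
    """A gridded climate field for one variable and era.

    ``values`` is (ny, nx) with row 0 at the *southern* edge; ``x`` and ``y``
    hold the cell-center coordinates (monotonically increasing).
    """

    variable: str  # "temperature" | "precipitation"
    era: str  # "current" | "lgm"
    values: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.era not in ERAS:
            raise ValueError(f"unknown era {self.era!r}")
        if self.values.shape != (self.y.size, self.x.size):
            raise ValueError("values shape must be (len(y), len(x))")


def extract_at_centroids(layer: ClimateLayer, centroids: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Sample a climate layer at cell centroids by nearest-cell lookup.

    Centroids falling outside the raster coverage (more than half a source
    cell beyond the edge) yield NaN and are logged; downstream stages exclude
    such cells.
    """
    pts = (
        centroids[["cx", "cy"]].to_numpy()
        if isinstance(centroids, pd.DataFrame)
        else np.asarray(centroids, dtype=float)
    )
    dx = layer.x[1] - layer.x[0] if layer.x.size > 1 else 1.0
    dy = layer.y[1] - layer.y[0] if layer.y.size > 1 else 1.0
    ix = np.rint((pts[:, 0] - layer.x[0]) / dx).astype(int)
    iy = np.rint((pts[:, 1] - layer.y[0]) / dy).astype(int)
    inside = (ix >= 0) & (ix < layer.x.size) & (iy >= 0) & (iy < layer.y.size)
    out = np.full(pts.shape[0], np.nan)
    out[inside] = layer.values[iy[inside], ix[inside]]
    n_out = int((~inside).sum())
    if n_out:
        logger.warning(
            "%d centroids fall outside the %s/%s raster; set to NaN", n_out, layer.variable, layer.era
        )
    return out


def compute_anomaly(
    current: np.ndarray, lgm: np.ndarray, mode: str = "signed"
) -> np.ndarray:
    """Climate anomaly between eras: ``current - LGM``.

    ``mode="signed"`` keeps the sign (antisymmetric in its arguments);
    ``mode="absolute"`` returns the magnitude of change.  Zero means no
    change since the Last Glacial Maximum.  Missing values in either era
    propagate to the anomaly.
    """
    current = np.asarray(current, dtype=float)
    lgm = np.asarray(lgm, dtype=float)
    diff = current - lgm
    if mode == "signed":
        return diff
    if mode == "absolute":
        return np.abs(diff)
    raise ValueError(f"unknown anomaly mode {mode!r}")


def build_climate_table(
    layers: dict[tuple[str, str], ClimateLayer],
    centroids: pd.DataFrame,
    anomaly_mode: str = "signed",
) -> pd.DataFrame:
    """Assemble the per-cell climate table from the four era/variable layers.

    Returns a DataFrame indexed by cell id with columns ``temp_current``,
    ``precip_current``, ``temp_anomaly``, ``precip_anomaly``.
    """
    cols = {}
    for var, short in (("temperature", "temp"), ("precipitation", "precip")):
        cur = extract_at_centroids(layers[(var, "current")], centroids)
        lgm = extract_at_centroids(layers[(var, "lgm")], centroids)
        cols[f"{short}_current"] = cur
        cols[f"{short}_anomaly"] = compute_anomaly(cur, lgm, mode=anomaly_mode)
    return pd.DataFrame(cols, index=centroids.index)


def write_ascii_grid(path: str | Path, layer: ClimateLayer, nodata: float = -9999.0) -> None:
    """Write a layer as an ESRI ASCII grid (plain-text raster)."""
    dx = float(layer.x[1] - layer.x[0]) if layer.x.size > 1 else 1.0
    values = np.where(np.isfinite(layer.values), layer.values, nodata)
    header = (
        f"ncols {layer.x.size}\n"
        f"nrows {layer.y.size}\n"
        f"xllcorner {layer.x[0] - dx / 2.0}\n"
        f"yllcorner {layer.y[0] - dx / 2.0}\n"
        f"cellsize {dx}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in values[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, variable: str, era: str) -> ClimateLayer:
    """Read an ESRI ASCII grid into a :class:`ClimateLayer`."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        meta[key.lower()] = float(val)
        i += 1
    values = np.loadtxt(lines[i:])
    values = np.atleast_2d(values)[::-1]  # file rows run north->south
    nodata = meta.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    cs = meta["cellsize"]
    x = meta["xllcorner"] + cs / 2.0 + cs * np.arange(int(meta["ncols"]))
    y = meta["yllcorner"] + cs / 2.0 + cs * np.arange(int(meta["nrows"]))
    return ClimateLayer(variable=variable, era=era, values=values, x=x, y=y)
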