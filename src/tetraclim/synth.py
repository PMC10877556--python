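"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design end to end: spatially autocorrelated
temperature/precipitation fields for two eras (current and Last Glacial
Maximum), species ranges as discs placed along the climate gradient,
log-normal body masses whose climate dependence follows each group's assumed
direction (Bergmann-type for endotherms, reversed for ectotherms),
categorical diets covering all three trophic classes, and — the piece the
statistical machinery is validated against — a grid-level linear-Gaussian
structural model with known standardized path coefficients.

Standardization contract: in the structural table every variable has unit
population variance, so the generating coefficients are directly comparable
to fitted standardized coefficients.  Residual standard deviations are
derived from the DAG-implied covariance unless an explicit ``noise_sd``
overrides them.  Richness is generated on a latent continuous standardized
scale (the models treat richness by OLS); ``richness_to_counts`` maps it to
integer counts for gridding-stage exercises.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, mapping

from tetraclim.climate import ClimateLayer, write_ascii_grid

__all__ = [
    "EXOGENOUS",
    "TRAIT_NODES",
    "THEORETICAL_EDGES",
    "DEFAULT_TRUE_PATHS",
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_climate_fields",
    "generate_grid_sem_data",
    "generate_ranges_and_traits",
    "generate_bundle",
    "simulate_linear_sem",
    "implied_covariance",
    "richness_to_counts",
    "write_bundle",
]

EXOGENOUS = ("climate", "instability")
TRAIT_NODES = ("body_size", "size_variance", "trophic_structure")
RESPONSE = "richness"

#: The theoretical DAG: climate and instability drive each community trait
#: and richness; each trait drives richness.
THEORETICAL_EDGES: tuple[tuple[str, str], ...] = tuple(
    [(e, t) for e in EXOGENOUS for t in TRAIT_NODES]
    + [(e, RESPONSE) for e in EXOGENOUS]
    + [(t, RESPONSE) for t in TRAIT_NODES]
)

#: Default standardized path coefficients.  Signs follow the study-system
#: expectations: warmer/wetter cells richer, larger-bodied communities
#: poorer, top-heavy communities poorer; magnitudes are moderate so every
#: implied residual variance stays positive.
DEFAULT_TRUE_PATHS: dict[tuple[str, str], float] = {
    ("climate", "body_size"): -0.25,
    ("climate", "size_variance"): 0.30,
    ("climate", "trophic_structure"): 0.15,
    ("climate", "richness"): 0.45,
    ("instability", "body_size"): 0.20,
    ("instability", "size_variance"): -0.30,
    ("instability", "trophic_structure"): -0.15,
    ("instability", "richness"): 0.20,
    ("body_size", "richness"): -0.25,
    ("size_variance", "richness"): 0.20,
    ("trophic_structure", "richness"): -0.15,
}

_GROUP_PARAMS = {
    # mean log10 mass, climate slope of log10 mass, (primary, omnivore, secondary) probs
    "amphibian": (1.0, 0.15, (0.02, 0.18, 0.80)),
    "squamate": (1.5, 0.15, (0.05, 0.20, 0.75)),
    "bird": (1.8, -0.15, (0.25, 0.50, 0.25)),
    "mammal": (2.2, -0.15, (0.30, 0.45, 0.25)),
}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic study system.

    ``true_paths`` maps DAG edges to standardized coefficients in [-1, 1];
    every edge must belong to the theoretical DAG.  ``noise_sd`` (None,
    scalar, or per-node mapping) overrides the unit-variance auto-scaling of
    residual SDs.  ``spatial_range`` is the autocorrelation length of the
    climate fields in cell units.
    """

    grid_nx: int = 25
    grid_ny: int = 16
    n_species_per_group: int = 40
    true_paths: Mapping[tuple[str, str], float] | None = None
    noise_sd: float | Mapping[str, float] | None = None
    trait_error_corr: float = 0.3
    spatial_range: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.grid_nx * self.grid_ny < 10:
            raise ValueError("grid must have at least 10 cells")
        if not self.spatial_range > 0:
            raise ValueError("spatial_range must be positive")
        paths = self.paths
        unknown = set(paths) - set(THEORETICAL_EDGES)
        if unknown:
            raise ValueError(f"edges outside the theoretical DAG: {sorted(unknown)}")
        if any(abs(v) > 1 for v in paths.values()):
            raise ValueError("standardized coefficients must lie in [-1, 1]")
        g = nx.DiGraph(list(paths))
        if not nx.is_directed_acyclic_graph(g):  # subset of a DAG; defensive
            raise ValueError("true_paths must form an acyclic graph")

    @property
    def paths(self) -> dict[tuple[str, str], float]:
        return dict(DEFAULT_TRUE_PATHS if self.true_paths is None else self.true_paths)

    @property
    def n_cells(self) -> int:
        return self.grid_nx * self.grid_ny

    def _streams(self) -> list[np.random.Generator]:
        """Independent per-stage substreams (fields, sem, species)."""
        return [np.random.default_rng(c) for c in np.random.SeedSequence(self.seed).spawn(3)]


@dataclasses.dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SyntheticConfig
    climate: dict[tuple[str, str], ClimateLayer]
    ranges: dict[str, object]
    traits: pd.DataFrame
    sem_table: pd.DataFrame
    truth: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if len(self.sem_table) != self.config.n_cells:
            raise ValueError("sem_table must have one row per grid cell")
        numeric = self.sem_table.select_dtypes(include=[np.number])
        if not np.isfinite(numeric.to_numpy()).all():
            raise ValueError("sem_table contains non-finite values")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")


def _latitude_gradient(ny: int, nx: int) -> np.ndarray:
    lat = np.linspace(-1.0, 1.0, ny)[:, None]
    return np.broadcast_to(1.0 - np.abs(lat), (ny, nx)).copy()


def generate_climate_fields(config: SyntheticConfig) -> dict[tuple[str, str], ClimateLayer]:
    """Four gridded climate fields: temp/precip x current/LGM.

    Each field is kernel-smoothed white noise (bandwidth ``spatial_range``)
    plus a latitudinal gradient peaking at the equator; LGM fields subtract a
    further independent autocorrelated perturbation so anomalies vary in
    space.  Deterministic given the config seed.
    """
    rng = config._streams()[0]
    ny, nx = config.grid_ny, config.grid_nx
    g = _latitude_gradient(ny, nx)
    s = config.spatial_range
    temp_cur = -5.0 + 30.0 * g + 6.0 * _smooth_field(rng, (ny, nx), s)
    precip_cur = np.clip(200.0 + 1800.0 * g + 300.0 * _smooth_field(rng, (ny, nx), s), 0.0, None)
    temp_lgm = temp_cur - (4.0 + 2.0 * _smooth_field(rng, (ny, nx), s))
    precip_lgm = np.clip(precip_cur - (150.0 + 120.0 * _smooth_field(rng, (ny, nx), s)), 0.0, None)
    x = np.arange(nx) + 0.5
    y = np.arange(ny) + 0.5
    return {
        ("temperature", "current"): ClimateLayer("temperature", "current", temp_cur, x, y),
        ("temperature", "lgm"): ClimateLayer("temperature", "lgm", temp_lgm, x, y),
        ("precipitation", "current"): ClimateLayer("precipitation", "current", precip_cur, x, y),
        ("precipitation", "lgm"): ClimateLayer("precipitation", "lgm", precip_lgm, x, y),
    }


def _topological_nodes(paths: Mapping[tuple[str, str], float]) -> list[str]:
    g = nx.DiGraph(list(paths))
    return list(nx.lexicographical_topological_sort(g))


def implied_covariance(
    paths: Mapping[tuple[str, str], float],
    error_corr: Mapping[frozenset, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Model-implied covariance and residual variances for unit-variance nodes.

    Nodes are processed in topological order; each endogenous node's residual
    variance is whatever brings its total variance to 1 given the covariance
    of its parents.  Correlated-error pairs contribute
    ``rho * sd_a * sd_b`` to the pair's covariance; such pairs must be
    non-adjacent and free of ancestor relations with each other's parents.

    Raises if any implied residual variance is nonpositive (coefficients too
    large for standardized variables).
    """
    error_corr = dict(error_corr or {})
    g = nx.DiGraph(list(paths))
    order = _topological_nodes(paths)
    for pair in error_corr:
        a, b = tuple(pair)
        if g.has_edge(a, b) or g.has_edge(b, a):
            raise ValueError(f"correlated-error pair {a},{b} must be non-adjacent")
        for x, y in ((a, b), (b, a)):
            # Cov(e_y, parents(y)) must vanish: partner x may not feed a parent.
            bad = set(g.predecessors(y)) & (nx.descendants(g, x) | {x})
            if bad:
                raise ValueError(f"error correlation between {a} and {b} conflicts with parents of {y}")
    cov = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    noise_var: dict[str, float] = {}
    partners = {n: {} for n in order}
    for pair, rho in error_corr.items():
        a, b = tuple(pair)
        partners[a][b] = rho
        partners[b][a] = rho
    done: list[str] = []
    for node in order:
        parents = list(g.predecessors(node))
        if parents:
            b = np.array([paths[(p, node)] for p in parents])
            sigma_pp = cov.loc[parents, parents].to_numpy()
            var_sys = float(b @ sigma_pp @ b)
            nv = 1.0 - var_sys
            if nv <= 0:
                raise ValueError(
                    f"path coefficients into {node!r} imply nonpositive residual variance "
                    f"(systematic variance {var_sys:.3f} >= 1)"
                )
            noise_var[node] = nv
            for z in done:
                c = float(b @ cov.loc[parents, z].to_numpy())
                if z in partners[node] and z in noise_var:
                    c += partners[node][z] * np.sqrt(noise_var[node] * noise_var[z])
                cov.loc[node, z] = cov.loc[z, node] = c
        done.append(node)
    return cov, noise_var


def simulate_linear_sem(
    paths: Mapping[tuple[str, str], float],
    n: int,
    rng: np.random.Generator,
    noise_sd: float | Mapping[str, float] | None = None,
    error_corr: Mapping[frozenset, float] | None = None,
    exog_values: Mapping[str, np.ndarray] | None = None,
    noise_values: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate a recursive linear-Gaussian SEM with standardized variables.

    Variables are generated in topological order; each endogenous variable is
    the coefficient-weighted sum of its parents plus Gaussian noise.  With
    ``noise_sd=None`` residual SDs come from :func:`implied_covariance`, so
    all variables have unit population variance and the coefficients are
    standardized.  ``exog_values`` / ``noise_values`` inject pre-made
    unit-variance columns (e.g., spatially autocorrelated fields).
    """
    error_corr = dict(error_corr or {})
    g = nx.DiGraph(list(paths))
    order = _topological_nodes(paths)
    if noise_sd is None:
        _, noise_var = implied_covariance(paths, error_corr)
    else:
        endo = [v for v in order if g.in_degree(v) > 0]
        if np.isscalar(noise_sd):
            noise_var = {v: float(noise_sd) ** 2 for v in endo}
        else:
            noise_var = {v: float(noise_sd[v]) ** 2 for v in endo}

    # Base errors: unit-variance, independent across nodes unless injected.
    base: dict[str, np.ndarray] = {}
    for node in order:
        if g.in_degree(node) == 0:
            continue
        if noise_values is not None and node in noise_values:
            base[node] = np.asarray(noise_values[node], dtype=float)
        else:
            base[node] = rng.standard_normal(n)
    # Correlate errors within connected components of the error-corr graph.
    errors: dict[str, np.ndarray] = {}
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(base)
    for pair, rho in error_corr.items():
        a, b = tuple(pair)
        if a in base and b in base:
            comp_graph.add_edge(a, b, rho=rho)
    for comp in nx.connected_components(comp_graph):
        members = sorted(comp)
        k = len(members)
        corr = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                if comp_graph.has_edge(members[i], members[j]):
                    corr[i, j] = corr[j, i] = comp_graph[members[i]][members[j]]["rho"]
        chol = np.linalg.cholesky(corr)
        raw = np.column_stack([base[m] for m in members])
        mixed = raw @ chol.T
        for i, m in enumerate(members):
            errors[m] = np.sqrt(noise_var[m]) * mixed[:, i]

    data: dict[str, np.ndarray] = {}
    for node in order:
        parents = list(g.predecessors(node))
        if not parents:
            if exog_values is not None and node in exog_values:
                data[node] = np.asarray(exog_values[node], dtype=float)
            else:
                data[node] = rng.standard_normal(n)
        else:
            systematic = sum(paths[(p, node)] * data[p] for p in parents)
            data[node] = systematic + errors[node]
    return pd.DataFrame(data)[order]


def generate_grid_sem_data(
    config: SyntheticConfig,
    spatial: bool = False,
    spatial_noise: float = 0.5,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Per-cell structural table with known standardized coefficients.

    Returns ``(table, truth)``.  The table has one row per grid cell (cell
    ids match :func:`tetraclim.gridding.build_grid` on a unit-resolution
    grid) with the model variables plus centroid coordinates ``cx, cy``.

    With ``spatial=True`` the exogenous variables are standardized
    kernel-smoothed random fields and a ``spatial_noise`` fraction of every
    residual SD is spatially structured, giving the Moran's-eigenvector
    machinery something real to absorb; with ``spatial=False`` (default) all
    sources are i.i.d., the cleanest setting for coefficient recovery.
    """
    rng = config._streams()[1]
    paths = config.paths
    n = config.n_cells
    dim_y, dim_x = config.grid_ny, config.grid_nx
    error_corr = {
        frozenset(p): config.trait_error_corr
        for p in [(a, b) for i, a in enumerate(TRAIT_NODES) for b in TRAIT_NODES[i + 1:]]
        if config.trait_error_corr != 0.0
        and p[0] in {e[1] for e in paths} | {e[0] for e in paths}
        and p[1] in {e[1] for e in paths} | {e[0] for e in paths}
    }

    def z(field: np.ndarray) -> np.ndarray:
        flat = field.ravel()
        return (flat - flat.mean()) / flat.std()

    exog_values = None
    noise_values = None
    if spatial:
        g = nx.DiGraph(list(paths))
        exog_values = {
            v: z(_smooth_field(rng, (dim_y, dim_x), config.spatial_range))
            for v in _topological_nodes(paths)
            if g.in_degree(v) == 0
        }
        f = float(spatial_noise)
        if not 0.0 <= f <= 1.0:
            raise ValueError("spatial_noise must lie in [0, 1]")
        noise_values = {
            v: np.sqrt(1 - f**2) * rng.standard_normal(n)
            + f * z(_smooth_field(rng, (dim_y, dim_x), config.spatial_range))
            for v in _topological_nodes(paths)
            if g.in_degree(v) > 0
        }
    table = simulate_linear_sem(
        paths,
        n,
        rng,
        noise_sd=config.noise_sd,
        error_corr=error_corr,
        exog_values=exog_values,
        noise_values=noise_values,
    )
    cells = [f"r{j}c{i}" for j in range(dim_y) for i in range(dim_x)]
    table.index = pd.Index(cells, name="cell")
    xs, ys = np.meshgrid(np.arange(dim_x) + 0.5, np.arange(dim_y) + 0.5)
    table["cx"] = xs.ravel()
    table["cy"] = ys.ravel()
    return table, dict(paths)


def richness_to_counts(latent: np.ndarray, log_mean: float = 2.5, log_sd: float = 0.8) -> np.ndarray:
    """Map latent standardized richness to integer species counts.

    ``counts = round(exp(log_mean + log_sd * z))`` — a convenience for
    exercising the gridding-stage filter, not used in coefficient-recovery
    checks.
    """
    return np.rint(np.exp(log_mean + log_sd * np.asarray(latent, dtype=float))).astype(int)


def generate_ranges_and_traits(
    config: SyntheticConfig,
    fields: dict[tuple[str, str], ClimateLayer] | None = None,
    radius_range: tuple[float, float] | None = None,
) -> tuple[dict[str, object], pd.DataFrame]:
    """Species ranges (discs along the climate gradient) and a trait table.

    Each species gets a disc centered at a climate-dependent location (cells
    whose temperature is close to the species' thermal optimum are more
    likely centers) with a random radius; a log-normal body mass whose mean
    tracks local temperature in the group's assumed direction; and diet
    fractions drawn from a mixture so all three trophic classes occur.
    Deterministic given the config seed.
    """
    if config.n_species_per_group < 3:
        raise ValueError("need at least 3 species per group")
    rng = config._streams()[2]
    fields = fields if fields is not None else generate_climate_fields(config)
    temp = fields[("temperature", "current")].values
    ny, nx = temp.shape
    temp_z = (temp - temp.mean()) / temp.std()
    if radius_range is None:
        radius_range = (1.5, max(nx, ny) / 3.0)
    ranges: dict[str, object] = {}
    rows = []
    for group in sorted(_GROUP_PARAMS):
        mu, slope, probs = _GROUP_PARAMS[group]
        for i in range(config.n_species_per_group):
            name = f"{group}_{i:03d}"
            optimum = rng.uniform(temp.min(), temp.max())
            weights = np.exp(-((temp - optimum) ** 2) / (2 * 4.0**2)).ravel()
            k = rng.choice(temp.size, p=weights / weights.sum())
            cy, cx = divmod(int(k), nx)
            center = (cx + 0.5 + rng.uniform(-0.5, 0.5), cy + 0.5 + rng.uniform(-0.5, 0.5))
            radius = rng.uniform(*radius_range)
            ranges[name] = Point(center).buffer(radius, quad_segs=12)
            log_mass = rng.normal(mu + slope * temp_z[cy, cx], 0.4)
            category = rng.choice(("primary", "omnivore", "secondary"), p=probs)
            if category == "primary":
                plant = rng.uniform(0.92, 1.0)
                animal = (1.0 - plant) * rng.uniform(0.0, 1.0)
            elif category == "secondary":
                animal = rng.uniform(0.92, 1.0)
                plant = (1.0 - animal) * rng.uniform(0.0, 1.0)
            else:
                plant = rng.uniform(0.2, 0.7)
                animal = (1.0 - plant) * rng.uniform(0.3, 0.9)
            rows.append(
                {
                    "species": name,
                    "group": group,
                    "body_mass_g": float(10.0**log_mass),
                    "diet_plant": float(plant),
                    "diet_animal": float(animal),
                }
            )
    return ranges, pd.DataFrame(rows)


def generate_bundle(config: SyntheticConfig, spatial: bool = True) -> SyntheticBundle:
    """Generate the full input bundle: climate, ranges, traits, SEM table."""
    fields = generate_climate_fields(config)
    ranges, traits = generate_ranges_and_traits(config, fields)
    sem_table, truth = generate_grid_sem_data(config, spatial=spatial)
    return SyntheticBundle(
        config=config, climate=fields, ranges=ranges, traits=traits, sem_table=sem_table, truth=truth
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Persist a bundle: GeoJSON ranges, ASCII-grid climate, CSV tables, JSON truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    features = []
    group_of = dict(zip(bundle.traits["species"], bundle.traits["group"]))
    for name, geom in bundle.ranges.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"species": name, "group": group_of.get(name)},
                "geometry": mapping(geom),
            }
        )
    (out / "ranges.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    for (var, era), layer in bundle.climate.items():
        write_ascii_grid(out / f"{var}_{era}.asc", layer)
    bundle.traits.to_csv(out / "traits.csv", index=False)
    bundle.sem_table.to_csv(out / "sem_table.csv")
    sidecar = {
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(bundle.config).items()
            if k != "true_paths"
        },
        "true_paths": {f"{a}->{b}": c for (a, b), c in bundle.truth.items()},
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
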