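"""The synthetic generator: determinism, standardization, known truth."""

import numpy as np
import pandas as pd
import pytest

from tetraclim.spatial import expected_morans_i, lattice_rook_weights, morans_i
from tetraclim.synth import (
    DEFAULT_TRUE_PATHS,
    SyntheticConfig,
    generate_bundle,
    generate_climate_fields,
    generate_grid_sem_data,
    generate_ranges_and_traits,
    implied_covariance,
    richness_to_counts,
    simulate_linear_sem,
)
from tetraclim.traits import aggregate_assemblage_traits
from tetraclim.gridding import GridSpec, build_grid, rasterize_ranges


def test_config_validation():
    with pytest.raises(ValueError, match="positive"):
        SyntheticConfig(grid_nx=0, grid_ny=5)
    with pytest.raises(ValueError, match="at least 10 cells"):
        SyntheticConfig(grid_nx=3, grid_ny=3)
    with pytest.raises(ValueError, match="theoretical DAG"):
        SyntheticConfig(true_paths={("richness", "climate"): 0.5})
    with pytest.raises(ValueError, match="spatial_range"):
        SyntheticConfig(spatial_range=0.0)


def test_overloaded_coefficients_rejected():
    """Systematic variance >= 1 leaves no room for residual noise."""
    paths = {("climate", "richness"): 0.9, ("instability", "richness"): 0.9}
    with pytest.raises(ValueError, match="residual variance"):
        implied_covariance(paths)


def test_same_seed_identical_bundle():
    a = generate_bundle(SyntheticConfig(grid_nx=10, grid_ny=4, n_species_per_group=5, seed=33))
    b = generate_bundle(SyntheticConfig(grid_nx=10, grid_ny=4, n_species_per_group=5, seed=33))
    pd.testing.assert_frame_equal(a.sem_table, b.sem_table)
    assert a.traits.to_csv() == b.traits.to_csv()  # byte-identical trait table
    for key in a.climate:
        np.testing.assert_array_equal(a.climate[key].values, b.climate[key].values)
    assert all(a.ranges[k].equals(b.ranges[k]) for k in a.ranges)


def test_sem_variables_near_unit_variance():
    cfg = SyntheticConfig(grid_nx=40, grid_ny=30, seed=2)  # n = 1200
    table, _ = generate_grid_sem_data(cfg)
    for node in ("climate", "instability", "body_size", "size_variance", "trophic_structure", "richness"):
        assert table[node].var() == pytest.approx(1.0, rel=0.10)


def test_zero_coefficients_give_uncorrelated_variables():
    paths = {edge: 0.0 for edge in DEFAULT_TRUE_PATHS}
    cfg = SyntheticConfig(grid_nx=50, grid_ny=40, true_paths=paths, trait_error_corr=0.0, seed=8)
    table, _ = generate_grid_sem_data(cfg)
    corr = table.drop(columns=["cx", "cy"]).corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert np.abs(corr).max() < 0.1


def test_noiseless_chain_is_deterministic(rng):
    paths = {("climate", "body_size"): 1.0, ("body_size", "richness"): 1.0}
    df = simulate_linear_sem(paths, 200, rng, noise_sd=0.0)
    np.testing.assert_allclose(df["richness"], df["climate"], atol=1e-12)


def test_reduced_form_path_tracing():
    """Chain -0.4 * -0.3 plus direct 0.5 gives a reduced-form slope of 0.62."""
    paths = {
        ("climate", "body_size"): -0.4,
        ("body_size", "richness"): -0.3,
        ("climate", "richness"): 0.5,
    }
    cfg = SyntheticConfig(grid_nx=50, grid_ny=40, true_paths=paths, seed=5)
    table, _ = generate_grid_sem_data(cfg)
    z = lambda s: (s - s.mean()) / s.std()
    slope = np.polyfit(z(table["climate"]), z(table["richness"]), 1)[0]
    assert slope == pytest.approx(0.62, abs=0.05)


def test_implied_covariance_matches_simulation(rng):
    cov, _ = implied_covariance(DEFAULT_TRUE_PATHS, {frozenset(("body_size", "size_variance")): 0.3})
    df = simulate_linear_sem(
        DEFAULT_TRUE_PATHS, 200_000, rng, error_corr={frozenset(("body_size", "size_variance")): 0.3}
    )
    emp = df.cov()
    np.testing.assert_allclose(
        emp.loc[cov.index, cov.columns].to_numpy(), cov.to_numpy(), atol=0.02
    )


def test_infinite_range_limit_is_constant_up_to_gradient():
    cfg = SyntheticConfig(grid_nx=25, grid_ny=16, spatial_range=1e4, seed=1)
    fields = generate_climate_fields(cfg)
    temp = fields[("temperature", "current")].values
    residual = temp - temp.mean(axis=1, keepdims=True)  # remove latitudinal part
    assert np.abs(residual).max() < 1e-3


def test_generated_field_is_spatially_autocorrelated():
    cfg = SyntheticConfig(grid_nx=20, grid_ny=15, spatial_range=2.0, seed=4)
    temp = generate_climate_fields(cfg)[("temperature", "current")].values
    w = lattice_rook_weights(20, 15)
    assert morans_i(temp.ravel(), w) > expected_morans_i(300)


def test_lgm_anomaly_is_nonconstant():
    cfg = SyntheticConfig(grid_nx=20, grid_ny=10, seed=6)
    fields = generate_climate_fields(cfg)
    anom = fields[("temperature", "current")].values - fields[("temperature", "lgm")].values
    assert anom.std() > 0.1


def test_full_domain_ranges_give_total_richness_everywhere():
    cfg = SyntheticConfig(grid_nx=10, grid_ny=4, n_species_per_group=3, seed=9)
    ranges, traits = generate_ranges_and_traits(cfg, radius_range=(100.0, 100.0))
    grid = build_grid(GridSpec(resolution=1.0, extent=(0, 0, 10, 4), projection="synthetic"))
    pm = rasterize_ranges(ranges, grid)
    assert (pm.matrix.sum(axis=1) == len(ranges)).all()


def test_all_plant_diet_forces_trophic_index_two():
    cfg = SyntheticConfig(grid_nx=10, grid_ny=4, n_species_per_group=3, seed=9)
    ranges, traits = generate_ranges_and_traits(cfg, radius_range=(100.0, 100.0))
    traits = traits.assign(diet_plant=1.0, diet_animal=0.0)
    grid = build_grid(GridSpec(resolution=1.0, extent=(0, 0, 10, 4), projection="synthetic"))
    pm = rasterize_ranges(ranges, grid)
    agg = aggregate_assemblage_traits(pm.matrix, traits)
    assert (agg["trophic_structure"] == 2.0).all()


def test_all_trophic_classes_occur():
    cfg = SyntheticConfig(grid_nx=10, grid_ny=4, n_species_per_group=40, seed=10)
    _, traits = generate_ranges_and_traits(cfg)
    from tetraclim.traits import classify_trophic_level

    cats = {
        classify_trophic_level(r["diet_plant"], r["diet_animal"]).category
        for _, r in traits.iterrows()
    }
    assert cats == {"primary", "omnivore", "secondary"}


def test_richness_to_counts_monotone_integer():
    z = np.array([-2.0, 0.0, 2.0])
    counts = richness_to_counts(z)
    assert counts.dtype.kind == "i"
    assert counts[0] < counts[1] < counts[2]
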