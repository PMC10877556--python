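"""Piecewise SEM: prefilter, submodels, d-separation, effect decomposition."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetraclim.psem import (
    PathModelSpec,
    basis_set,
    collinearity_prefilter,
    dsep_fisher_c,
    effect_decomposition,
    fit_psem,
    fit_submodel,
)
from tetraclim.synth import DEFAULT_TRUE_PATHS, SyntheticConfig, generate_grid_sem_data, simulate_linear_sem


# ---------------------------------------------------------------- prefilter
def test_duplicated_predictor_drops_exactly_one(rng):
    x = rng.standard_normal(200)
    df = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.standard_normal(200), "y": x + rng.standard_normal(200)})
    kept, log = collinearity_prefilter(df, ["a", "b"], "y")
    assert len(kept) == 1 and len(log) == 1
    assert log[0]["abs_r"] > 0.99


def test_moderately_correlated_pair_is_kept(rng):
    a = rng.standard_normal(300)
    b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(300)
    df = pd.DataFrame({"a": a, "b": b, "y": rng.standard_normal(300)})
    kept, log = collinearity_prefilter(df, ["a", "b"], "y")
    assert kept == ["a", "b"] and log == []


def test_prefilter_terminates_with_all_pairs_below_threshold(rng):
    base = rng.standard_normal(300)
    df = pd.DataFrame(
        {
            "a": base,
            "b": base + 0.1 * rng.standard_normal(300),
            "c": base + 0.1 * rng.standard_normal(300),
            "y": base + rng.standard_normal(300),
        }
    )
    kept, log = collinearity_prefilter(df, ["a", "b", "c"], "y")
    corr = df[kept].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= 0.7
    assert len(log) >= 1


# ---------------------------------------------------------------- submodels
def test_perfect_fit_standardized_slope_one(rng):
    x = rng.standard_normal(100)
    df = pd.DataFrame({"x": x, "y": x})
    fit = fit_submodel("y", ["x"], df)
    assert fit.std_coefs["x"] == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_simple_regression_std_coef_equals_pearson_r(rng):
    df = pd.DataFrame(rng.standard_normal((150, 2)), columns=["x", "y"])
    fit = fit_submodel("y", ["x"], df)
    r = np.corrcoef(df["x"], df["y"])[0, 1]
    assert fit.std_coefs["x"] == pytest.approx(r, abs=1e-12)


def test_rank_deficient_design_names_columns(rng):
    x = rng.standard_normal(50)
    df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.standard_normal(50)})
    with pytest.raises(ValueError, match="x2"):
        fit_submodel("y", ["x", "x2"], df)


def test_pure_noise_predictor_calibration(rng):
    """|beta_std| of an irrelevant predictor stays below 0.07 almost always."""
    n, reps = 2000, 200
    x = rng.standard_normal((reps, n))
    y = rng.standard_normal((reps, n))
    # simple-regression standardized slope == Pearson r, computed in bulk
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    assert np.mean(np.abs(r) < 0.07) >= 0.95


# ------------------------------------------------------------ d-separation
def _brute_force_basis(edges, correlated=frozenset(), excluded=frozenset()):
    """Independent enumeration: non-adjacent pairs, union-of-parents conditioning."""
    g = nx.DiGraph(edges)
    order = list(nx.lexicographical_topological_sort(g))
    pos = {v: i for i, v in enumerate(order)}
    out = set()
    for u, v in itertools.combinations(order, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if frozenset((u, v)) in correlated or frozenset((u, v)) in excluded:
            continue
        if g.in_degree(u) == 0 and g.in_degree(v) == 0:
            continue
        a, b = (u, v) if pos[u] < pos[v] else (v, u)
        cond = tuple(sorted(set(g.predecessors(a)) | set(g.predecessors(b))))
        out.add((a, b, cond))
    return out


@pytest.mark.parametrize(
    "edges",
    [
        [("x", "m"), ("m", "y")],
        [("x1", "m"), ("x2", "m"), ("m", "y"), ("x1", "y")],
        [("a", "b"), ("b", "c"), ("c", "d"), ("a", "e"), ("e", "d")],
        [("u", "v"), ("v", "w"), ("u", "w"), ("q", "v"), ("q", "r"), ("w", "r")],
    ],
)
def test_basis_set_matches_brute_force(edges):
    spec = PathModelSpec(edges=tuple(edges), response=edges[-1][1])
    assert set(basis_set(spec)) == _brute_force_basis(edges)


def test_basis_set_excludes_correlated_errors_and_exogenous_pairs():
    edges = [("x1", "m1"), ("x1", "m2"), ("x2", "m1"), ("x2", "m2"), ("m1", "y"), ("m2", "y")]
    corr = frozenset({frozenset(("m1", "m2"))})
    spec = PathModelSpec(edges=tuple(edges), correlated_errors=corr, response="y")
    claims = set(basis_set(spec))
    assert claims == _brute_force_basis(edges, correlated=corr)
    assert all({"m1", "m2"} != set(c[:2]) for c in claims)
    assert all({"x1", "x2"} != set(c[:2]) for c in claims)


def test_fisher_c_is_minus_two_sum_log_p(rng):
    paths = {("x1", "m"): 0.5, ("x2", "m"): 0.4, ("m", "y"): 0.6}
    spec = PathModelSpec(edges=tuple(paths), response="y")
    df = simulate_linear_sem(paths, 400, rng)
    claims, c, dof, p = dsep_fisher_c(spec, df)
    assert dof == 2 * len(claims) == 4
    assert c == pytest.approx(-2.0 * sum(np.log(cl.p_value) for cl in claims))
    assert p == pytest.approx(stats.chi2.sf(c, dof))
    # single claim with p = e^-1 contributes exactly 2 to C
    assert -2.0 * np.log(np.exp(-1.0)) == pytest.approx(2.0)


def test_saturated_model_reports_empty_basis(rng):
    table, _ = generate_grid_sem_data(SyntheticConfig(grid_nx=10, grid_ny=4, seed=0))
    spec = PathModelSpec.canonical()
    claims, c, dof, p = dsep_fisher_c(spec, table)
    assert claims == [] and dof == 0
    assert np.isnan(c) and np.isnan(p)


def test_cyclic_spec_rejected():
    with pytest.raises(ValueError, match="acyclic"):
        PathModelSpec(edges=(("a", "b"), ("b", "a")))
    with pytest.raises(ValueError, match="non-adjacent"):
        PathModelSpec(edges=(("a", "b"),), correlated_errors=frozenset({frozenset(("a", "b"))}))


# ------------------------------------------------------ effect decomposition
def test_chain_indirect_is_product_and_total_is_sum():
    spec = PathModelSpec(edges=(("x", "m"), ("m", "y"), ("x", "y")), response="y")
    effects = effect_decomposition(spec, {("x", "m"): 0.5, ("m", "y"): 0.4, ("x", "y"): 0.3})
    assert effects.loc["x", "indirect"] == pytest.approx(0.20)
    assert effects.loc["x", "total"] == pytest.approx(0.50)
    assert effects.loc["m", "direct"] == pytest.approx(0.4)
    assert effects.loc["m", "indirect"] == 0.0


def test_no_mediated_path_means_indirect_zero():
    spec = PathModelSpec(edges=(("x", "y"),), response="y")
    effects = effect_decomposition(spec, {("x", "y"): 0.7})
    assert effects.loc["x", "indirect"] == 0.0
    assert effects.loc["x", "total"] == pytest.approx(0.7)


def test_effects_conservation_on_fitted_model():
    """total = direct + indirect holds exactly, and indirect equals an
    independent enumeration of path products over the fitted DAG."""
    cfg = SyntheticConfig(grid_nx=40, grid_ny=25, seed=12)
    table, _ = generate_grid_sem_data(cfg)
    fit = fit_psem(PathModelSpec.canonical(), table)
    assert np.allclose(fit.effects["total"], fit.effects["direct"] + fit.effects["indirect"])
    coefs = {
        (p, node): fit.coefficient(p, node)
        for node in fit.submodels
        for p in fit.submodels[node].predictors
    }
    g = nx.DiGraph()
    for (a, b), c in coefs.items():
        g.add_edge(a, b, w=c)
    for node in fit.effects.index:
        paths = [
            np.prod([g[a][b]["w"] for a, b in zip(p[:-1], p[1:])])
            for p in nx.all_simple_paths(g, node, "richness")
            if len(p) > 2
        ]
        assert fit.effects.loc[node, "indirect"] == pytest.approx(sum(paths), abs=1e-12)


# ------------------------------------------------------------------ fit_psem
def test_recovery_of_true_standardized_coefficients():
    cfg = SyntheticConfig(grid_nx=40, grid_ny=25, seed=21)  # n = 1000
    table, truth = generate_grid_sem_data(cfg)
    fit = fit_psem(PathModelSpec.canonical(), table)
    for edge, beta in truth.items():
        assert fit.coefficient(*edge) == pytest.approx(beta, abs=0.12)


def test_total_effect_matches_reduced_form(rng):
    """With nearly noiseless mediators the total effect of an exogenous node
    equals its reduced-form simple-regression standardized slope."""
    paths = dict(DEFAULT_TRUE_PATHS)
    noise = {"body_size": 0.1, "size_variance": 0.1, "trophic_structure": 0.1, "richness": 0.6}
    df = simulate_linear_sem(paths, 2000, rng, noise_sd=noise)
    fit = fit_psem(PathModelSpec.canonical(), df)
    z = lambda s: (s - s.mean()) / s.std(ddof=1)
    for exog in ("climate", "instability"):
        slope = float(np.polyfit(z(df[exog]), z(df["richness"]), 1)[0])
        assert fit.effects.loc[exog, "total"] == pytest.approx(slope, abs=0.05)


def test_mem_inclusion_never_increases_residual_autocorrelation():
    cfg = SyntheticConfig(grid_nx=20, grid_ny=15, seed=30)
    table, _ = generate_grid_sem_data(cfg, spatial=True)
    from tetraclim.spatial import build_spatial_weights, compute_mem_basis

    w = build_spatial_weights(table[["cx", "cy"]].to_numpy())
    basis = compute_mem_basis(w)
    fit = fit_psem(PathModelSpec.canonical(), table, weights=w, basis=basis, n_perm=199, seed=3)
    for node, audit in fit.residual_morans_i.items():
        assert abs(audit["after"]) <= abs(audit["before"]) + 1e-9
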