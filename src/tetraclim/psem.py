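"""Piecewise structural equation models over gridded assemblage data.

A piecewise SEM is estimated as a set of local OLS regressions — one per
endogenous node of a directed acyclic path model — rather than a single
covariance-matrix likelihood.  Global goodness of fit comes from tests of
directed separation: every pair of non-adjacent nodes yields a conditional
independence claim, each claim is tested by the p-value of the would-be
predictor in an augmented regression, and Fisher's C = -2 * sum(ln p_i) is
referred to a chi-square distribution with 2k degrees of freedom.

The full workflow (``fit_psem``) mirrors the study design: a collinearity
prefilter (|r| > 0.7 resolved by single-predictor AIC), OLS submodels,
per-submodel selection of Moran's eigenvector maps that minimize residual
spatial autocorrelation, refitting with the selected eigenvectors, the
d-separation test, and the decomposition of standardized effects on the
response into direct, indirect (products of coefficients along mediated
paths), and total (direct + indirect) components.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from tetraclim.spatial import MemBasis, MirSelection, SpatialWeights, morans_i, select_mems_mir

logger = logging.getLogger(__name__)

__all__ = [
    "PathModelSpec",
    "SubmodelFit",
    "DsepClaim",
    "SemFit",
    "collinearity_prefilter",
    "fit_submodel",
    "dsep_fisher_c",
    "effect_decomposition",
    "fit_psem",
]


@dataclasses.dataclass(frozen=True)
class PathModelSpec:
    """A directed acyclic path model with optional correlated errors.

    ``edges`` are (cause, effect) pairs over data columns; every node with at
    least one incoming edge gets its own OLS submodel.  ``correlated_errors``
    are unordered pairs whose residual covariance is left free — they are
    excluded from the d-separation basis set (the standard treatment of free
    covariances).  ``response`` names the final outcome used in effect
    decomposition.
    """

    edges: tuple[tuple[str, str], ...]
    correlated_errors: frozenset = frozenset()
    response: str = "richness"
    #: Extra unordered pairs excluded from the basis set, e.g. an indicator
    #: versus a deterministic composite built from it (no testable claim).
    excluded_claims: frozenset = frozenset()

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        for pair in self.correlated_errors:
            a, b = tuple(pair)
            if g.has_edge(a, b) or g.has_edge(b, a):
                raise ValueError(f"correlated-error pair ({a}, {b}) must be non-adjacent")

    @property
    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    @property
    def endogenous(self) -> list[str]:
        g = self.graph
        return [v for v in self.nodes if g.in_degree(v) > 0]

    @property
    def exogenous(self) -> list[str]:
        g = self.graph
        return [v for v in self.nodes if g.in_degree(v) == 0]

    @classmethod
    def canonical(
        cls,
        traits: Sequence[str] = ("body_size", "size_variance", "trophic_structure"),
        exogenous: Sequence[str] = ("climate", "instability"),
        response: str = "richness",
    ) -> "PathModelSpec":
        """The theoretical model: climate drivers -> traits -> richness."""
        edges = (
            [(e, t) for e in exogenous for t in traits]
            + [(e, response) for e in exogenous]
            + [(t, response) for t in traits]
        )
        pairs = frozenset(frozenset(p) for p in itertools.combinations(traits, 2))
        return cls(edges=tuple(edges), correlated_errors=pairs, response=response)


@dataclasses.dataclass
class SubmodelFit:
    """One OLS submodel of a piecewise SEM.

    Standardized coefficients ``std_coefs`` (``b * sd(x) / sd(y)``) cover the
    substantive predictors only; selected spatial eigenvectors enter the
    design but are excluded from reporting.
    """

    response: str
    predictors: tuple[str, ...]
    mems: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    std_coefs: pd.Series
    r_squared: float
    aic: float
    residuals: np.ndarray
    nobs: int


@dataclasses.dataclass(frozen=True)
class DsepClaim:
    """One independence claim of the basis set, with its test result."""

    pair: tuple[str, str]  # (independent predictor, regressed node)
    conditioning: tuple[str, ...]
    p_value: float


@dataclasses.dataclass
class SemFit:
    """A fitted piecewise SEM."""

    spec: PathModelSpec
    submodels: dict[str, SubmodelFit]
    claims: list[DsepClaim]
    fisher_c: float
    df: int
    p_value: float
    effects: pd.DataFrame
    collinearity_log: list[dict]
    mem_selection: dict[str, MirSelection]
    residual_morans_i: dict[str, dict[str, float]]

    @property
    def saturated(self) -> bool:
        return self.df == 0

    def coefficient(self, cause: str, effect: str) -> float:
        return float(self.submodels[effect].std_coefs[cause])


def collinearity_prefilter(
    data: pd.DataFrame,
    candidates: Sequence[str],
    response: str,
    threshold: float = 0.7,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop one member of every highly correlated predictor pair.

    For each pair with |Pearson r| > ``threshold`` (most correlated pair
    first), the member whose single-predictor model for ``response`` has the
    higher AIC is dropped; iteration continues until no remaining pair
    exceeds the threshold.  Returns the retained variables (original order)
    and a decision log.
    """
    retained = list(candidates)
    if len(retained) < 2:
        return retained, []
    log: list[dict] = []
    aic_cache: dict[str, float] = {}

    def single_aic(var: str) -> float:
        if var not in aic_cache:
            x = sm.add_constant(data[[var]].to_numpy(dtype=float))
            aic_cache[var] = float(sm.OLS(data[response].to_numpy(dtype=float), x).fit().aic)
        return aic_cache[var]

    while True:
        corr = data[retained].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        worst = corr.stack().idxmax()
        r = float(corr.loc[worst])
        if r <= threshold:
            break
        a, b = sorted(worst)
        drop = a if single_aic(a) > single_aic(b) else b
        keep = b if drop == a else a
        log.append(
            {"pair": (a, b), "abs_r": r, "dropped": drop, "kept": keep,
             "aic_dropped": single_aic(drop), "aic_kept": single_aic(keep)}
        )
        logger.info("collinearity prefilter: dropped %s (|r|=%.3f with %s)", drop, r, keep)
        retained.remove(drop)
        if len(retained) < 2:
            break
    return retained, log


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")


def fit_submodel(
    response: str,
    predictors: Sequence[str],
    data: pd.DataFrame,
    mems: pd.DataFrame | None = None,
) -> SubmodelFit:
    """OLS submodel with optional spatial eigenvector covariates.

    Standardized coefficients are reported for the substantive predictors
    only; residuals are retained for the spatial-autocorrelation audit.
    """
    predictors = list(predictors)
    mem_cols = list(mems.columns) if mems is not None else []
    n = len(data)
    if n <= len(predictors) + len(mem_cols) + 1:
        raise ValueError("not enough observations for the requested design")
    design = data[predictors].astype(float).copy()
    if mems is not None:
        design = pd.concat([design, mems.astype(float)], axis=1)
    design.insert(0, "const", 1.0)
    _check_rank(design)
    y = data[response].to_numpy(dtype=float)
    fit = sm.OLS(y, design).fit()
    sd_y = float(np.std(y, ddof=1))
    std = pd.Series(
        {p: float(fit.params[p]) * float(data[p].std(ddof=1)) / sd_y for p in predictors}
    )
    return SubmodelFit(
        response=response,
        predictors=tuple(predictors),
        mems=tuple(mem_cols),
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        std_coefs=std,
        r_squared=float(fit.rsquared),
        aic=float(fit.aic),
        residuals=np.asarray(fit.resid),
        nobs=n,
    )


def basis_set(spec: PathModelSpec) -> list[tuple[str, str, tuple[str, ...]]]:
    """Independence claims implied by the path model.

    One claim per non-adjacent node pair, conditioning on the union of both
    nodes' parents; the node later in topological order is the regressed
    variable.  Pairs declared as correlated errors and pairs of two exogenous
    nodes (free covariances) are excluded.
    """
    g = spec.graph
    order = spec.nodes
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for u, v in itertools.combinations(order, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if frozenset((u, v)) in spec.correlated_errors or frozenset((u, v)) in spec.excluded_claims:
            continue
        if g.in_degree(u) == 0 and g.in_degree(v) == 0:
            continue
        first, second = (u, v) if pos[u] < pos[v] else (v, u)
        cond = sorted((set(g.predecessors(first)) | set(g.predecessors(second))) - {first, second})
        claims.append((first, second, tuple(cond)))
    return claims


def dsep_fisher_c(
    spec: PathModelSpec,
    data: pd.DataFrame,
    mems_by_response: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[list[DsepClaim], float, int, float]:
    """Tests of directed separation and Fisher's C.

    Each claim (u _||_ v | parents) is tested by regressing the later node on
    the earlier one plus the conditioning set (plus that submodel's spatial
    eigenvectors, when provided) and reading off the p-value of the added
    predictor.  Returns ``(claims, C, df, p)``; a saturated model (empty
    basis set) yields ``C = nan``, ``df = 0``, ``p = nan``.
    """
    claims_spec = basis_set(spec)
    claims: list[DsepClaim] = []
    for first, second, cond in claims_spec:
        cols = [first] + list(cond)
        design = data[cols].astype(float)
        if mems_by_response and second in mems_by_response:
            design = pd.concat([design, mems_by_response[second].astype(float)], axis=1)
        design = sm.add_constant(design)
        fit = sm.OLS(data[second].to_numpy(dtype=float), design).fit()
        claims.append(DsepClaim(pair=(first, second), conditioning=cond, p_value=float(fit.pvalues[first])))
    if not claims:
        logger.info("saturated model: empty basis set, Fisher's C undefined")
        return [], float("nan"), 0, float("nan")
    tiny = np.finfo(float).tiny
    c = -2.0 * float(sum(np.log(max(cl.p_value, tiny)) for cl in claims))
    df = 2 * len(claims)
    p = float(stats.chi2.sf(c, df))
    return claims, c, df, p


def effect_decomposition(
    spec: PathModelSpec,
    coefficients: Mapping[tuple[str, str], float],
    response: str | None = None,
) -> pd.DataFrame:
    """Direct / indirect / total standardized effects on the response.

    The direct effect of a node is its edge coefficient into the response
    (zero if absent); each mediated path contributes the product of the
    standardized coefficients along it; the indirect effect is the sum over
    all such multi-edge paths, and total = direct + indirect exactly.
    """
    response = response or spec.response
    g = nx.DiGraph()
    for (a, b), c in coefficients.items():
        g.add_edge(a, b, coef=float(c))
    rows = []
    for node in spec.nodes:
        if node == response:
            continue
        direct = float(g[node][response]["coef"]) if g.has_edge(node, response) else 0.0
        indirect = 0.0
        if node in g and response in g:
            for path in nx.all_simple_paths(g, node, response):
                if len(path) <= 2:
                    continue
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= g[a][b]["coef"]
                indirect += prod
        rows.append({"node": node, "direct": direct, "indirect": indirect, "total": direct + indirect})
    return pd.DataFrame(rows).set_index("node")


def fit_psem(
    spec: PathModelSpec,
    data: pd.DataFrame,
    weights: SpatialWeights | None = None,
    basis: MemBasis | None = None,
    *,
    prefilter: bool = False,
    collinearity_threshold: float = 0.7,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    max_mems: int | None = None,
    i_ceiling: float | None = None,
) -> SemFit:
    """Fit the full piecewise SEM.

    Stages: optional collinearity prefilter over each submodel's predictors
    (dropped predictors lose their edges) -> base OLS submodels -> when a
    spatial weight matrix and MEM basis are supplied, per-submodel MIR
    selection on the base residuals followed by a refit with the selected
    eigenvectors -> d-separation / Fisher's C -> standardized effect
    decomposition.  Residual Moran's I before/after eigenvector inclusion is
    recorded per submodel.
    """
    edges = list(spec.edges)
    collinearity_log: list[dict] = []
    if prefilter:
        g = spec.graph
        for node in spec.endogenous:
            parents = sorted(g.predecessors(node))
            kept, log = collinearity_prefilter(data, parents, node, threshold=collinearity_threshold)
            for entry in log:
                entry["response"] = node
            collinearity_log.extend(log)
            dropped = set(parents) - set(kept)
            edges = [e for e in edges if not (e[1] == node and e[0] in dropped)]
        spec = dataclasses.replace(spec, edges=tuple(edges))

    g = spec.graph
    submodels: dict[str, SubmodelFit] = {}
    mem_selection: dict[str, MirSelection] = {}
    mems_by_response: dict[str, pd.DataFrame] = {}
    residual_mi: dict[str, dict[str, float]] = {}
    for k, node in enumerate(spec.endogenous):
        parents = sorted(g.predecessors(node))
        base = fit_submodel(node, parents, data)
        fit = base
        if weights is not None and basis is not None and basis.n_vectors > 0:
            before = morans_i(base.residuals, weights)
            sel = select_mems_mir(
                base.residuals,
                basis,
                weights,
                alpha=alpha,
                n_perm=n_perm,
                seed=seed + 1000 * k,
                design=data[parents].to_numpy(dtype=float),
                response=data[node].to_numpy(dtype=float),
                i_ceiling=i_ceiling,
                max_select=max_mems,
            )
            mem_selection[node] = sel
            if sel.selected:
                mem_df = pd.DataFrame(
                    {f"MEM{j + 1}": basis.vectors[:, j] for j in sel.selected}, index=data.index
                )
                mems_by_response[node] = mem_df
                fit = fit_submodel(node, parents, data, mems=mem_df)
            residual_mi[node] = {"before": before, "after": morans_i(fit.residuals, weights)}
        submodels[node] = fit

    claims, c, df, p = dsep_fisher_c(spec, data, mems_by_response or None)
    coefs = {
        (pred, node): float(submodels[node].std_coefs[pred])
        for node in submodels
        for pred in submodels[node].predictors
    }
    effects = effect_decomposition(spec, coefs)
    return SemFit(
        spec=spec,
        submodels=submodels,
        claims=claims,
        fisher_c=c,
        df=df,
        p_value=p,
        effects=effects,
        collinearity_log=collinearity_log,
        mem_selection=mem_selection,
        residual_morans_i=residual_mi,
    )
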