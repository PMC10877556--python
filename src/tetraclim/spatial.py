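"""Distance-based Moran's eigenvector maps (dbMEM) and spatial diagnostics.

The dbMEM construction follows the standard recipe: a truncation distance
``t`` equal to the longest edge of the Euclidean minimum spanning tree over
the cell centroids, spatial weights ``w_ij = 1 - (d_ij / (4 t))**2`` for
``0 < d_ij <= t`` (zero otherwise), eigen-decomposition of the doubly
centered weight matrix, and retention of the eigenvectors with positive
eigenvalues (positive spatial autocorrelation).  Eigenvector selection for a
regression model minimizes the absolute Moran's I of the model residuals
(MIR forward selection), stopping once a permutation test no longer detects
residual autocorrelation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialWeights",
    "MemBasis",
    "MirSelection",
    "build_spatial_weights",
    "lattice_rook_weights",
    "compute_mem_basis",
    "morans_i",
    "expected_morans_i",
    "morans_i_test",
    "select_mems_mir",
]


@dataclasses.dataclass(frozen=True)
class SpatialWeights:
    """Symmetric spatial weight matrix over analysis cells.

    Attributes
    ----------
    matrix : (n, n) ndarray
        Symmetric, nonnegative, zero diagonal.
    rule : str
        Identifier of the connectivity rule used to build the matrix.
    truncation : float or None
        Truncation distance ``t`` (None for rules without one).
    """

    matrix: np.ndarray
    rule: str = "dbmem"
    truncation: float | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (the normalizer in Moran's I)."""
        return float(self.matrix.sum())


@dataclasses.dataclass(frozen=True)
class MemBasis:
    """Moran's eigenvector maps: columns of ``vectors`` are the MEMs.

    Only positive-eigenvalue eigenvectors are kept, ordered by decreasing
    eigenvalue, so Moran's I is non-increasing with rank.  Every retained
    vector has zero sum (a consequence of the double centering) and unit
    Euclidean norm.
    """

    vectors: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    morans_i: np.ndarray  # (k,)

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass(frozen=True)
class MirSelection:
    """Outcome of MIR forward selection.

    ``selected`` holds MEM column indices in the order they were added;
    ``residual_i_path`` records |Moran's I| of the residuals before any
    selection and after each addition; ``p_values`` the permutation p-value
    of the residuals at each stopping check.
    """

    selected: list[int]
    residual_i_path: list[float]
    p_values: list[float]


def build_spatial_weights(coords: np.ndarray, rule: str = "dbmem") -> SpatialWeights:
    """Build a dbMEM spatial weight matrix from cell centroid coordinates.

    The truncation distance ``t`` is the longest edge of the Euclidean
    minimum spanning tree over the centroids, which guarantees the graph of
    nonzero weights is connected.  Weights decay as ``1 - (d/(4t))**2``
    within the truncation distance and are zero beyond it.

    Parameters
    ----------
    coords : (n, 2) array
        Projected centroid coordinates; at least 3 distinct points.
    rule : str
        Only ``"dbmem"`` is implemented.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 coordinates to build spatial weights")
    if rule != "dbmem":
        raise ValueError(f"unknown connectivity rule {rule!r}")
    condensed = pdist(coords)
    if np.any(condensed == 0.0):
        raise ValueError("duplicate coordinates are not allowed")
    dist = squareform(condensed)
    mst = minimum_spanning_tree(dist)
    t = float(mst.data.max())
    # MST edges are <= t by construction, so the truncated graph stays connected.
    with np.errstate(invalid="ignore"):
        w = 1.0 - (dist / (4.0 * t)) ** 2
    w[(dist <= 0.0) | (dist > t)] = 0.0
    np.fill_diagonal(w, 0.0)
    assert _is_connected(w), "truncated weight graph must be connected"
    return SpatialWeights(matrix=w, rule="dbmem", truncation=t)


def lattice_rook_weights(nx: int, ny: int) -> SpatialWeights:
    """Binary rook-contiguity weights for an ``nx`` x ``ny`` lattice.

    Cells are ordered row-major (y outer, x inner), matching the flattening
    used by the synthetic climate fields.  Convenience for diagnostics and
    calibration runs.
    """
    n = nx * ny
    w = np.zeros((n, n))
    for j in range(ny):
        for i in range(nx):
            k = j * nx + i
            if i + 1 < nx:
                w[k, k + 1] = w[k + 1, k] = 1.0
            if j + 1 < ny:
                w[k, k + nx] = w[k + nx, k] = 1.0
    return SpatialWeights(matrix=w, rule="rook", truncation=None)


def _is_connected(w: np.ndarray) -> bool:
    n = w.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(w[i])[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def compute_mem_basis(weights: SpatialWeights, tol: float = 1e-9) -> MemBasis:
    """Eigen-decompose the doubly centered weight matrix.

    With ``H = I - 11'/n`` the spectrum of ``H W H`` splits the eigenvectors
    into positive spatial autocorrelation (eigenvalue > 0) and negative
    (eigenvalue < 0); only the positive side is retained, ordered by
    decreasing eigenvalue.  Moran's I of eigenvector ``k`` equals
    ``(n / S0) * eigenvalue_k``, so the stored Moran's I values are
    non-increasing with rank.
    """
    w = weights.matrix
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells for a MEM basis")
    h = np.eye(n) - np.ones((n, n)) / n
    omega = h @ w @ h
    omega = (omega + omega.T) / 2.0
    eigval, eigvec = np.linalg.eigh(omega)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    cutoff = tol * max(1.0, float(np.abs(eigval).max()))
    keep = eigval > cutoff
    vectors = eigvec[:, keep]
    values = eigval[keep]
    mi = np.array([morans_i(vectors[:, k], weights) for k in range(vectors.shape[1])])
    return MemBasis(vectors=vectors, eigenvalues=values, morans_i=mi)


def morans_i(x: np.ndarray, weights: SpatialWeights) -> float:
    """Moran's I spatial autocorrelation statistic.

    ``I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i**2)`` with
    ``z = x - mean(x)``.  Raises on constant input, for which the statistic
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant variable")
    w = weights.matrix
    return float(weights.n / weights.s0 * (z @ w @ z) / denom)


def expected_morans_i(n: int) -> float:
    """Null expectation of Moran's I for i.i.d. data: ``-1/(n-1)``."""
    return -1.0 / (n - 1)


def morans_i_test(
    x: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Two-sided permutation test for Moran's I.

    Returns ``(I, p)`` with ``p = (1 + #{|I_perm| >= |I|}) / (n_perm + 1)``;
    the permutation distribution is generated by shuffling cell labels, so
    the p-value is exact-by-construction and always in ``(0, 1]``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant variable")
    w = weights.matrix
    scale = weights.n / weights.s0
    i_obs = scale * float(z @ w @ z) / denom
    zp = rng.permuted(np.broadcast_to(z, (n_perm, z.size)).copy(), axis=1)
    i_perm = scale * np.einsum("ij,ij->i", zp, zp @ w) / denom
    p = (1.0 + np.count_nonzero(np.abs(i_perm) >= abs(i_obs))) / (n_perm + 1.0)
    return float(i_obs), float(p)


def _ols_residuals(y: np.ndarray, columns: list[np.ndarray]) -> np.ndarray:
    n = y.size
    design = np.column_stack([np.ones(n)] + columns) if columns else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def select_mems_mir(
    residuals: np.ndarray,
    basis: MemBasis,
    weights: SpatialWeights,
    *,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    design: np.ndarray | None = None,
    response: np.ndarray | None = None,
    i_ceiling: float | None = None,
    max_select: int | None = None,
) -> MirSelection:
    """Forward selection of MEMs minimizing residual |Moran's I| (MIR).

    Starting from the residuals of a model fitted without spatial terms, the
    selection repeatedly adds the candidate eigenvector whose inclusion most
    reduces the absolute Moran's I of the refitted model's residuals.  It
    stops as soon as a permutation test finds the current residuals spatially
    independent at ``alpha`` (optionally, when |I| drops below ``i_ceiling``),
    when no candidate reduces |I|, or when the basis is exhausted.  Ties are
    broken in favor of the lowest eigenvector rank.

    Parameters
    ----------
    residuals : (n,) array
        Residuals of the non-spatial model.
    design, response : optional
        Substantive predictor matrix (without intercept) and the response of
        the model being augmented.  When provided, each candidate step refits
        the full model with the candidate MEMs added; when omitted, the
        residuals themselves are regressed on the selected MEMs, which is
        equivalent when the MEMs are orthogonal to the predictors.
    i_ceiling : float, optional
        Additional absolute-|I| stopping ceiling (the permissive variant);
        None disables it.
    """
    if basis.n_vectors == 0:
        return MirSelection(selected=[], residual_i_path=[], p_values=[])
    rng = np.random.default_rng(seed)
    residuals = np.asarray(residuals, dtype=float)
    if design is not None:
        if response is None:
            raise ValueError("response is required when design is given")
        response = np.asarray(response, dtype=float)
        base_cols = [np.asarray(design, dtype=float)[:, j] for j in range(np.asarray(design).shape[1])]
    else:
        response = residuals
        base_cols = []

    selected: list[int] = []
    path: list[float] = []
    p_values: list[float] = []
    current_resid = residuals
    remaining = list(range(basis.n_vectors))
    while True:
        i_cur, p = morans_i_test(current_resid, weights, n_perm=n_perm, seed=rng)
        path.append(abs(i_cur))
        p_values.append(p)
        if p > alpha:
            break
        if i_ceiling is not None and abs(i_cur) < i_ceiling:
            break
        if not remaining or (max_select is not None and len(selected) >= max_select):
            break
        best_k, best_i, best_resid = None, abs(i_cur), None
        for k in remaining:
            cols = base_cols + [basis.vectors[:, j] for j in selected + [k]]
            resid_k = _ols_residuals(response, cols)
            i_k = abs(morans_i(resid_k, weights))
            if i_k < best_i - 1e-15:
                best_k, best_i, best_resid = k, i_k, resid_k
        if best_k is None:  # no candidate reduces |I|
            break
        selected.append(best_k)
        remaining.remove(best_k)
        current_resid = best_resid
    return MirSelection(selected=selected, residual_i_path=path, p_values=p_values)
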