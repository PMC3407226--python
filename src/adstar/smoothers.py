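"""Penalized-basis machinery for the structured additive predictor.

Three smooth-term building blocks:

* cubic B-spline design matrices on equidistant knots (P-splines), penalized
  by the second-difference penalty that corresponds to a second-order
  random-walk (RW2) prior on adjacent spline coefficients;
* the Markov-random-field (MRF) penalty for areal spatial effects — the graph
  Laplacian of the district adjacency graph, equivalently the precision
  structure of the intrinsic conditional autoregressive (CAR) prior in which a
  district's effect is conditionally normal around the mean of its neighbours
  with variance tau^2 / n_neighbours;
* sum-to-zero constraint absorption that reparameterizes a smooth so its
  fitted contribution is orthogonal to the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis",
    "PenaltyMatrix",
    "ConstrainedSmooth",
    "bspline_basis",
    "rw2_penalty",
    "mrf_penalty",
    "apply_constraint",
]

#: Relative eigenvalue tolerance below which an eigenvalue counts as zero.
NULLSPACE_RTOL = 1e-9


@dataclass(frozen=True)
class SplineBasis:
    """Equidistant B-spline basis over the observed covariate range."""

    knots: np.ndarray  # full (boundary-extended) knot vector
    degree: int
    lo: float
    hi: float

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, values: np.ndarray) -> sp.csr_matrix:
        """Evaluate the basis at ``values`` (must lie in [lo, hi])."""
        x = np.asarray(values, dtype=float)
        if np.any(x < self.lo) or np.any(x > self.hi):
            raise ValueError(
                f"values outside basis range [{self.lo}, {self.hi}]"
            )
        return sp.csr_matrix(
            BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False)
        )


@dataclass(frozen=True)
class PenaltyMatrix:
    """Symmetric PSD penalty with a known null-space dimension."""

    matrix: np.ndarray
    nullspace_dim: int

    def __post_init__(self) -> None:
        K = self.matrix
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("penalty must be square")
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("penalty must be symmetric")

    def quad_form(self, b: np.ndarray) -> float:
        return float(b @ self.matrix @ b)


def nullspace_dimension(K: np.ndarray, rtol: float = NULLSPACE_RTOL) -> int:
    """Count eigenvalues below rtol * max eigenvalue (0-matrix => dim n)."""
    ev = np.linalg.eigvalsh((K + K.T) / 2.0)
    top = ev[-1] if ev.size else 0.0
    if top <= 0:
        return K.shape[0]
    return int(np.sum(ev < rtol * top))


def bspline_basis(
    values: Sequence[float] | np.ndarray,
    n_interior_knots: int,
    degree: int = 3,
) -> tuple[SplineBasis, sp.csr_matrix]:
    """Equidistant B-spline basis evaluated at ``values``.

    The knot grid places ``n_interior_knots`` equally spaced knots strictly
    inside the covariate range and extends ``degree`` further knots at the
    same spacing beyond each boundary, giving ``n_interior_knots + degree + 1``
    basis functions whose rows form a partition of unity on the range.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("covariate is constant; cannot build a spline basis")
    if n_interior_knots < degree:
        raise ValueError(
            f"need n_interior_knots >= degree, got {n_interior_knots} < {degree}"
        )
    h = (hi - lo) / (n_interior_knots + 1)
    knots = lo + h * np.arange(-degree, n_interior_knots + degree + 2)
    # guard against fp drift so boundary values evaluate inside the support
    knots[degree] = lo
    knots[-degree - 1] = hi if degree > 0 else knots[-1]
    basis = SplineBasis(knots=knots, degree=degree, lo=lo, hi=hi)
    X = basis.design(x)
    return basis, X


def rw2_penalty(n_coef: int) -> PenaltyMatrix:
    """Second-order random-walk penalty K = D2' D2 on coefficient sequences.

    D2 is the (n-2) x n second-difference operator; the null space is spanned
    by constant and linear coefficient sequences.
    """
    if n_coef < 3:
        raise ValueError(f"RW2 penalty needs >= 3 coefficients, got {n_coef}")
    D = np.diff(np.eye(n_coef), n=2, axis=0)
    return PenaltyMatrix(matrix=D.T @ D, nullspace_dim=2)


def mrf_penalty(edges: Sequence[tuple], nodes: Optional[Sequence] = None) -> tuple[PenaltyMatrix, list]:
    """Graph-Laplacian penalty of the intrinsic CAR prior.

    ``edges`` is an undirected edge list; ``nodes`` fixes the row order
    (default: sorted).  Diagonal = neighbour counts, off-diagonal = -1 for
    neighbours.  Row s of K / tau^2 is the conditional precision of district
    s given the rest: effect_s | rest ~ N(mean of neighbours, tau^2 / n_s).
    Returns the penalty together with the node order used.
    """
    seen = set()
    G = nx.Graph()
    if nodes is not None:
        G.add_nodes_from(nodes)
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop at node {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate edge {a!r}-{b!r}")
        seen.add(key)
        G.add_edge(a, b)
    order = list(nodes) if nodes is not None else sorted(G.nodes())
    K = nx.laplacian_matrix(G, nodelist=order).toarray().astype(float)
    n_components = nx.number_connected_components(G)
    return PenaltyMatrix(matrix=K, nullspace_dim=n_components), order


@dataclass(frozen=True)
class ConstrainedSmooth:
    """A smooth term reparameterized to a (weighted) sum-to-zero subspace.

    ``design`` is the constrained n x (p-1) design, ``penalty`` the penalty
    expressed in the constrained coordinates, and ``transform`` the p x (p-1)
    map back to original basis coefficients (original = transform @ beta).
    """

    name: str
    design: sp.csr_matrix = field(repr=False)
    penalty: PenaltyMatrix
    transform: np.ndarray = field(repr=False)

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]


def apply_constraint(
    name: str,
    design: sp.spmatrix | np.ndarray,
    penalty: PenaltyMatrix,
    weights: Optional[np.ndarray] = None,
) -> ConstrainedSmooth:
    """Absorb the (weighted) sum-to-zero constraint into a smooth term.

    Finds an orthonormal basis Z of the null space of the 1 x p constraint
    row c = w' B and returns the term with design B Z and penalty Z' K Z, so
    that any fitted contribution satisfies sum_i w_i f(x_i) = 0.  With no
    weights the plain mean constraint is used.  The penalty's remaining null
    directions (e.g. the linear trend of an RW2 smooth) stay in the block as
    unpenalized coordinates.
    """
    B = sp.csr_matrix(design)
    n, p = B.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    c = np.asarray(B.T @ w, dtype=float).ravel()  # 1 x p constraint
    norm = np.linalg.norm(c)
    if norm < 1e-12:  # already orthogonal to the intercept
        Z = np.eye(p)
    else:
        # Householder-style null-space basis: columns 2..p of the orthogonal
        # complement of c.
        q, _ = np.linalg.qr(np.column_stack([c / norm, np.eye(p)[:, : p - 1]]))
        Z = q[:, 1:]
        # ensure exact orthogonality to c
        Z = Z - np.outer(c, c @ Z) / (norm**2)
    Kc = Z.T @ penalty.matrix @ Z
    Kc = (Kc + Kc.T) / 2.0
    new_null = nullspace_dimension(Kc)
    return ConstrainedSmooth(
        name=name,
        design=sp.csr_matrix(B @ Z),
        penalty=PenaltyMatrix(matrix=Kc, nullspace_dim=new_null),
        transform=Z,
    )
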