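"""Linear (P1) tetrahedral finite-element assembly and solvers.

Shared by the fiber-orientation Laplace solves and the quasistatic
volume-conductor Poisson solve.  Conventions:

* stiffness  K_ij = ∫ ∇N_i · σ ∇N_j dΩ   (σ scalar or 3×3 per tet)
* Robin surface term  ∫ α N_i N_j dΓ  on boundary triangles
* loads: volume source density s (A/m³), surface flux g = -∇ϕ·n, and the
  Robin external-potential term α ϕ_e.
* Dirichlet constraints are eliminated (row/column removal), which keeps the
  reduced system symmetric positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

DIRECT_SOLVE_LIMIT = 10_000   # unknowns; above this use preconditioned CG


class SolverError(RuntimeError):
    pass


def shape_gradients(vertices: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the 4 barycentric shape functions per tet and tet volumes.

    Returns (grads, vols): grads (m, 4, 3) with grads[e, i] = ∇λ_i, vols (m,).
    """
    v0 = vertices[tets[:, 0]]
    J = np.stack(
        [vertices[tets[:, i]] - v0 for i in (1, 2, 3)], axis=2
    )  # (m, 3, 3) columns are edge vectors
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise SolverError("degenerate or inverted tets in FEM assembly")
    # barycentric coords satisfy (λ1,λ2,λ3) = J^{-1}(x - v0), so ∇λ_i is the
    # i-th row of J^{-1}
    g123 = np.linalg.inv(J)              # (m, 3, 3), g123[e, i-1, :] = ∇λ_i
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)   # (m, 4, 3)
    return grads, detJ / 6.0


def assemble_stiffness(
    vertices: np.ndarray, tets: np.ndarray, sigma: np.ndarray | float = 1.0
) -> sp.csr_matrix:
    """Stiffness matrix with per-tet conductivity.

    ``sigma`` may be a scalar, an (m,) array of scalars, or an (m, 3, 3)
    array of symmetric tensors.
    """
    n = len(vertices)
    grads, vols = shape_gradients(vertices, tets)
    sig = np.asarray(sigma, dtype=np.float64)
    if sig.ndim == 3:
        flux = np.einsum("eab,eib->eia", sig, grads)
    else:
        if sig.ndim == 0:
            sig = np.full(len(tets), float(sig))
        flux = grads * sig[:, None, None]
    Ke = np.einsum("eia,eja->eij", flux, grads) * vols[:, None, None]  # (m,4,4)
    m = len(tets)
    t32 = tets.astype(np.int32)
    rows = np.broadcast_to(t32[:, :, None], (m, 4, 4)).reshape(-1)
    cols = np.broadcast_to(t32[:, None, :], (m, 4, 4)).reshape(-1)
    K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)), shape=(n, n))
    return K.tocsr()


def triangle_areas(vertices: np.ndarray, tris: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(
        np.cross(
            vertices[tris[:, 1]] - vertices[tris[:, 0]],
            vertices[tris[:, 2]] - vertices[tris[:, 0]],
        ),
        axis=1,
    )


def assemble_boundary_mass(
    n: int, vertices: np.ndarray, tris: np.ndarray, coeff: float | np.ndarray
) -> sp.csr_matrix:
    """∫ coeff N_i N_j dΓ over the triangles (consistent P1 surface mass)."""
    if len(tris) == 0:
        return sp.csr_matrix((n, n))
    areas = triangle_areas(vertices, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=np.float64), (len(tris),))
    Me = (np.ones((3, 3)) + np.eye(3)) / 12.0
    vals = (c * areas)[:, None, None] * Me[None, :, :]
    rows = np.repeat(tris, 3, axis=1).reshape(-1)
    cols = np.tile(tris, (1, 3)).reshape(-1)
    return sp.coo_matrix((vals.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def surface_load(n: int, vertices: np.ndarray, tris: np.ndarray, g: float | np.ndarray) -> np.ndarray:
    """Load from a boundary flux or Robin α·ϕ_e term: each triangle spreads
    g·A/3 to its vertices."""
    b = np.zeros(n)
    if len(tris) == 0:
        return b
    areas = triangle_areas(vertices, tris)
    gv = np.broadcast_to(np.asarray(g, dtype=np.float64), (len(tris),))
    contrib = (gv * areas / 3.0)[:, None].repeat(3, axis=1)
    np.add.at(b, tris.reshape(-1), contrib.reshape(-1))
    return b


def volume_load(
    n: int, vertices: np.ndarray, tets: np.ndarray, s: float | np.ndarray
) -> np.ndarray:
    """Load from a per-tet volume source density s (lumped V/4 per vertex)."""
    b = np.zeros(n)
    if len(tets) == 0:
        return b
    _, vols = shape_gradients(vertices, tets)
    sv = np.broadcast_to(np.asarray(s, dtype=np.float64), (len(tets),))
    contrib = (sv * vols / 4.0)[:, None].repeat(4, axis=1)
    np.add.at(b, tets.reshape(-1), contrib.reshape(-1))
    return b


@dataclass
class SolveInfo:
    method: str
    residual: float
    iterations: int = 0


def solve_constrained(
    K: sp.csr_matrix,
    b: np.ndarray,
    dirichlet_idx: np.ndarray | None = None,
    dirichlet_val: float | np.ndarray = 0.0,
    rtol: float = 1e-10,
) -> tuple[np.ndarray, SolveInfo]:
    """Solve K x = b with Dirichlet constraints eliminated.

    Direct sparse LU below DIRECT_SOLVE_LIMIT unknowns, otherwise conjugate
    gradients with a Jacobi preconditioner.  Raises SolverError on a singular
    system (no constraints and no Robin term) or non-convergence.
    """
    n = K.shape[0]
    x = np.zeros(n)
    if dirichlet_idx is not None and len(dirichlet_idx):
        mask = np.ones(n, dtype=bool)
        mask[dirichlet_idx] = False
        free = np.flatnonzero(mask)
        vals = np.broadcast_to(np.asarray(dirichlet_val, dtype=np.float64),
                               (len(dirichlet_idx),))
        x[dirichlet_idx] = vals
        rhs = b[free] - K[free][:, dirichlet_idx] @ vals
        A = K[free][:, free]
    else:
        free = np.arange(n)
        rhs = b
        A = K
        # a pure-Neumann Laplacian is singular; detect via the constant vector
        if abs(A @ np.ones(n)).max() < 1e-9 * max(abs(A.diagonal()).max(), 1e-300):
            raise SolverError("singular system: no Dirichlet or Robin constraint present")

    if len(free) <= DIRECT_SOLVE_LIMIT:
        try:
            lu = spla.splu(A.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular factorization
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        xf = lu.solve(rhs)
        method = "splu"
        iters = 0
    else:
        # symmetric Jacobi scaling handles the large conductivity contrast
        # (e.g. the 10^6 S/m electrode regions) well for CG
        d = 1.0 / np.sqrt(A.diagonal())
        As = (sp.diags(d) @ A @ sp.diags(d)).tocsr()
        count = [0]
        y, info = spla.cg(As, d * rhs, rtol=1e-10, atol=0.0, maxiter=50_000,
                          callback=lambda _: count.__setitem__(0, count[0] + 1))
        if info != 0:
            raise SolverError(f"CG did not converge after {count[0]} iterations")
        xf = d * y
        method = "cg"
        iters = count[0]
    x[free] = xf
    rnorm = float(np.linalg.norm(A @ xf - rhs))
    bnorm = float(np.linalg.norm(rhs))
    rel = rnorm / bnorm if bnorm > 0 else rnorm
    if not np.isfinite(rel) or (bnorm > 0 and rel > 1e-5):
        raise SolverError(f"solver residual too large: {rel:.3e}")
    return x, SolveInfo(method=method, residual=rel, iterations=iters)
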