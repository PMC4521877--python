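"""Shared P1 tetrahedral finite-element kernels.

All operators here work on a node array (n, 3) in mm and a tet index array
(m, 4).  They are used by the transmural Laplace solve, the monodomain
solver and the co-rotational mechanics.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tet_volumes(nodes, tets):
    """Signed volumes (mm^3) of each tetrahedron."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def shape_gradients(nodes, tets):
    """Gradients of the four linear shape functions per element.

    Returns
    -------
    vols : (m,) positive volumes in mm^3
    grads : (m, 4, 3) gradient of shape function of local node k, in 1/mm
    """
    a = nodes[tets[:, 0]]
    # E columns are the edge vectors e_k = x_k - x_0; barycentric coords of
    # nodes 1..3 satisfy lambda = E^-1 (x - x_0), so grad(lambda_k) are the
    # rows of E^-1.
    E = np.stack([nodes[tets[:, k]] - a for k in (1, 2, 3)], axis=2)  # (m,3,3)
    vol6 = np.linalg.det(E)
    if np.any(np.abs(vol6) < 1e-12):
        bad = int(np.argmin(np.abs(vol6)))
        raise ValueError(f"degenerate tetrahedron {bad} (volume ~ 0)")
    g123 = np.linalg.inv(E)  # rows are gradients of local nodes 1..3
    g0 = -g123.sum(axis=1)
    grads = np.concatenate([g0[:, None, :], g123], axis=1)
    return np.abs(vol6) / 6.0, grads


def assemble_stiffness(nodes, tets, diffusivity):
    """Assemble the P1 stiffness matrix K_ij = sum_e V_e grad_i . D grad_j.

    ``diffusivity`` is either a scalar, an (m,) array of scalars, or an
    (m, 3, 3) array of per-element tensors.
    """
    vols, grads = shape_gradients(nodes, tets)
    D = np.asarray(diffusivity, dtype=float)
    if D.ndim == 0:
        Dg = D * grads
    elif D.ndim == 1:
        Dg = D[:, None, None] * grads
    else:
        Dg = np.einsum("eab,ekb->eka", D, grads)
    ke = np.einsum("eia,eja,e->eij", grads, Dg, vols)  # (m,4,4)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(len(nodes),) * 2)
    return K.tocsr()


def lumped_mass(nodes, tets):
    """Row-sum (lumped) P1 mass vector: V_e/4 to each node, in mm^3."""
    vols = np.abs(tet_volumes(nodes, tets))
    m = np.zeros(len(nodes))
    np.add.at(m, tets.ravel(), np.repeat(vols / 4.0, 4))
    return m


def solve_laplace_dirichlet(nodes, tets, dirichlet_nodes, dirichlet_values):
    """Solve div(grad u) = 0 with Dirichlet data; natural BC elsewhere."""
    from scipy.sparse.linalg import spsolve

    K = assemble_stiffness(nodes, tets, 1.0)
    n = len(nodes)
    fixed = np.zeros(n, dtype=bool)
    fixed[dirichlet_nodes] = True
    u = np.zeros(n)
    u[dirichlet_nodes] = dirichlet_values
    free = ~fixed
    rhs = -K[free][:, fixed] @ u[fixed]
    u[free] = spsolve(K[free][:, free].tocsc(), rhs)
    return u
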