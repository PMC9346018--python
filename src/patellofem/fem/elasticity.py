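"""Small-strain linear elasticity on 4-node tetrahedra.

Constant-strain elements with exact one-point integration; the assembled
operator is symmetric positive semi-definite with the six rigid-body
zero-energy modes before constraints are applied.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .materials import MaterialParams
from .tetmesh import TetMesh


def shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-element shape-function gradients and volumes.

    Returns ``grads`` of shape (m, 4, 3) with grad N_i per element, and
    volumes (m,).
    """
    X = nodes[tets]                       # (m, 4, 3)
    M = X[:, 1:] - X[:, :1]               # rows e1, e2, e3
    vol = np.linalg.det(M) / 6.0
    if np.any(np.abs(vol) < 1e-12):
        raise ValueError(f"inverted/degenerate element {int(np.argmin(np.abs(vol)))}")
    Minv = np.linalg.inv(M)               # (m, 3, 3)
    g = Minv.transpose(0, 2, 1)           # grad N_{i+1} = row i of M^{-T}
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vol


def b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, (m, 6, 12), Voigt
    [xx, yy, zz, xy, yz, zx] with engineering shears."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness(nodes4: np.ndarray, material: MaterialParams) -> np.ndarray:
    """12x12 stiffness block of a single tetrahedron."""
    grads, vol = shape_gradients(nodes4[None, ...], np.arange(4)[None, :])
    B = b_matrices(grads)[0]
    return float(vol[0]) * B.T @ material.stiffness_matrix() @ B


def assemble(mesh: TetMesh, material: MaterialParams) -> sp.csr_matrix:
    """Assembled global stiffness operator (3n x 3n, CSR)."""
    grads, vol = shape_gradients(mesh.nodes, mesh.tets)
    B = b_matrices(grads)                          # (m, 6, 12)
    C = material.stiffness_matrix()
    Ke = np.einsum("eik,ij,ejl,e->ekl", B, C, B, vol, optimize=True)  # (m,12,12)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    )
    return K.tocsr()


def element_stresses(
    mesh: TetMesh, material: MaterialParams, u: np.ndarray
) -> np.ndarray:
    """Per-element stress tensors in Voigt order, (m, 6), MPa.

    ``u`` is the flat (3n,) nodal displacement vector.
    """
    grads, _ = shape_gradients(mesh.nodes, mesh.tets)
    B = b_matrices(grads)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    eps = np.einsum("eij,ej->ei", B, ue)
    return eps @ material.stiffness_matrix().T


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress sqrt(3 J2) from Voigt stresses."""
    s = np.atleast_2d(stress_voigt)
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return vm if stress_voigt.ndim > 1 else float(vm[0])
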