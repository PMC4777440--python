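"""Normal modes: diagonalization, rigid-body removal, low-frequency selection.

Modes are exact eigenpairs of the (unit-mass) Cα Hessian.  A connected
three-dimensional structure has exactly six zero modes (three translations,
three rotations); degenerate toys that are exactly collinear have five.  Any
other near-zero count signals a disconnected or ill-conditioned network and
is reported as an error, including the connected components when the cause
is disconnection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg

from .enm import Hessian

__all__ = [
    "ModeSet",
    "ModeError",
    "DisconnectedStructureError",
    "compute_modes",
    "rigid_body_basis",
]

DEFAULT_N_MODES = 10
DEFAULT_RIGID_TOL = 1e-8
# above this many residues the dense eigensolve gives way to shift-invert
DENSE_LIMIT_RESIDUES = 800


class ModeError(ValueError):
    pass


class DisconnectedStructureError(ModeError):
    def __init__(self, n_near_zero: int, n_components: int):
        self.n_near_zero = n_near_zero
        self.n_components = n_components
        super().__init__(
            f"{n_near_zero} near-zero modes: the spring network has "
            f"{n_components} connected components (each rigid body "
            "contributes 6); analyze components separately"
        )


@dataclass
class ModeSet:
    """Low-frequency internal modes of one system, ascending eigenvalues."""

    eigenvalues: np.ndarray   # (n_modes,), energy/Å²
    vectors: np.ndarray       # (n_modes, 3N), orthonormal rows
    n_removed_rigid: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def frequencies(self) -> np.ndarray:
        """ω_μ = sqrt(λ_μ) in the model's natural units."""
        return np.sqrt(self.eigenvalues)

    def displacements(self, mu: int) -> np.ndarray:
        """Mode μ reshaped to per-residue 3-vectors, (N, 3)."""
        return self.vectors[mu].reshape(-1, 3)

    def subset(self, indices) -> "ModeSet":
        idx = np.asarray(indices, dtype=int)
        return ModeSet(
            eigenvalues=self.eigenvalues[idx],
            vectors=self.vectors[idx],
            n_removed_rigid=self.n_removed_rigid,
        )


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of translations + rotations about centroid."""
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    basis = np.zeros((6, 3 * n))
    for a in range(3):
        basis[a, a::3] = 1.0
    for a, axis in enumerate(np.eye(3)):
        rot = np.cross(np.broadcast_to(axis, (n, 3)), centered)
        basis[3 + a] = rot.ravel()
    # collinear structures give a rank-5 basis; orthonormalize what is there
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q.T[keep]


def _connected_components(H: np.ndarray) -> int:
    n = H.shape[0] // 3
    blocks = np.abs(H).reshape(n, 3, n, 3).sum(axis=(1, 3))
    np.fill_diagonal(blocks, 0.0)
    adj = scipy.sparse.csr_matrix(blocks > 1e-12 * max(blocks.max(), 1e-300))
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    return n_comp


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # deterministic convention: largest-|component| entry made positive
    out = vectors.copy()
    for row in out:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return out


def compute_modes(
    h: Hessian,
    n_modes: int = DEFAULT_N_MODES,
    rigid_tol: float = DEFAULT_RIGID_TOL,
    solver: str = "auto",
) -> ModeSet:
    """Lowest ``n_modes`` internal modes of a Hessian.

    Eigenvalues below ``rigid_tol`` times the largest eigenvalue are
    classified as rigid-body modes and removed; the remaining spectrum is
    returned ascending with a deterministic sign convention on each vector.

    ``solver``: "dense" (scipy.linalg.eigh), "iterative" (shift-invert
    eigsh), or "auto" which picks dense for small systems.
    """
    H = h.matrix
    dim = H.shape[0]
    if n_modes < 1:
        raise ModeError("n_modes must be >= 1")
    if dim < 3 * 2:
        raise ModeError("Hessian too small")
    if dim < n_modes + 6:
        raise ModeError(
            f"3N = {dim} cannot supply {n_modes} internal modes plus 6 rigid"
        )
    asym = np.abs(H - H.T).max()
    if asym > 1e-9 * max(np.abs(H).max(), 1e-300):
        raise ModeError(f"Hessian not symmetric (max asymmetry {asym:g})")

    if solver == "auto":
        solver = "dense" if dim <= 3 * DENSE_LIMIT_RESIDUES else "iterative"

    if solver == "dense":
        evals, evecs = scipy.linalg.eigh(H)
        lam_max = evals[-1]
    elif solver == "iterative":
        sp = scipy.sparse.csr_matrix(H)
        # Gershgorin upper bound is enough to scale the rigid tolerance
        lam_max = float(np.abs(H).sum(axis=1).max())
        want = min(n_modes + 12, dim - 1)
        evals, evecs = scipy.sparse.linalg.eigsh(sp, k=want, sigma=0, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    else:
        raise ModeError(f"unknown solver {solver!r}")

    thresh = rigid_tol * max(lam_max, 1e-300)
    n_rigid = int(np.sum(evals < thresh))
    if n_rigid > 6:
        raise DisconnectedStructureError(n_rigid, _connected_components(H))
    if n_rigid < 5:
        raise ModeError(
            f"only {n_rigid} near-zero modes found; expected 6 "
            "(5 for exactly collinear structures) — over-restrained or "
            "ill-conditioned Hessian"
        )
    internal = slice(n_rigid, n_rigid + n_modes)
    if evals.shape[0] < n_rigid + n_modes:
        raise ModeError("iterative solver returned too few converged modes")
    lam = evals[internal].copy()
    vec = _fix_signs(evecs[:, internal].T)
    return ModeSet(eigenvalues=lam, vectors=vec, n_removed_rigid=n_rigid)
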