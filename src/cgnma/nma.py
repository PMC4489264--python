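"""Normal mode analysis: diagonalization, vibrational entropy, predicted
b-factors and squared overlap.

Eigenvalues are in relative stiffness units (the spring constants are
relative), so the vibrational entropy is defined only up to an additive
constant — exactly what cancels in the mutation differences ΔΔS_vib that the
downstream scoring uses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["ModeSet", "diagonalize", "vibrational_entropy",
           "predicted_bfactors", "squared_overlap"]

DEFAULT_ZERO_TOL = 1e-8  # relative to the largest eigenvalue


@dataclass
class ModeSet:
    """Eigenvalues (ascending) and orthonormal eigenvectors of a Hessian.

    ``n_trivial`` counts the numerically-zero eigenvalues; for a connected,
    non-collinear network these are the six rigid-body translations and
    rotations, and the first internal mode is mode 7 (1-based).
    """
    eigenvalues: np.ndarray   # (3N,)
    eigenvectors: np.ndarray  # (3N, 3N), columns
    n_trivial: int
    zero_tol: float

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.size // 3

    @property
    def internal_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_trivial:]

    def mode(self, index_1based: int) -> np.ndarray:
        """Column eigenvector for a 1-based mode index (ascending order)."""
        if not 1 <= index_1based <= self.eigenvalues.size:
            raise IndexError(f"mode index {index_1based} out of range")
        return self.eigenvectors[:, index_1based - 1]

    @property
    def first_internal_mode(self) -> int:
        """1-based index of the first mode above the zero tolerance."""
        return self.n_trivial + 1


def diagonalize(hessian: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL) -> ModeSet:
    """Full symmetric eigendecomposition of a Hessian.

    The zero tolerance is relative: a mode is trivial when its eigenvalue is
    below ``zero_tol`` times the largest eigenvalue.  A trivial-mode count
    other than 6 triggers a warning (likely a disconnected network or
    collinear nodes).
    """
    h = np.asarray(hessian, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("Hessian must be square")
    if not np.allclose(h, h.T, atol=1e-8):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = scipy.linalg.eigh(h)
    scale = max(float(evals[-1]), 1.0e-300)
    threshold = zero_tol * scale
    n_trivial = int(np.sum(evals < threshold))
    if n_trivial != 6:
        warnings.warn(
            f"expected 6 trivial (rigid-body) modes, found {n_trivial}; "
            "the network may be disconnected (6 per rigid component) or the "
            "nodes collinear", stacklevel=2)
    return ModeSet(eigenvalues=evals, eigenvectors=evecs,
                   n_trivial=n_trivial, zero_tol=threshold)


def vibrational_entropy(modes: ModeSet) -> float:
    """Vibrational entropy, up to an additive constant: S = −½ Σ ln λ over
    the internal modes.

    Stiffening any mode (raising its λ) lowers S.  The constant cancels in
    differences between structures of equal size, which is the only use the
    mutation scoring makes of it.
    """
    lam = modes.internal_eigenvalues
    if np.any(lam <= 0):
        raise ValueError("nontrivial eigenvalues must be positive")
    return float(-0.5 * np.sum(np.log(lam)))


def predicted_bfactors(modes: ModeSet) -> np.ndarray:
    """Per-residue mean-square-fluctuation estimate, relative units.

    b_i = Σ over internal modes m of ‖v_m restricted to node i‖² / λ_m.
    """
    lam = modes.internal_eigenvalues
    if np.any(lam <= 0):
        raise ValueError("nontrivial eigenvalues must be positive")
    v = modes.eigenvectors[:, modes.n_trivial:]          # (3N, M)
    per_node = (v ** 2).reshape(modes.n_nodes, 3, -1).sum(axis=1)  # (N, M)
    return per_node @ (1.0 / lam)


def squared_overlap(mode_vector: np.ndarray, displacement: np.ndarray) -> float:
    """Squared cosine between a unit mode direction and a displacement:
    (v·Δ)² / (Δ·Δ).  Equals 1 iff Δ is parallel to v; the overlaps over a
    full orthonormal basis sum to 1."""
    v = np.asarray(mode_vector, dtype=float).reshape(-1)
    d = np.asarray(displacement, dtype=float).reshape(-1)
    if v.shape != d.shape:
        raise ValueError("mode and displacement must have equal length")
    dd = float(d @ d)
    if dd == 0.0:
        raise ValueError("displacement must be nonzero")
    return float((v @ d) ** 2 / dd)
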