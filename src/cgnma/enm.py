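"""Spring-network construction and Hessian assembly.

Two model families are supported:

* ``ANM`` — the classic anisotropic network model: every node pair within a
  distance cutoff (default 18 Å) is joined by a spring of equal stiffness,
  independent of residue identity.
* ``ENCOM_LIKE`` — a sequence-aware variant: sequence-consecutive residues
  get a strong covalent spring, and every other pair gets a spring whose
  stiffness adds a surface-in-contact term summed over heavy-atom pairs and
  weighted by an atom-type interaction matrix.  Because the contact term
  depends on the side-chain atom census, two structures with identical CA
  traces but different sequences yield different Hessians — the property that
  makes vibrational-entropy mutation scoring possible at all.

The potential is pairwise Hookean, V = Σ ½ k_ij (d_ij − d⁰_ij)², so the
analytic Hessian has the standard ENM block form and can be cross-checked
against central finite differences of the potential (``build_hessian_numeric``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from ._chem import N_ATOM_CLASSES, default_interaction_matrix, vdw_radius
from .structure_io import CoarseModel, Residue, Structure

__all__ = [
    "ModelKind", "InteractionMatrix", "PotentialParams", "SpringNetwork",
    "contact_weight", "build_network", "potential_energy",
    "build_hessian", "build_hessian_numeric",
]

CONTACT_TOLERANCE = 1.4  # Å, water-probe-like ramp width of the contact surrogate


class ModelKind(str, Enum):
    ANM = "ANM"
    ENCOM_LIKE = "ENCOM_LIKE"


@dataclass
class InteractionMatrix:
    """Symmetric non-negative weights over atom-type class pairs."""
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_ATOM_CLASSES, N_ATOM_CLASSES):
            raise ValueError(f"expected {N_ATOM_CLASSES}x{N_ATOM_CLASSES} weights")
        if not np.allclose(w, w.T):
            raise ValueError("interaction matrix must be symmetric")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("interaction weights must be finite and >= 0")
        self.weights = w

    @classmethod
    def default(cls) -> "InteractionMatrix":
        return cls(default_interaction_matrix())

    def __getitem__(self, classes: tuple[int, int]) -> float:
        i, j = classes
        return float(self.weights[i - 1, j - 1])


@dataclass
class PotentialParams:
    model_kind: ModelKind = ModelKind.ENCOM_LIKE
    anm_cutoff: float = 18.0          # Å
    base_spring: float = 1.0          # energy/Å², uniform cutoff term
    covalent_spring: float = 10.0     # energy/Å², sequence-consecutive residues
    contact_scale: float = 1.0        # multiplier on the surface-weighted term
    interaction_matrix: InteractionMatrix = field(default_factory=InteractionMatrix.default)

    def __post_init__(self):
        if isinstance(self.model_kind, str):
            self.model_kind = ModelKind(self.model_kind)
        if self.anm_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for name in ("base_spring", "covalent_spring", "contact_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def anm(cls, cutoff: float = 18.0, spring: float = 1.0) -> "PotentialParams":
        return cls(model_kind=ModelKind.ANM, anm_cutoff=cutoff, base_spring=spring)


@dataclass
class SpringNetwork:
    node_coords: np.ndarray                       # (N, 3) equilibrium positions
    springs: list[tuple[int, int, float, float]]  # (i, j, k_ij, d0_ij), i < j

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


def _contact_ramp(distance: float, r_a: float, r_b: float) -> float:
    """Linear contact-surface surrogate: 1 at full overlap of vdW spheres plus
    a 1.4 Å probe, ramping to 0 at separation, clamped to [0, 1]."""
    return float(np.clip((r_a + r_b + CONTACT_TOLERANCE - distance) / CONTACT_TOLERANCE, 0.0, 1.0))


def contact_weight(residue_a: Residue, residue_b: Residue,
                   im: InteractionMatrix | None = None) -> float:
    """Surface-in-contact weight between two residues.

    Sums, over all heavy-atom pairs, the interaction-matrix entry for the two
    atom-type classes times the contact ramp of the pair distance.  Symmetric
    in its arguments; zero when every atom pair is beyond contact range.
    """
    im = im or InteractionMatrix.default()
    atoms_a = residue_a.heavy_atoms()
    atoms_b = residue_b.heavy_atoms()
    if not atoms_a or not atoms_b:
        return 0.0
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    dists = cdist(xa, xb)
    total = 0.0
    for p, a in enumerate(atoms_a):
        ra = vdw_radius(a.name)
        for q, b in enumerate(atoms_b):
            s = _contact_ramp(dists[p, q], ra, vdw_radius(b.name))
            if s > 0.0:
                total += im[a.atom_type_class, b.atom_type_class] * s
    return total


# residue pairs whose CA atoms are farther than this cannot have any heavy
# atoms in contact for ordinary side chains; used only as a pre-screen
_CONTACT_PRESCREEN = 25.0


def build_network(model: CoarseModel, structure: Structure | None,
                  params: PotentialParams) -> SpringNetwork:
    """Assemble the spring list for a coarse model.

    ANM: one spring (k = base_spring) per node pair within the cutoff.
    ENCOM_LIKE: covalent springs between sequence-consecutive residues of the
    same chain, plus k = base_spring·[d ≤ cutoff] + contact_scale·w_ij for
    every other pair; zero-stiffness springs are omitted.
    """
    nodes = model.nodes
    n = model.n_nodes
    dmat = cdist(nodes, nodes)
    springs: list[tuple[int, int, float, float]] = []

    if params.model_kind is ModelKind.ANM:
        for i in range(n):
            for j in range(i + 1, n):
                if dmat[i, j] <= params.anm_cutoff and params.base_spring > 0:
                    springs.append((i, j, params.base_spring, dmat[i, j]))
        return SpringNetwork(nodes, springs)

    if structure is None:
        raise ValueError("ENCOM_LIKE network requires the atomic structure")
    residues = model.residues
    im = params.interaction_matrix
    for i in range(n):
        ri = residues[i]
        for j in range(i + 1, n):
            rj = residues[j]
            d = dmat[i, j]
            consecutive = (ri.chain_id == rj.chain_id
                           and rj.seq_number - ri.seq_number == 1
                           and abs(j - i) == 1)
            if consecutive:
                k = params.covalent_spring
            else:
                k = params.base_spring if d <= params.anm_cutoff else 0.0
                if params.contact_scale > 0 and d <= _CONTACT_PRESCREEN:
                    k += params.contact_scale * contact_weight(ri, rj, im)
            if k > 0:
                springs.append((i, j, k, d))
    return SpringNetwork(nodes, springs)


def potential_energy(net: SpringNetwork, coords: np.ndarray) -> float:
    """Pairwise Hookean energy V = Σ ½ k_ij (d_ij − d⁰_ij)² at the given
    coordinates (flat 3N vector or (N, 3))."""
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    if xyz.shape[0] != net.n_nodes:
        raise ValueError(f"expected {net.n_nodes} nodes, got {xyz.shape[0]}")
    v = 0.0
    for i, j, k, d0 in net.springs:
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        v += 0.5 * k * (d - d0) ** 2
    return v


def build_hessian(net: SpringNetwork) -> np.ndarray:
    """Analytic 3N×3N Hessian of the pairwise Hookean potential at equilibrium.

    Off-diagonal block for a spring (i, j):  −(k/d⁰²)(r_i − r_j)(r_i − r_j)ᵀ;
    diagonal blocks make every 3×3 super-row sum to zero (translation
    invariance).
    """
    n = net.n_nodes
    h = np.zeros((3 * n, 3 * n))
    for i, j, k, d0 in net.springs:
        rij = net.node_coords[i] - net.node_coords[j]
        block = (k / d0 ** 2) * np.outer(rij, rij)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] -= block
        h[sl_j, sl_i] -= block
        h[sl_i, sl_i] += block
        h[sl_j, sl_j] += block
    return h


def build_hessian_numeric(net: SpringNetwork, h: float = 1e-4) -> np.ndarray:
    """Central-finite-difference Hessian of :func:`potential_energy`.

    O(h²)-accurate; quadratic in system size, intended as an independent
    oracle for :func:`build_hessian` on small systems.
    """
    if h <= 0:
        raise ValueError("step must be positive")
    x0 = net.node_coords.reshape(-1).copy()
    n3 = x0.size
    out = np.zeros((n3, n3))

    def v_at(delta_a, a, delta_b=0.0, b=None):
        x = x0.copy()
        x[a] += delta_a
        if b is not None:
            x[b] += delta_b
        return potential_energy(net, x)

    v0 = potential_energy(net, x0)
    for a in range(n3):
        out[a, a] = (v_at(h, a) - 2 * v0 + v_at(-h, a)) / h ** 2
        for b in range(a + 1, n3):
            val = (v_at(h, a, h, b) - v_at(h, a, -h, b)
                   - v_at(-h, a, h, b) + v_at(-h, a, -h, b)) / (4 * h ** 2)
            out[a, b] = out[b, a] = val
    return out
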