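"""Deterministic synthetic structures for tests, demos and calibration.

Everything here is generated from (kind, size, seed) with no downloads:
an ideal α-helix CA trace, a two-domain dumbbell with a hinge-like slow
mode, a collinear toy chain, a two-chain helical dimer, and synthetic
ΔΔG calibration tables.  Stub side chains use the same deterministic
pseudo-geometry as the sequence-swap mutant builder, so fixtures and
mutants are chemically consistent.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._chem import AA1_TO_3, SIDECHAIN_ATOMS, atom_class, element_of
from .mutations import STUB_SPACING
from .structure_io import Atom, Residue, Structure, structure_to_pdb

__all__ = ["make_helix", "make_dumbbell", "make_line", "make_dimer",
           "make_pdb_text", "make_ddg_table", "DEFAULT_SEQUENCE",
           "DUMBBELL_CUTOFF", "dumbbell_separation_vector",
           "dumbbell_domain_indices"]

# fixed 20-mer cycled through fixture sequences; covers every residue class
DEFAULT_SEQUENCE = "AVLIFKRDESTNQHWYMCGP"

HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Å


def _residue(chain: str, seq: int, aa1: str, ca: np.ndarray,
             sidechain_dir: np.ndarray) -> Residue:
    res3 = AA1_TO_3[aa1]
    atoms = [Atom("CA", "C", ca, False, atom_class(res3, "CA"))]
    d = sidechain_dir / max(np.linalg.norm(sidechain_dir), 1e-9)
    for idx, name in enumerate(SIDECHAIN_ATOMS[aa1]):
        xyz = ca + STUB_SPACING * (idx + 1) * d
        atoms.append(Atom(name, element_of(name), xyz, False, atom_class(res3, name)))
    return Residue(chain, seq, "", res3, atoms)


def _sequence(n: int, seed: int) -> str:
    # deterministic rotation of the fixed 20-mer so different seeds give
    # different (but reproducible) sequences
    shift = seed % len(DEFAULT_SEQUENCE)
    s = DEFAULT_SEQUENCE[shift:] + DEFAULT_SEQUENCE[:shift]
    return (s * (n // len(s) + 1))[:n]


def make_helix(n: int = 20, seed: int = 0, chain: str = "A",
               sequence: str | None = None) -> Structure:
    """Ideal α-helix CA trace (1.5 Å rise, 100°/residue, 2.3 Å radius) with
    stub side chains.  Consecutive CA distance is ≈ 3.8 Å by construction.

    Stub directions mix the radial outward normal with the helix axis
    (1 : 1.5); this brings side chains of residues i and i+3/i+4 into vdW
    contact — the canonical helical contact topology — so sequence-aware
    spring networks actually feel mutations on this fixture."""
    if n < 2:
        raise ValueError("need n >= 2")
    seq = sequence or _sequence(n, seed)
    residues = []
    for i in range(n):
        theta = np.deg2rad(HELIX_TWIST * i)
        ca = np.array([HELIX_RADIUS * np.cos(theta),
                       HELIX_RADIUS * np.sin(theta),
                       HELIX_RISE * i])
        stub_dir = np.array([np.cos(theta), np.sin(theta), 1.5])
        residues.append(_residue(chain, i + 1, seq[i], ca, stub_dir))
    return Structure(chains={chain: residues}, source_id=f"helix{n}_s{seed}")


_CLUSTER_OFFSETS = np.array([
    (0, 0, 0), (3.8, 0, 0), (0, 3.8, 0), (0, 0, 3.8),
    (3.8, 3.8, 0), (3.8, 0, 3.8), (0, 3.8, 3.8), (3.8, 3.8, 3.8),
    (-3.8, 0, 0), (0, -3.8, 0), (0, 0, -3.8), (-3.8, -3.8, 0),
    (-3.8, 0, -3.8), (0, -3.8, -3.8), (7.6, 0, 0), (0, 7.6, 0),
], dtype=float)


# cutoff (Å) matched to the dumbbell fixture's ~40 Å extent for hinge-mode
# analyses; the 18 Å protein default blankets the whole toy with springs
DUMBBELL_CUTOFF = 11.0

_DUMBBELL_ARM = 11.0        # Å, elbow centroid to lobe centroid
_DUMBBELL_HALF_ANGLE = 50.0  # degrees each lobe makes with the bisector
_DUMBBELL_LOBE_SCALE = 1.3
_DUMBBELL_ELBOW_SCALE = 0.9
_DUMBBELL_JITTER = 0.02     # Å, seed-dependent positional noise


def make_dumbbell(n_per_domain: int = 8, linker_len: int = 6,
                  seed: int = 0, chain: str = "A") -> Structure:
    """Two compact lobes fused at a small elbow cluster — a bent, hinged
    two-domain miniature of open/closed proteins like adenylate kinase.

    Residue order: lobe A, elbow (``linker_len`` residues), lobe B.  The
    slowest internal mode at the fixture's canonical geometry is hinge-like:
    it counter-rotates the lobes about the elbow, opening or closing the
    cleft (see :func:`dumbbell_separation_vector`).  Analyses of this fixture
    should use ``anm_cutoff=DUMBBELL_CUTOFF``."""
    if n_per_domain < 2 or n_per_domain > len(_CLUSTER_OFFSETS):
        raise ValueError(f"n_per_domain must be in [2, {len(_CLUSTER_OFFSETS)}]")
    if not 1 <= linker_len <= len(_CLUSTER_OFFSETS):
        raise ValueError("linker_len (elbow size) out of range")
    rng = np.random.default_rng(seed)
    a = np.deg2rad(_DUMBBELL_HALF_ANGLE)
    u1 = np.array([-np.sin(a), np.cos(a), 0.0])
    u2 = np.array([np.sin(a), np.cos(a), 0.0])
    center_a, center_b = _DUMBBELL_ARM * u1, _DUMBBELL_ARM * u2
    seq = _sequence(2 * n_per_domain + linker_len, 0)
    residues: list[Residue] = []
    num = 1

    def add(ca, outward_from):
        nonlocal num
        ca = np.asarray(ca, dtype=float) + rng.normal(scale=_DUMBBELL_JITTER, size=3)
        residues.append(_residue(chain, num, seq[num - 1], ca, ca - outward_from))
        num += 1

    for off in _CLUSTER_OFFSETS[:n_per_domain]:
        add(center_a + off * _DUMBBELL_LOBE_SCALE, center_a)
    for off in _CLUSTER_OFFSETS[:linker_len]:
        add(off * _DUMBBELL_ELBOW_SCALE, np.zeros(3))
    for off in _CLUSTER_OFFSETS[:n_per_domain]:
        add(center_b + off * _DUMBBELL_LOBE_SCALE, center_b)
    return Structure(chains={chain: residues},
                     source_id=f"dumbbell{n_per_domain}x2+{linker_len}_s{seed}")


def dumbbell_domain_indices(n_per_domain: int = 8, linker_len: int = 6,
                            ) -> tuple[list[int], list[int], list[int]]:
    """Node index lists (lobe A, elbow, lobe B) matching make_dumbbell order."""
    a = list(range(n_per_domain))
    e = list(range(n_per_domain, n_per_domain + linker_len))
    b = list(range(n_per_domain + linker_len, 2 * n_per_domain + linker_len))
    return a, e, b


def dumbbell_separation_vector(structure: Structure, n_per_domain: int = 8,
                               linker_len: int = 6) -> np.ndarray:
    """Inter-domain separation displacement of the dumbbell (flat 3N vector).

    The field rigidly counter-rotates the two lobes about the axis through
    the elbow centroid perpendicular to the bend plane — the hinge-opening
    motion that changes the lobe separation.  Normalized to unit length;
    zero on the elbow."""
    nodes = np.array([r.node_coord for r in structure.chains["A"]])
    ia, ie, ib = dumbbell_domain_indices(n_per_domain, linker_len)
    elbow_c = nodes[ie].mean(axis=0)
    zhat = np.array([0.0, 0.0, 1.0])
    field = np.zeros_like(nodes)
    for idx, sign in ((ia, 1.0), (ib, -1.0)):
        for i in idx:
            field[i] = sign * np.cross(zhat, nodes[i] - elbow_c)
    flat = field.reshape(-1)
    return flat / np.linalg.norm(flat)


def make_line(n: int = 3, spacing: float = 3.8, chain: str = "A") -> Structure:
    """Collinear CA-only chain along x — the degenerate toy geometry."""
    residues = []
    for i in range(n):
        ca = np.array([i * spacing, 0.0, 0.0])
        res = Residue(chain, i + 1, "", "GLY",
                      [Atom("CA", "C", ca, False, atom_class("GLY", "CA"))])
        residues.append(res)
    return Structure(chains={chain: residues}, source_id=f"line{n}")


def make_dimer(n_per_chain: int = 10, separation: float = 8.0,
               seed: int = 0) -> Structure:
    """Two parallel helices in chains A and B, close enough for inter-chain
    contacts near the interface."""
    a = make_helix(n_per_chain, seed=seed, chain="A")
    b = make_helix(n_per_chain, seed=seed + 1, chain="B")
    shift = np.array([separation, 0.0, 0.0])
    for res in b.chains["B"]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    return Structure(chains={"A": a.chains["A"], "B": b.chains["B"]},
                     source_id=f"dimer{n_per_chain}_s{seed}")


def make_pdb_text(structure: Structure) -> str:
    """Serialize a fixture to PDB text (round-trip companion to parse_pdb)."""
    return structure_to_pdb(structure)


def make_ddg_table(alpha: float = -1.0, beta: float = 0.4, n: int = 300,
                   sigma: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Synthetic calibration rows: ddG_exp = α·ddG_A + β·ddG_B + ε.

    ddG_A mimics vibrational-entropy scores (zero-centered, unit scale);
    ddG_B mimics an enthalpic predictor with the usual destabilizing bias
    (mean +1 kcal/mol); ε ~ N(0, σ)."""
    rng = np.random.default_rng(seed)
    ddg_a = rng.normal(0.0, 1.0, size=n)
    ddg_b = rng.normal(1.0, 1.5, size=n)
    ddg_exp = alpha * ddg_a + beta * ddg_b + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame({"ddG_A": ddg_a, "ddG_B": ddg_b, "ddG_exp": ddg_exp})
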