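"""Uniform, RMSD-constrained conformational ensembles from selected modes.

Each conformer is the input structure displaced along a combination of
selected internal eigenvectors.  Because eigenvectors are orthonormal, a
conformer with amplitude tuple (a_1..a_m) sits at RMSD sqrt(Σ a_k² / N) from
the input, so the amplitude lattice can be constrained exactly:

* per-mode amplitudes on a δ-spaced grid, δ = min_rmsd·√N, out to
  A = max_rmsd·√N;
* the Cartesian product over modes, pruned to the ball ‖a‖ ≤ A so no
  conformer exceeds the maximum RMSD;
* if the surviving grid still exceeds the conformer cap (default 350), the
  grid spacing — i.e. the minimum RMSD between conformers — is increased
  geometrically until it fits, preserving uniform coverage.

A multi-start greedy heuristic orders the conformers into a smooth
visualization trajectory (the exact ordering problem is the NP-hard
traveling-salesman path problem); single-mode oscillation trajectories are
emitted for the first 20 internal modes by default.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .nma import ModeSet
from .structure_io import CoarseModel, write_coarse_trajectory

__all__ = [
    "ModeSelection", "SamplingParams", "Conformer", "Ensemble",
    "amplitude_grid", "filter_min_separation", "enforce_cap",
    "generate_conformers", "rmsd", "pairwise_rmsd_matrix", "order_trajectory",
    "mode_trajectory", "build_ensemble", "DEFAULT_CAP",
]

DEFAULT_CAP = 350
CAP_GROWTH = 1.2       # geometric min-RMSD growth factor while over the cap
N_MODE_TRAJECTORIES = 20


@dataclass
class ModeSelection:
    """1-based indices of modes to sample; must all be internal (> 6 for a
    connected structure)."""
    mode_indices: list[int]

    def __post_init__(self):
        idx = list(self.mode_indices)
        if not idx:
            raise ValueError("select at least one mode")
        if len(set(idx)) != len(idx):
            raise ValueError("mode indices must be distinct")
        if min(idx) < 7:
            raise ValueError("modes 1-6 are rigid-body; the first internal mode is 7")
        self.mode_indices = idx

    def validate_against(self, modes: ModeSet) -> None:
        if min(self.mode_indices) <= modes.n_trivial:
            raise ValueError(
                f"selected mode {min(self.mode_indices)} is within the "
                f"{modes.n_trivial} trivial modes")
        if max(self.mode_indices) > modes.eigenvalues.size:
            raise ValueError("mode index beyond spectrum")


@dataclass
class SamplingParams:
    max_rmsd: float = 2.0       # Å, distortion from the input structure
    min_rmsd: float = 0.5       # Å, between any two conformers
    cap: int = DEFAULT_CAP

    def __post_init__(self):
        if not (0 < self.min_rmsd <= self.max_rmsd):
            raise ValueError("need 0 < min_rmsd <= max_rmsd")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


@dataclass
class Conformer:
    amplitudes: tuple[float, ...]   # per selected mode, Å·√N units
    coords: np.ndarray              # (N, 3)
    rmsd_from_input: float


@dataclass
class Ensemble:
    model: CoarseModel
    selection: ModeSelection
    conformers: list[Conformer]
    pairwise_rmsd: np.ndarray
    ordering: list[int]
    effective_min_rmsd: float

    def __len__(self) -> int:
        return len(self.conformers)

    def amplitude_table(self) -> pd.DataFrame:
        cols = [f"mode_{m}" for m in self.selection.mode_indices]
        df = pd.DataFrame([c.amplitudes for c in self.conformers], columns=cols)
        df.insert(0, "conformer", np.arange(len(self.conformers)))
        df["rmsd_from_input"] = [c.rmsd_from_input for c in self.conformers]
        return df

    def write_outputs(self, outdir, n_frames: int = 10,
                      modes: ModeSet | None = None) -> None:
        """Emit the standard output set: ordered multi-model PDB, individual
        conformer PDBs, amplitude table, pairwise-RMSD file and (when a mode
        set is given) per-mode trajectories for the first 20 internal modes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ordered = [self.conformers[i].coords for i in self.ordering]
        write_coarse_trajectory(self.model, ordered, outdir / "trajectory.pdb")
        for i, conf in enumerate(self.conformers):
            write_coarse_trajectory(self.model, [conf.coords],
                                    outdir / f"conformer_{i:04d}.pdb")
        self.amplitude_table().to_csv(outdir / "amplitudes.csv", index=False)
        np.savetxt(outdir / "pairwise_rmsd.txt", self.pairwise_rmsd, fmt="%.6f")
        if modes is not None:
            amp = max(a for c in self.conformers for a in
                      (abs(x) for x in c.amplitudes)) if len(self.conformers) > 1 else 1.0
            emit_mode_trajectories(self.model, modes, amp, n_frames, outdir)


def amplitude_grid(selection: ModeSelection, params: SamplingParams,
                   n_nodes: int) -> list[tuple[float, ...]]:
    """δ-lattice of amplitude tuples inside the max-RMSD ball.

    Per mode: a ∈ {0, ±δ, ±2δ, …} with δ = min_rmsd·√N, out to max_rmsd·√N;
    the Cartesian product is pruned of tuples whose implied RMSD
    ‖a‖/√N exceeds max_rmsd.  The all-zero tuple (the input structure) is
    always retained exactly once.
    """
    sqrt_n = np.sqrt(n_nodes)
    delta = params.min_rmsd * sqrt_n
    amax = params.max_rmsd * sqrt_n
    return _lattice(delta, amax, len(selection.mode_indices))


def _lattice(delta: float, amax: float, n_modes: int) -> list[tuple[float, ...]]:
    m = int(np.floor(amax / delta + 1e-9))
    axis = [0.0]
    for step in range(1, m + 1):
        axis.extend((step * delta, -step * delta))
    axis_sorted = sorted(axis)
    tuples = []
    for tup in itertools.product(axis_sorted, repeat=n_modes):
        if np.sqrt(sum(a * a for a in tup)) <= amax + 1e-9:
            tuples.append(tup)
    return tuples


def filter_min_separation(tuples: list[tuple[float, ...]], min_dist: float,
                          ) -> list[tuple[float, ...]]:
    """Greedily drop tuples closer than ``min_dist`` (amplitude-space
    Euclidean norm) to an already-kept tuple, keeping lexicographically
    smaller tuples first.  On a pure δ-lattice with min_dist = δ this keeps
    everything; it matters only for user-supplied tuples."""
    from scipy.spatial import cKDTree
    ordered = sorted(tuples)
    pts = np.asarray(ordered, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, r=min_dist - 1e-9)
    kept_mask = np.zeros(len(ordered), dtype=bool)
    for i, neighbors in enumerate(neighbor_lists):
        if not any(j < i and kept_mask[j] for j in neighbors):
            kept_mask[i] = True
    return [t for t, keep in zip(ordered, kept_mask) if keep]


def enforce_cap(selection: ModeSelection, params: SamplingParams, n_nodes: int,
                ) -> tuple[list[tuple[float, ...]], float]:
    """Regenerate the grid with geometrically growing min-RMSD until the
    conformer count fits the cap; returns (tuples, effective_min_rmsd)."""
    sqrt_n = np.sqrt(n_nodes)
    min_rmsd = params.min_rmsd
    while True:
        delta = min_rmsd * sqrt_n
        tuples = _lattice(delta, params.max_rmsd * sqrt_n, len(selection.mode_indices))
        tuples = filter_min_separation(tuples, delta)
        if len(tuples) <= params.cap:
            return tuples, min_rmsd
        min_rmsd *= CAP_GROWTH


def generate_conformers(model: CoarseModel, modes: ModeSet,
                        selection: ModeSelection,
                        tuples: list[tuple[float, ...]]) -> list[Conformer]:
    """Displace the input coordinates along each amplitude tuple:
    x = x₀ + Σ_k a_k v_k, with the RMSD from input computed from the actual
    coordinates (it matches sqrt(Σ a²/N) by orthonormality)."""
    selection.validate_against(modes)
    x0 = model.coords_flat
    basis = np.column_stack([modes.mode(m) for m in selection.mode_indices])
    conformers = []
    for tup in tuples:
        x = x0 + basis @ np.asarray(tup)
        conformers.append(Conformer(
            amplitudes=tuple(tup),
            coords=x.reshape(-1, 3),
            rmsd_from_input=rmsd(x0, x),
        ))
    return conformers


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation over nodes, computed in a shared frame
    (no superposition: conformers are generated in the input frame and the
    trivial modes are never sampled)."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("coordinate sets have different sizes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pairwise_rmsd_matrix(conformers: list[Conformer]) -> np.ndarray:
    coords = np.array([c.coords.reshape(-1) for c in conformers])
    n_nodes = conformers[0].coords.shape[0]
    if len(conformers) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords) / np.sqrt(n_nodes))


def order_trajectory(pairwise: np.ndarray) -> list[int]:
    """Multi-start greedy path through the conformers.

    From every start, repeatedly hop to the nearest unvisited conformer
    (ties: lowest index); return the path with the lowest total RMSD
    (ties: lowest start index).  A cheap heuristic for the NP-hard exact
    ordering, adequate for visualization.
    """
    d = np.asarray(pairwise, dtype=float)
    n = d.shape[0]
    if n == 0:
        raise ValueError("empty ensemble")
    best_path, best_total = None, np.inf
    for start in range(n):
        visited = np.zeros(n, dtype=bool)
        path = [start]
        visited[start] = True
        total = 0.0
        cur = start
        for _ in range(n - 1):
            dist = np.where(visited, np.inf, d[cur])
            nxt = int(np.argmin(dist))   # argmin takes the lowest index on ties
            total += dist[nxt]
            path.append(nxt)
            visited[nxt] = True
            cur = nxt
        if total < best_total - 1e-12:
            best_path, best_total = path, total
    return best_path


def mode_trajectory(model: CoarseModel, modes: ModeSet, mode_index: int,
                    amplitude: float, n_frames: int = 10) -> list[np.ndarray]:
    """Sinusoidal oscillation along one internal mode: frame t displaces by
    a·sin(2πt/n_frames), t = 0..n_frames−1 (frame 0 is the input)."""
    if mode_index <= modes.n_trivial:
        raise ValueError(
            f"mode {mode_index} is trivial (first internal mode is "
            f"{modes.first_internal_mode})")
    v = modes.mode(mode_index)
    x0 = model.coords_flat
    frames = []
    for t in range(n_frames):
        a = amplitude * np.sin(2 * np.pi * t / n_frames)
        frames.append((x0 + a * v).reshape(-1, 3))
    return frames


def emit_mode_trajectories(model: CoarseModel, modes: ModeSet, amplitude: float,
                           n_frames: int, outdir,
                           n_modes: int = N_MODE_TRAJECTORIES) -> list[Path]:
    """Write one oscillation PDB per internal mode, for the first
    ``n_modes`` internal modes available (default 20)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = modes.first_internal_mode
    last = min(first + n_modes - 1, modes.eigenvalues.size)
    paths = []
    for raw in range(first, last + 1):
        frames = mode_trajectory(model, modes, raw, amplitude, n_frames)
        p = outdir / f"mode_{raw:03d}.pdb"
        write_coarse_trajectory(model, frames, p)
        paths.append(p)
    return paths


def build_ensemble(model: CoarseModel, modes: ModeSet, selection: ModeSelection,
                   params: SamplingParams) -> Ensemble:
    """Full pipeline: capped amplitude lattice → conformers → pairwise RMSDs
    → visualization ordering."""
    selection.validate_against(modes)
    tuples, eff_min = enforce_cap(selection, params, model.n_nodes)
    conformers = generate_conformers(model, modes, selection, tuples)
    pw = pairwise_rmsd_matrix(conformers)
    ordering = order_trajectory(pw)
    return Ensemble(model=model, selection=selection, conformers=conformers,
                    pairwise_rmsd=pw, ordering=ordering,
                    effective_min_rmsd=eff_min)
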