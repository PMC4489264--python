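"""Model/Results facade over the toolkit.

`ElasticNetworkModel` holds a preprocessed structure, its coarse-grained
node representation and the spring network; `fit()` diagonalizes the Hessian
and returns a `NormalModeResults` carrying the spectrum, vibrational
entropy, predicted b-factors and a `summary()`.  Mutation scanning and
ensemble sampling hang off the results object, mirroring how statistical
modelling packages attach post-estimation tools to their results classes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensembles as ens
from . import mutations as mut
from .enm import PotentialParams, SpringNetwork, build_hessian, build_network
from .nma import ModeSet, diagonalize, predicted_bfactors, squared_overlap, vibrational_entropy
from .structure_io import (CoarseModel, Structure, build_coarse_model,
                           parse_pdb, preprocess, read_pdb)

__all__ = ["ElasticNetworkModel", "NormalModeResults", "MutationScanResults"]


class ElasticNetworkModel:
    """A coarse-grained elastic network built from a protein structure.

    Parameters
    ----------
    structure:
        Parsed structure; it is preprocessed (chain selection, heteroatom /
        hydrogen stripping) unless ``preprocessed=True``.
    params:
        Spring-network parameters; defaults to the sequence-aware
        ``ENCOM_LIKE`` family.
    chains:
        Chains to include (default: all).
    """

    def __init__(self, structure: Structure, params: PotentialParams | None = None,
                 chains: set[str] | None = None, preprocessed: bool = False):
        self.params = params or PotentialParams()
        self.structure = structure if preprocessed else preprocess(structure, chains)
        self.coarse: CoarseModel = build_coarse_model(self.structure)
        self.network: SpringNetwork = build_network(self.coarse, self.structure, self.params)

    @classmethod
    def from_pdb(cls, path, params: PotentialParams | None = None,
                 chains: set[str] | None = None) -> "ElasticNetworkModel":
        return cls(read_pdb(path), params=params, chains=chains)

    @classmethod
    def from_pdb_text(cls, text: str, params: PotentialParams | None = None,
                      chains: set[str] | None = None) -> "ElasticNetworkModel":
        return cls(parse_pdb(text), params=params, chains=chains)

    @property
    def n_nodes(self) -> int:
        return self.coarse.n_nodes

    def hessian(self) -> np.ndarray:
        return build_hessian(self.network)

    def fit(self, zero_tol: float = 1e-8) -> "NormalModeResults":
        """Diagonalize the Hessian and wrap the spectrum in a results object."""
        modes = diagonalize(self.hessian(), zero_tol=zero_tol)
        return NormalModeResults(self, modes)


class NormalModeResults:
    """Normal-mode spectrum of a fitted elastic network."""

    def __init__(self, model: ElasticNetworkModel, modes: ModeSet):
        self.model = model
        self.modes = modes

    # -- spectrum ----------------------------------------------------------
    @property
    def eigenvalues(self) -> np.ndarray:
        return self.modes.eigenvalues

    @property
    def n_trivial(self) -> int:
        return self.modes.n_trivial

    @property
    def first_internal_mode(self) -> int:
        return self.modes.first_internal_mode

    @property
    def vibrational_entropy(self) -> float:
        return vibrational_entropy(self.modes)

    @property
    def bfactors(self) -> np.ndarray:
        return predicted_bfactors(self.modes)

    def bfactor_frame(self) -> pd.DataFrame:
        res = self.model.coarse.residues
        return pd.DataFrame({
            "chain": [r.chain_id for r in res],
            "seq_number": [r.seq_number for r in res],
            "aa": [r.aa_type for r in res],
            "bfactor": self.bfactors,
        })

    def export_modes(self, outdir) -> None:
        """Write the spectrum as plain text: eigenvalues.csv and a
        whitespace-delimited eigenvector matrix (columns = modes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"mode": np.arange(1, self.eigenvalues.size + 1),
                      "eigenvalue": self.eigenvalues,
                      "trivial": np.arange(self.eigenvalues.size) < self.n_trivial,
                      }).to_csv(outdir / "eigenvalues.csv", index=False)
        np.savetxt(outdir / "eigenvectors.txt", self.modes.eigenvectors, fmt="%.10e")

    def squared_overlaps(self, displacement: np.ndarray) -> np.ndarray:
        """Squared overlap of every internal mode with a displacement."""
        return np.array([
            squared_overlap(self.modes.mode(m), displacement)
            for m in range(self.first_internal_mode, self.eigenvalues.size + 1)
        ])

    def summary(self) -> str:
        lam = self.modes.internal_eigenvalues
        b = self.bfactors
        top = np.argsort(b)[::-1][:3]
        res = self.model.coarse.residues
        lines = [
            "Elastic network normal mode analysis",
            "=" * 40,
            f"model kind          : {self.model.params.model_kind.value}",
            f"residues (nodes)    : {self.model.n_nodes}",
            f"springs             : {len(self.model.network.springs)}",
            f"trivial modes       : {self.n_trivial}",
            f"first internal mode : {self.first_internal_mode}",
            f"lowest internal eig : {lam[0]:.6g}",
            f"vibrational entropy : {self.vibrational_entropy:.6g} (relative units)",
            "most flexible nodes : " + ", ".join(
                f"{res[i].chain_id}{res[i].seq_number}({res[i].aa_type})" for i in top),
        ]
        return "\n".join(lines)

    # -- ensembles ---------------------------------------------------------
    def sample_ensemble(self, mode_indices: list[int] | None = None,
                        max_rmsd: float = 2.0, min_rmsd: float = 0.5,
                        cap: int = ens.DEFAULT_CAP) -> ens.Ensemble:
        if mode_indices is None:
            first = self.first_internal_mode
            mode_indices = [first, first + 1]
        return ens.build_ensemble(
            self.model.coarse, self.modes,
            ens.ModeSelection(mode_indices),
            ens.SamplingParams(max_rmsd=max_rmsd, min_rmsd=min_rmsd, cap=cap))

    def mode_trajectory(self, mode_index: int, amplitude: float,
                        n_frames: int = 10) -> list[np.ndarray]:
        return ens.mode_trajectory(self.model.coarse, self.modes, mode_index,
                                   amplitude, n_frames)

    # -- mutations ---------------------------------------------------------
    def scan_mutations(self, specs, ddg_b: dict[str, float] | None = None,
                       combo: mut.CombinationModel | None = None,
                       mutant_mode: str = "sequence_swap",
                       command_template: str | None = None) -> "MutationScanResults":
        """Score a list of mutations (or a range spec string) against this
        wild-type fit."""
        if isinstance(specs, str):
            specs = mut.enumerate_mutations(specs, self.model.structure)
        combo = combo or mut.CombinationModel()
        wt_b = self.bfactors
        scores: list[mut.MutationScore] = []
        skipped: list[str] = []
        for spec in specs:
            mutant = mut.model_mutant(self.model.structure, spec, mode=mutant_mode,
                                      command_template=command_template)
            if mutant is None:
                skipped.append(spec.label)
                continue
            mm = ElasticNetworkModel(mutant, params=self.model.params, preprocessed=True)
            mres = mm.fit()
            dds = mut.ddS_vib(self.modes, mres.modes)
            b_val = (ddg_b or {}).get(spec.label)
            scores.append(mut.MutationScore(
                spec=spec,
                ddS_vib=dds,
                ddG_B=b_val,
                ddG_combined=mut.combine_ddg(dds, b_val, combo),
                bfactor_delta=mut.bfactor_delta_profile(wt_b, mres.bfactors),
            ))
        return MutationScanResults(self, scores, combo, skipped)


@dataclass
class MutationScanResults:
    """Scored mutation scan with its job-wide color scale and summaries."""
    wild_type: NormalModeResults
    scores: list[mut.MutationScore]
    combo: mut.CombinationModel
    skipped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "mutation": s.spec.label,
            "chain": s.spec.chain_id,
            "position": s.spec.seq_number,
            "wt_aa": s.spec.wt_aa,
            "mut_aa": s.spec.mut_aa,
            "ddS_vib": s.ddS_vib,
            "ddG_B": s.ddG_B,
            "ddG_combined": s.ddG_combined,
        } for s in self.scores])

    @property
    def delta_matrix(self) -> np.ndarray:
        return np.array([s.bfactor_delta for s in self.scores])

    @property
    def color_scale(self) -> float:
        return mut.color_scale(self.delta_matrix)

    def heatmap(self) -> pd.DataFrame | None:
        return mut.heatmap_matrix(self.scores)

    def top(self, k: int = 25) -> pd.DataFrame:
        return mut.top_stabilizing(self.scores, k)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Mutation scan",
            "=" * 40,
            f"mutations scored : {len(self.scores)} (skipped: {len(self.skipped)})",
            f"combination      : ddG = {self.combo.alpha}*ddS_vib + {self.combo.beta}*ddG_B",
        ]
        if len(df):
            best = df.sort_values("ddS_vib").iloc[0]
            lines.append(f"most stabilizing (entropic): {best.mutation} "
                         f"(ddS_vib = {best.ddS_vib:.4g})")
        return "\n".join(lines)

    def write_outputs(self, outdir) -> None:
        """Per-mutation CSVs, PyMOL coloring scripts, heatmap and top-25
        summary, as the server workflow emits them."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "mutations.csv", index=False)
        residues = self.wild_type.model.coarse.residues
        scale = self.color_scale if self.scores else 0.0
        wt_b = self.wild_type.bfactors
        for s in self.scores:
            stem = outdir / f"mutant_{s.spec.label}"
            pd.DataFrame({
                "chain": [r.chain_id for r in residues],
                "seq_number": [r.seq_number for r in residues],
                "bfactor_wt": wt_b,
                "bfactor_mut": wt_b + s.bfactor_delta,
                "delta": s.bfactor_delta,
            }).to_csv(stem.with_suffix(".csv"), index=False)
            mut.write_pymol_coloring(stem.with_suffix(".pml"), residues,
                                     s.bfactor_delta, scale)
        self.top(25).to_csv(outdir / "top25_stabilizing.csv", index=False)
        grid = self.heatmap()
        if grid is not None:
            grid.to_csv(outdir / "heatmap.csv")
            self._plot_heatmap(grid, outdir / "heatmap.png")

    @staticmethod
    def _plot_heatmap(grid: pd.DataFrame, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(4, 0.4 * grid.shape[1]),
                                        max(3, 0.4 * grid.shape[0])))
        im = ax.imshow(grid.to_numpy(dtype=float), cmap="coolwarm", aspect="auto")
        ax.set_xticks(range(grid.shape[1]), grid.columns)
        ax.set_yticks(range(grid.shape[0]), grid.index)
        ax.set_xlabel("mutant residue")
        ax.set_ylabel("position")
        fig.colorbar(im, ax=ax, label="predicted ddG")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
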