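"""Single-point mutation enumeration and scoring.

The stability score of a mutation is the vibrational entropy difference
ΔΔS_vib between mutant and wild-type mode spectra (sequence-aware model
required: under a sequence-agnostic ANM every mutation is exactly neutral).
ΔΔS_vib can be linearly combined with an external enthalpic predictor
(e.g. a FoldX ΔΔG read from CSV) as

    ΔΔG = α·ΔΔG_A + β·ΔΔG_B

with default coefficients α = −1.12, β = 0.38, the best-performing
combination reported for vibrational-entropy + FoldX scoring.  ``calibrate``
re-estimates (α, β) on a user table by bootstrapped no-intercept least
squares.  Negative combined ΔΔG is stabilizing.
"""
from __future__ import annotations

import re
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._chem import AA1_TO_3, AA3_TO_1, SIDECHAIN_ATOMS, STANDARD_AA1, atom_class, element_of
from .structure_io import Atom, Residue, Structure, parse_pdb, structure_to_pdb
from .nma import ModeSet, vibrational_entropy

__all__ = [
    "MutationSpec", "CombinationModel", "MutationScore", "CalibrationResult",
    "enumerate_mutations", "parse_mutation_file", "model_mutant",
    "place_stub_sidechain", "ddS_vib", "combine_ddg", "calibrate",
    "bfactor_delta_profile", "color_scale", "heatmap_matrix",
    "top_stabilizing", "load_ddg_b_csv", "write_pymol_coloring",
]

STUB_SPACING = 1.5  # Å between consecutive pseudo-side-chain atoms


@dataclass(frozen=True)
class MutationSpec:
    """A single-point mutation addressed by author (PDB) numbering."""
    chain_id: str
    seq_number: int
    wt_aa: str
    mut_aa: str
    icode: str = ""

    def __post_init__(self):
        if self.wt_aa not in STANDARD_AA1 or self.mut_aa not in STANDARD_AA1:
            raise ValueError(f"nonstandard amino acid in {self.wt_aa}->{self.mut_aa}")
        if self.mut_aa == self.wt_aa:
            raise ValueError(f"mutation to self at {self.chain_id}{self.seq_number}")

    @property
    def label(self) -> str:
        """Compact mutation string, e.g. ``KA13Q`` (wt, chain, position, mut)."""
        return f"{self.wt_aa}{self.chain_id}{self.seq_number}{self.icode}{self.mut_aa}"

    def validate_against(self, structure: Structure) -> None:
        res = structure.find(self.chain_id, self.seq_number, self.icode)
        if res is None:
            raise ValueError(f"no residue {self.chain_id}:{self.seq_number}{self.icode}")
        if res.aa_type != self.wt_aa:
            raise ValueError(
                f"wild type mismatch at {self.chain_id}{self.seq_number}: "
                f"structure has {res.aa_type}, spec says {self.wt_aa}")


@dataclass
class CombinationModel:
    """Coefficients of the linear stability combination ΔΔG = α·ΔΔG_A + β·ΔΔG_B."""
    alpha: float = -1.12
    beta: float = 0.38

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")


@dataclass
class MutationScore:
    spec: MutationSpec
    ddS_vib: float
    ddG_B: float | None = None
    ddG_combined: float | None = None
    bfactor_delta: np.ndarray | None = None

    @property
    def ddG(self) -> float:
        """Combined ΔΔG when available, otherwise the entropic score alone."""
        return self.ddG_combined if self.ddG_combined is not None else self.ddS_vib


@dataclass
class CalibrationResult:
    alpha_median: float
    beta_median: float
    rmse_median: dict[str, float]        # keys: all / stabilizing / destabilizing
    rmse_spread: dict[str, float]        # std over bootstrap samples
    n_bootstrap: int
    n_resampled: int = 0                 # rank-deficient draws that were redrawn

    def summary(self) -> str:
        lines = [
            "Bootstrap calibration of ddG = alpha*ddG_A + beta*ddG_B",
            f"  samples: {self.n_bootstrap}  (rank-deficient redraws: {self.n_resampled})",
            f"  alpha (median): {self.alpha_median: .4f}",
            f"  beta  (median): {self.beta_median: .4f}",
        ]
        for k in ("all", "stabilizing", "destabilizing"):
            lines.append(f"  RMSE {k:<13s}: {self.rmse_median[k]:.4f} "
                         f"+/- {self.rmse_spread[k]:.4f}")
        return "\n".join(lines)


_SPEC_RE = re.compile(r"^(?P<chain>\w):(?P<start>\d+)(?:-(?P<end>\d+))?:(?P<targets>\w+)$")


def enumerate_mutations(range_spec: str, structure: Structure) -> list[MutationSpec]:
    """Expand a range spec ``CHAIN:START[-END]:TARGETS`` into mutation specs.

    TARGETS is a string of one-letter target residues, or ``ALL`` for the 19
    non-wild-type residues at each position.  Positions absent from the
    structure are skipped with a warning; self-mutations are excluded.
    """
    m = _SPEC_RE.match(range_spec.strip())
    if not m:
        raise ValueError(f"cannot parse mutation spec {range_spec!r}")
    chain = m.group("chain")
    start = int(m.group("start"))
    end = int(m.group("end") or start)
    targets_token = m.group("targets").upper()
    if targets_token == "ALL":
        targets = sorted(STANDARD_AA1)
    else:
        bad = [t for t in targets_token if t not in STANDARD_AA1]
        if bad:
            raise ValueError(f"unknown target residue(s) {bad!r} in {range_spec!r}")
        targets = list(targets_token)

    specs: list[MutationSpec] = []
    for pos in range(start, end + 1):
        res = structure.find(chain, pos)
        if res is None or res.aa_type is None:
            warnings.warn(f"position {chain}:{pos} absent from structure; skipped")
            continue
        for t in targets:
            if t == res.aa_type:
                continue
            specs.append(MutationSpec(chain, pos, res.aa_type, t, res.icode))
    return specs


def parse_mutation_file(text: str, structure: Structure) -> list[MutationSpec]:
    """One range spec per line; blank lines and '#' comments ignored."""
    specs: list[MutationSpec] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            specs.extend(enumerate_mutations(line, structure))
    return specs


def _stub_direction(res: Residue, structure: Structure) -> np.ndarray:
    """Deterministic CA→CB direction for pseudo-side-chain placement."""
    ca = res.node_coord
    cb = res.get_atom("CB")
    if cb is not None:
        v = cb.coords - ca
    else:
        n, c = res.get_atom("N"), res.get_atom("C")
        if n is not None and c is not None:
            # ideal tetrahedral bisector opposite the backbone
            u1 = (n.coords - ca) / np.linalg.norm(n.coords - ca)
            u2 = (c.coords - ca) / np.linalg.norm(c.coords - ca)
            v = -(u1 + u2)
        else:
            others = [r.node_coord for r in structure.chains.get(res.chain_id, [])
                      if r.key != res.key and r.ca is not None]
            v = ca - np.mean(others, axis=0) if others else np.array([1.0, 0.0, 0.0])
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])


def place_stub_sidechain(res: Residue, aa1: str, structure: Structure) -> list[Atom]:
    """Pseudo-side-chain heavy atoms for residue type ``aa1``: the canonical
    atom census placed at fixed 1.5 Å spacing along the CA→CB direction.

    The geometry is a deterministic stub — what matters to the contact
    weights is the atom-class census and its rough extent, not rotamers."""
    direction = _stub_direction(res, structure)
    ca = res.node_coord
    res3 = AA1_TO_3[aa1]
    atoms = []
    for idx, name in enumerate(SIDECHAIN_ATOMS[aa1]):
        xyz = ca + STUB_SPACING * (idx + 1) * direction
        atoms.append(Atom(name, element_of(name), xyz, False, atom_class(res3, name)))
    return atoms


def model_mutant(structure: Structure, spec: MutationSpec,
                 mode: str = "sequence_swap",
                 command_template: str | None = None) -> Structure | None:
    """Build a mutant structure.

    ``sequence_swap`` keeps the backbone and CA fixed and replaces the
    side-chain heavy atoms with the stub census of the target residue, so
    contact weights (hence the sequence-aware Hessian) change without moving
    any node.  ``external_command`` runs a user-configured modelling tool;
    failures skip the mutation (returning None) rather than aborting the run.
    """
    spec.validate_against(structure)
    if mode == "sequence_swap":
        mut = structure.copy()
        res = mut.find(spec.chain_id, spec.seq_number, spec.icode)
        backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
        res.name = AA1_TO_3[spec.mut_aa]
        for a in backbone:
            a.atom_type_class = atom_class(res.name, a.name)
        res.atoms = backbone + place_stub_sidechain(res, spec.mut_aa, mut)
        return mut
    if mode == "external_command":
        if not command_template:
            raise ValueError("external_command mode requires a command template")
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.pdb"
            out = Path(tmp) / "mutant.pdb"
            inp.write_text(structure_to_pdb(structure))
            cmd = command_template.format(
                input=inp, output=out, chain=spec.chain_id,
                position=f"{spec.seq_number}{spec.icode}",
                wt=spec.wt_aa, mut=spec.mut_aa)
            try:
                subprocess.run(cmd, shell=True, check=True, capture_output=True)
                return parse_pdb(out.read_text(), source_id=spec.label)
            except (subprocess.CalledProcessError, OSError, ValueError) as exc:
                warnings.warn(f"external modelling failed for {spec.label}: {exc}; skipped")
                return None
    raise ValueError(f"unknown mutant modelling mode {mode!r}")


def ddS_vib(wt_modes: ModeSet, mut_modes: ModeSet) -> float:
    """Vibrational entropy difference S(mut) − S(wt); antisymmetric under
    argument swap, exactly zero for identical spectra."""
    if wt_modes.eigenvalues.size != mut_modes.eigenvalues.size:
        raise ValueError("mode sets have different sizes")
    if wt_modes.n_trivial != mut_modes.n_trivial:
        raise ValueError("mode sets have different trivial-mode counts")
    return vibrational_entropy(mut_modes) - vibrational_entropy(wt_modes)


def combine_ddg(ddS: float, ddG_B: float | None,
                model: CombinationModel | None = None) -> float | None:
    """α·ΔΔS_vib + β·ΔΔG_B; None when the external term is missing."""
    if ddG_B is None:
        return None
    model = model or CombinationModel()
    return model.alpha * ddS + model.beta * ddG_B


def _as_calibration_array(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[["ddG_A", "ddG_B", "ddG_exp"]].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def calibrate(table, n_bootstrap: int = 10_000, subset_threshold: float = 0.5,
              seed: int | np.random.Generator | None = 0) -> CalibrationResult:
    """Bootstrap calibration of (α, β).

    For each bootstrap resample of the rows a no-intercept least-squares fit
    of ddG_exp on (ddG_A, ddG_B) gives the (α, β) minimizing the RMSE on
    that sample; reported values are medians over samples, with RMSE broken
    out for all rows and the stabilizing (< threshold) / destabilizing
    (> threshold) subsets.  Rank-deficient resamples are redrawn (counted).
    """
    data = _as_calibration_array(table)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("calibration table needs columns (ddG_A, ddG_B, ddG_exp)")
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to calibrate")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    alphas = np.empty(n_bootstrap)
    betas = np.empty(n_bootstrap)
    rmses = {k: np.full(n_bootstrap, np.nan) for k in ("all", "stabilizing", "destabilizing")}
    n_resampled = 0
    # redrawing cannot repair a design that is singular on the full table
    full_rank = np.linalg.matrix_rank(data[:, :2])
    max_redraws = 5 if full_rank == 2 else 0
    for b in range(n_bootstrap):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n) if n_bootstrap > 1 else np.arange(n)
            x, y = data[idx, :2], data[idx, 2]
            coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
            if rank == 2:
                break
            n_resampled += 1
        alphas[b], betas[b] = coef
        resid = y - x @ coef
        rmses["all"][b] = np.sqrt(np.mean(resid ** 2))
        stab = y < subset_threshold
        destab = y > subset_threshold
        if stab.any():
            rmses["stabilizing"][b] = np.sqrt(np.mean(resid[stab] ** 2))
        if destab.any():
            rmses["destabilizing"][b] = np.sqrt(np.mean(resid[destab] ** 2))
    if n_resampled:
        warnings.warn(f"redrew {n_resampled} rank-deficient bootstrap sample(s)")
    return CalibrationResult(
        alpha_median=float(np.median(alphas)),
        beta_median=float(np.median(betas)),
        rmse_median={k: float(np.nanmedian(v)) for k, v in rmses.items()},
        rmse_spread={k: float(np.nanstd(v)) for k, v in rmses.items()},
        n_bootstrap=n_bootstrap,
        n_resampled=n_resampled,
    )


def bfactor_delta_profile(wt_b: np.ndarray, mut_b: np.ndarray) -> np.ndarray:
    """Per-residue flexibility change, mutant − wild type.  Positive values
    are gains of flexibility (colored red), negative rigidification (blue)."""
    wt_b = np.asarray(wt_b, dtype=float)
    mut_b = np.asarray(mut_b, dtype=float)
    if wt_b.shape != mut_b.shape:
        raise ValueError("b-factor profiles have different lengths")
    return mut_b - wt_b


def color_scale(all_deltas: np.ndarray) -> float:
    """Color-range scale for b-factor difference maps.

    S = min(max|δ|, 3·std(|δ|)) over all mutations and residues of one job;
    when std(|δ|) degenerates to 0 with nonzero deltas, max|δ| is used.
    Colors are therefore comparable only within a single job.
    """
    d = np.abs(np.asarray(all_deltas, dtype=float))
    if d.size == 0:
        raise ValueError("empty delta matrix")
    dmax = float(d.max())
    if dmax == 0.0:
        return 0.0
    spread = 3.0 * float(d.std())
    if spread <= 1e-12 * dmax:  # degenerate: all |delta| equal
        return dmax
    return min(dmax, spread)


def map_delta_colors(deltas: np.ndarray, scale: float) -> np.ndarray:
    """Clamp δ/S to [−1, 1] and map onto blue(−1)–white(0)–red(+1) RGB rows."""
    d = np.asarray(deltas, dtype=float)
    t = np.zeros_like(d) if scale == 0 else np.clip(d / scale, -1.0, 1.0)
    rgb = np.ones(d.shape + (3,))
    neg, pos = t < 0, t > 0
    rgb[neg, 0] = 1 + t[neg]; rgb[neg, 1] = 1 + t[neg]     # toward blue
    rgb[pos, 1] = 1 - t[pos]; rgb[pos, 2] = 1 - t[pos]     # toward red
    return rgb


def write_pymol_coloring(path, residues, deltas: np.ndarray, scale: float) -> None:
    """PyMOL script coloring each residue by its flexibility change."""
    rgb = map_delta_colors(np.asarray(deltas, dtype=float), scale)
    lines = ["bg_color white", "hide everything", "show cartoon"]
    for res, (r, g, b) in zip(residues, rgb):
        cname = f"dflex_{res.chain_id}{res.seq_number}{res.icode}"
        lines.append(f"set_color {cname}, [{r:.3f}, {g:.3f}, {b:.3f}]")
        lines.append(f"color {cname}, chain {res.chain_id} and resi {res.seq_number}{res.icode}")
    Path(path).write_text("\n".join(lines) + "\n")


def heatmap_matrix(scores: list[MutationScore]) -> pd.DataFrame | None:
    """Positions × residue-type grid of predicted ΔΔG.

    Emitted only when the job covers more than two positions and more than
    two mutant types; otherwise None (a note is logged by callers).  Missing
    cells are NaN."""
    if not scores:
        raise ValueError("no scores")
    rows = [{"position": f"{s.spec.chain_id}{s.spec.seq_number}{s.spec.icode}",
             "mut_aa": s.spec.mut_aa, "ddG": s.ddG} for s in scores]
    df = pd.DataFrame(rows)
    if df["position"].nunique() <= 2 or df["mut_aa"].nunique() <= 2:
        return None
    return df.pivot_table(index="position", columns="mut_aa", values="ddG",
                          aggfunc="first")


def top_stabilizing(scores: list[MutationScore], k: int = 25) -> pd.DataFrame:
    """Summary of the k most stabilizing mutations (ascending predicted ΔΔG)."""
    rows = [{"mutation": s.spec.label, "ddS_vib": s.ddS_vib,
             "ddG_B": s.ddG_B, "ddG": s.ddG} for s in scores]
    df = pd.DataFrame(rows).sort_values("ddG", kind="stable").reset_index(drop=True)
    return df.head(k)


def load_ddg_b_csv(path) -> dict[str, float]:
    """External enthalpic ΔΔG values keyed by mutation string (e.g. KA13Q)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    mcol = cols.get("mutation", df.columns[0])
    vcol = cols.get("value", cols.get("ddg_b", df.columns[1]))
    return {str(m): float(v) for m, v in zip(df[mcol], df[vcol])}
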