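"""Read, filter and coarse-grain protein structures.

Parsing is delegated to :mod:`gemmi`; on top of it this module collapses
multi-model files to the first model, resolves alternate locations to the
highest-occupancy conformer, strips heteroatoms/hydrogens, and reduces each
residue to a single node at its CA position — the representation on which the
elastic network is built.
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._chem import AA3_TO_1, atom_class, element_of

__all__ = [
    "Atom", "Residue", "Structure", "CoarseModel", "PDBParseError",
    "parse_pdb", "read_pdb", "preprocess", "build_coarse_model",
    "structure_to_pdb", "write_multimodel_pdb", "write_coarse_trajectory",
]


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray          # (3,), Angstrom
    is_hetero: bool = False
    atom_type_class: int = 8

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    icode: str                  # insertion code, "" when absent
    name: str                   # 3-letter residue name as read
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa_type(self) -> str | None:
        """One-letter code, or None for a nonstandard residue."""
        return AA3_TO_1.get(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.get_atom("CA")

    @property
    def node_coord(self) -> np.ndarray:
        ca = self.ca
        if ca is None:
            raise ValueError(f"residue {self.key} has no CA atom")
        return ca.coords

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in ("H", "D")]


@dataclass
class Structure:
    """Residues grouped by chain, in file order within each chain."""
    chains: dict[str, list[Residue]]
    source_id: str = ""

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def find(self, chain_id: str, seq_number: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, ()):
            if r.seq_number == seq_number and r.icode == icode:
                return r
        return None

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class CoarseModel:
    """One node per residue at the CA position."""
    nodes: np.ndarray                 # (N, 3)
    residues: list[Residue]           # node i <-> residues[i]

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.residues)

    @property
    def coords_flat(self) -> np.ndarray:
        return self.nodes.reshape(-1)

    def sequence(self, chain_id: str | None = None) -> str:
        res = [r for r in self.residues if chain_id is None or r.chain_id == chain_id]
        return "".join(r.aa_type or "X" for r in res)


def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise PDBParseError(
                    f"malformed coordinates on line {lineno}: {line.rstrip()!r}"
                ) from None


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by file order (first label)
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ + 1e-12:
            best = a
    return best


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    All models beyond the first are discarded; alternate locations are
    resolved to the highest-occupancy atom (ties: first in file order).
    """
    if not any(line.startswith("ATOM  ") for line in text.splitlines()):
        raise PDBParseError("no ATOM records found")
    _validate_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models found")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        for gres in chain:
            res = Residue(
                chain_id=chain.name,
                seq_number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                name=gres.name,
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for a in gres:
                if a.name not in by_name:
                    order.append(a.name)
                by_name.setdefault(a.name, []).append(a)
            for name in order:
                ga = _pick_altloc(by_name[name])
                elem = ga.element.name.upper() if ga.element else element_of(name)
                res.atoms.append(Atom(
                    name=name,
                    element=elem or element_of(name),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    is_hetero=(gres.het_flag == "H"),
                    atom_type_class=atom_class(gres.name, name),
                ))
            chains.setdefault(chain.name, []).append(res)
    return Structure(chains=chains, source_id=source_id or st.name)


def read_pdb(path: str | Path) -> Structure:
    p = Path(path)
    return parse_pdb(p.read_text(), source_id=p.stem)


def preprocess(structure: Structure, chains: set[str] | None = None) -> Structure:
    """Restrict to selected chains and strip heteroatoms and hydrogens.

    Selenomethionine (MSE) is recovered as MET; other nonstandard residues
    and residues left without a CA are dropped with a warning.  All residues
    of every selected chain are kept so that inter-chain contacts between
    selected chains enter the spring network.
    """
    available = set(structure.chains)
    if chains is None:
        chains = available
    chains = set(chains)
    if not chains:
        raise ValueError("chain selection is empty")
    missing = chains - available
    if missing:
        raise ValueError(
            f"chain(s) {sorted(missing)} not in structure; available: {sorted(available)}"
        )

    out: dict[str, list[Residue]] = {}
    for cid in structure.chains:
        if cid not in chains:
            continue
        kept: list[Residue] = []
        for res in structure.chains[cid]:
            name = res.name
            atoms = res.atoms
            if name == "MSE":
                name = "MET"
                atoms = [
                    Atom("SD", "S", a.coords, False, atom_class("MET", "SD"))
                    if a.name == "SE" else
                    Atom(a.name, a.element, a.coords, False, atom_class("MET", a.name))
                    for a in atoms
                ]
            elif name not in AA3_TO_1:
                if not all(a.is_hetero for a in res.atoms):
                    warnings.warn(f"dropping nonstandard residue {name} at {res.key}")
                continue
            heavy = [
                Atom(a.name, a.element, a.coords, False, a.atom_type_class)
                for a in atoms
                if a.element not in ("H", "D") and (name == "MET" or not a.is_hetero)
            ]
            new = Residue(cid, res.seq_number, res.icode, name, heavy)
            if new.ca is None:
                warnings.warn(f"dropping residue {new.key}: no CA after stripping")
                continue
            kept.append(new)
        out[cid] = kept
    if sum(len(v) for v in out.values()) == 0:
        raise ValueError("no residues survive preprocessing")
    return Structure(chains=out, source_id=structure.source_id)


def build_coarse_model(structure: Structure) -> CoarseModel:
    """Reduce a preprocessed structure to one node per residue at CA.

    Node order is deterministic: chains in structure order, residues sorted
    by (sequence number, insertion code) within each chain.
    """
    residues: list[Residue] = []
    for cid in structure.chains:
        residues.extend(sorted(structure.chains[cid], key=lambda r: (r.seq_number, r.icode)))
    if len(residues) < 2:
        raise ValueError(f"need at least 2 residues, got {len(residues)}")
    nodes = np.array([r.node_coord for r in residues])
    return CoarseModel(nodes=nodes, residues=residues)


def _atom_name_field(name: str) -> str:
    # PDB column 13-16: names shorter than 4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def _atom_line(serial: int, name: str, resname: str, chain: str, seq: int,
               icode: str, xyz: np.ndarray, element: str, hetero: bool = False) -> str:
    rec = "HETATM" if hetero else "ATOM  "
    return (
        f"{rec}{serial % 100000:5d} {_atom_name_field(name)} {resname:>3s} "
        f"{chain:1s}{seq:4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def structure_to_pdb(structure: Structure) -> str:
    """Serialize a Structure to PDB text (single model)."""
    lines: list[str] = []
    serial = 1
    for cid, residues in structure.chains.items():
        for res in residues:
            for a in res.atoms:
                lines.append(_atom_line(serial, a.name, res.name, cid,
                                        res.seq_number, res.icode, a.coords,
                                        a.element, a.is_hetero))
                serial += 1
        lines.append(f"TER   {serial % 100000:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _conformer_records(conf) -> list[tuple[str, str, str, int, str, np.ndarray, str]]:
    if isinstance(conf, CoarseModel):
        return [("CA", r.name, r.chain_id, r.seq_number, r.icode, xyz, "C")
                for r, xyz in zip(conf.residues, conf.nodes)]
    if isinstance(conf, Structure):
        recs = []
        for cid, residues in conf.chains.items():
            for r in residues:
                for a in r.atoms:
                    recs.append((a.name, r.name, cid, r.seq_number, r.icode,
                                 a.coords, a.element))
        return recs
    raise TypeError(f"cannot write conformer of type {type(conf).__name__}")


def write_multimodel_pdb(conformers: list, path: str | Path) -> None:
    """Write conformers as consecutive MODEL/ENDMDL blocks in the given order.

    Conformers must share atom count and ordering; coordinates round-trip
    through the fixed-width format to 3 decimals.
    """
    if not conformers:
        raise ValueError("no conformers to write")
    all_recs = [_conformer_records(c) for c in conformers]
    n0 = len(all_recs[0])
    for i, recs in enumerate(all_recs):
        if len(recs) != n0:
            raise ValueError(f"conformer {i} has {len(recs)} atoms, expected {n0}")
    lines: list[str] = []
    for imodel, recs in enumerate(all_recs, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        for serial, (name, resname, cid, seq, icode, xyz, elem) in enumerate(recs, 1):
            lines.append(_atom_line(serial, name, resname, cid, seq, icode, xyz, elem))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_coarse_trajectory(model: CoarseModel, coords_list: list[np.ndarray],
                            path: str | Path) -> None:
    """Write a series of node-coordinate frames over a coarse model as a
    multi-model CA-trace PDB."""
    frames = []
    for xyz in coords_list:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if xyz.shape[0] != model.n_nodes:
            raise ValueError("frame size does not match model")
        frames.append(CoarseModel(nodes=xyz, residues=model.residues))
    write_multimodel_pdb(frames, path)
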