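"""Multi-model PDB input/output and site resolution.

Docking poses and trajectory frames are both consumed as multi-model PDB
files: one MODEL per pose/frame, with a declared ligand chain and receptor
chain.  Reading is backed by Biopython's :mod:`Bio.PDB` (strict multi-model
parsing, altloc handling), preceded by a light fixed-column pre-scan so that
malformed ATOM records are reported with their line number.  Writing is
plain fixed-column formatting, preserving coordinates to the PDB's three
decimals so a read→write→read round trip is exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Pose",
    "PoseEnsemble",
    "SiteSelection",
    "PDBFormatError",
    "SiteNotFoundError",
    "load_ensemble",
    "write_ensemble",
    "resolve_site",
    "is_heavy",
]

#: atom names treated as backbone (everything else is side chain)
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"})

_TWO_LETTER_ELEMENTS = frozenset({"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA", "CU", "NI", "SE"})


class PDBFormatError(ValueError):
    """Malformed or contract-violating PDB content."""


class SiteNotFoundError(KeyError):
    """A site selection resolved to zero residues."""


@dataclass(frozen=True)
class Atom:
    """One atom of a pose: identity, residue context and Cartesian position (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    xyz: np.ndarray
    is_sidechain: bool
    occupancy: float = 1.0

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.name} has invalid coordinates {self.xyz!r}")
        object.__setattr__(self, "xyz", xyz)
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")

    def moved_to(self, xyz) -> "Atom":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


def is_heavy(atom: Atom) -> bool:
    return atom.element.upper() not in ("H", "D")


@dataclass
class Pose:
    """One model of a multi-model file: an ordered atom list."""

    model_id: int
    atoms: List[Atom]

    def chains(self) -> set:
        return {a.chain_id for a in self.atoms}

    def chain_atoms(self, chain_id: str) -> List[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residues(self, chain_id: str) -> Dict[int, List[Atom]]:
        """Residue-seq → atoms mapping for one chain, in file order."""
        out: Dict[int, List[Atom]] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                out.setdefault(a.residue_seq, []).append(a)
        return out

    def residue_name(self, chain_id: str, residue_seq: int) -> str:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_seq == residue_seq:
                return a.residue_name
        raise SiteNotFoundError(f"no residue {chain_id}:{residue_seq} in model {self.model_id}")


@dataclass
class PoseEnsemble:
    """Ordered poses with declared ligand/receptor chain roles."""

    poses: List[Pose]
    ligand_chain: str
    receptor_chain: str
    source: str = ""

    def __post_init__(self):
        for pose in self.poses:
            chains = pose.chains()
            for role, cid in (("ligand", self.ligand_chain), ("receptor", self.receptor_chain)):
                if cid not in chains:
                    raise PDBFormatError(
                        f"model {pose.model_id} lacks declared {role} chain {cid!r} "
                        f"(source {self.source or '<memory>'})"
                    )

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def assert_constant_composition(self) -> None:
        """Raise unless per-chain atom counts are identical across poses (trajectory contract)."""
        def sig(pose: Pose):
            return tuple(sorted((a.chain_id, a.residue_seq, a.name) for a in pose.atoms))

        ref = sig(self.poses[0])
        for pose in self.poses[1:]:
            if sig(pose) != ref:
                raise PDBFormatError(
                    f"model {pose.model_id} has different atom composition than model "
                    f"{self.poses[0].model_id}; not a trajectory"
                )


@dataclass(frozen=True)
class SiteSelection:
    """A chain + 1-based inclusive residue range, optionally labelled ('EVHH')."""

    chain_id: str
    first: int
    last: int
    label: Optional[str] = None

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError(f"site range reversed: {self.first} > {self.last}")

    @classmethod
    def parse(cls, text: str, label: Optional[str] = None) -> "SiteSelection":
        """Parse 'A:11-14' notation."""
        try:
            chain, rng = text.split(":")
            first, last = rng.split("-")
            return cls(chain.strip(), int(first), int(last), label)
        except Exception as exc:
            raise ValueError(f"cannot parse site selection {text!r}; expected 'A:11-14'") from exc

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.first}-{self.last}"


def _prescan(path: Path) -> None:
    """Cheap fixed-column validation of ATOM/HETATM records, with line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"{path} line {lineno}: truncated {rec} record")
            try:
                int(line[6:11])
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"{path} line {lineno}: malformed {rec} record: {line.rstrip()!r}"
                ) from None
            if line[26] != " ":
                raise PDBFormatError(
                    f"{path} line {lineno}: insertion codes are not supported "
                    f"(icode {line[26]!r})"
                )


def _infer_element(name: str) -> str:
    stripped = name.strip()
    if len(name) >= 2 and name[:2].upper() in _TWO_LETTER_ELEMENTS and not name[0].isdigit():
        return name[:2].strip().upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise PDBFormatError(f"cannot infer element from atom name {name!r}")


def _select_altloc(bio_atom):
    """Highest-occupancy conformer; ties broken toward altloc 'A'."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def load_ensemble(
    path: Union[str, Path],
    ligand_chain: str,
    receptor_chain: str,
) -> PoseEnsemble:
    """Load a multi-model PDB as a :class:`PoseEnsemble`.

    One pose per MODEL record (or a single pose for a model-less file).
    Hydrogens are kept when present.  Altloc policy: highest occupancy,
    ties → 'A'.  Missing declared chains and malformed records raise
    :class:`PDBFormatError` naming the model / line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    poses: List[Pose] = []
    for model in structure:
        atoms: List[Atom] = []
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.id
                if icode.strip():
                    raise PDBFormatError(f"insertion code on residue {resseq} in {path}")
                for bio_atom in residue:
                    a = _select_altloc(bio_atom)
                    name = a.get_name()
                    element = (a.element or "").strip().upper() or _infer_element(
                        a.get_fullname()
                    )
                    atoms.append(
                        Atom(
                            serial=a.get_serial_number() or len(atoms) + 1,
                            name=name,
                            element=element,
                            residue_name=residue.get_resname().strip(),
                            residue_seq=resseq,
                            chain_id=chain.id,
                            xyz=a.get_coord(),
                            is_sidechain=name not in BACKBONE_NAMES,
                            occupancy=a.get_occupancy() or 1.0,
                        )
                    )
        model_id = getattr(model, "serial_num", 0) or (model.id + 1)
        poses.append(Pose(model_id=model_id, atoms=atoms))
    if not poses:
        raise PDBFormatError(f"{path}: no models found")
    return PoseEnsemble(
        poses=poses, ligand_chain=ligand_chain, receptor_chain=receptor_chain, source=str(path)
    )


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_ensemble(ensemble_or_poses, path: Union[str, Path]) -> None:
    """Write poses as a multi-model PDB (fixed format, 3-decimal coordinates)."""
    poses = ensemble_or_poses.poses if hasattr(ensemble_or_poses, "poses") else ensemble_or_poses
    with open(path, "w") as fh:
        multi = len(poses) > 1
        for pose in poses:
            if multi:
                fh.write(f"MODEL     {pose.model_id:4d}\n")
            for atom in pose.atoms:
                fh.write(
                    "ATOM  {serial:5d} {name}{alt}{res:>3s} {chain}{seq:4d}{icode}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                        serial=atom.serial,
                        name=_format_atom_name(atom.name, atom.element),
                        alt=" ",
                        res=atom.residue_name,
                        chain=atom.chain_id,
                        seq=atom.residue_seq,
                        icode=" ",
                        x=atom.xyz[0],
                        y=atom.xyz[1],
                        z=atom.xyz[2],
                        occ=atom.occupancy,
                        b=0.0,
                        elem=atom.element[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def resolve_site(ensemble: PoseEnsemble, selection: SiteSelection) -> List[List[Atom]]:
    """Resolve a site selection to atoms, per model.

    Returns one atom list per pose (atoms of residues in the inclusive range).
    Raises :class:`SiteNotFoundError` if any model resolves zero residues.
    """
    out: List[List[Atom]] = []
    for pose in ensemble:
        atoms = [
            a
            for a in pose.atoms
            if a.chain_id == selection.chain_id
            and selection.first <= a.residue_seq <= selection.last
        ]
        if not atoms:
            raise SiteNotFoundError(
                f"site not found: chain {selection.chain_id!r} residues "
                f"{selection.first}-{selection.last} resolve to zero residues in "
                f"model {pose.model_id}"
            )
        out.append(atoms)
    return out
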