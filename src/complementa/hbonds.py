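"""Geometric hydrogen-bond detection and docking-pose triage.

Hydrogen bonds are called from geometry alone: a donor-capable N/O in one
site, an acceptor N/O in the other, donor–acceptor heavy-atom distance below
a cutoff (default 3.5 Å), plus an angular check — the D–H···A angle when
explicit hydrogens are present, otherwise a heavy-atom proxy (the
antecedent–D···A angle).  Donor/acceptor capability comes from a fixed
residue-template table; histidine ring nitrogens are treated as both
donor- and acceptor-capable since protonation states are unknown in docking
outputs.

On top of detection sit the triage tools: His–Glu pair identification,
site-orientation labels (parallel / antiparallel / crosswise from the Cα
end-to-end vectors of the two sites), and the model-selection filter that
keeps poses with at least ``min_bonds`` site–site hydrogen bonds through at
least ``min_distinct_sidechain_atoms`` distinct side-chain atoms.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .structio import (
    Atom,
    Pose,
    PoseEnsemble,
    SiteSelection,
    SiteNotFoundError,
    is_heavy,
)

__all__ = [
    "HBondCriteria",
    "AtomRef",
    "HBond",
    "PoseTriageReport",
    "detect_hbonds",
    "his_glu_pairs",
    "classify_orientation",
    "filter_models",
]

# residue-template donor table: resname -> donor atom -> antecedent heavy atom
SIDECHAIN_DONORS: Dict[str, Dict[str, str]] = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "TRP": {"NE1": "CE2"},
    # His ring nitrogens: protonation unknown → donor-capable on both
    "HIS": {"ND1": "CG", "NE2": "CE1"},
}

# resname -> acceptor atom names (backbone O/OXT handled separately)
SIDECHAIN_ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

BACKBONE_DONOR = ("N", "CA")  # donor atom, antecedent
BACKBONE_ACCEPTORS = ("O", "OXT")

_H_COVALENT_MAX = 1.25  # Å, H considered attached to a donor heavy atom


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds for calling a hydrogen bond.

    ``max_da_distance`` — donor–acceptor heavy-atom distance cutoff (Å).
    ``min_dha_angle`` — D–H···A angle (degrees), applied when the donor has
    an explicit hydrogen.  ``min_heavy_angle`` — antecedent–D···A proxy angle
    (degrees), applied when hydrogens are absent.
    """

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0
    min_heavy_angle: float = 90.0

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not (0 <= self.min_dha_angle <= 180) or not (0 <= self.min_heavy_angle <= 180):
            raise ValueError("angles must be within [0, 180] degrees")


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    residue_seq: int
    residue_name: str
    atom_name: str

    def label(self) -> str:
        return f"{self.residue_name.capitalize()}{self.residue_seq}({self.chain_id}):{self.atom_name}"


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    angle: Optional[float]  # D–H···A if measured, else None ("n/a")
    donor_is_sidechain: bool
    acceptor_is_sidechain: bool

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("H-bond distance must be positive")
        if (self.donor.chain_id, self.donor.residue_seq) == (
            self.acceptor.chain_id,
            self.acceptor.residue_seq,
        ):
            raise ValueError("donor and acceptor must be on different residues")

    def to_dict(self) -> dict:
        return {
            "donor": self.donor.label(),
            "acceptor": self.acceptor.label(),
            "distance": round(self.distance, 3),
            "angle": None if self.angle is None else round(self.angle, 1),
            "donor_is_sidechain": self.donor_is_sidechain,
            "acceptor_is_sidechain": self.acceptor_is_sidechain,
        }


def _angle_deg(p_center: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - p_center
    v2 = p2 - p_center
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _site_residues(pose: Pose, site: SiteSelection) -> Dict[int, List[Atom]]:
    residues = {
        seq: atoms
        for seq, atoms in pose.residues(site.chain_id).items()
        if site.first <= seq <= site.last
    }
    if not residues:
        raise SiteNotFoundError(
            f"site not found: {site} resolves to zero residues in model {pose.model_id}"
        )
    return residues


def _donors_of(atoms: List[Atom]) -> List[Tuple[Atom, Optional[Atom], List[Atom]]]:
    """(donor heavy atom, antecedent or None, attached hydrogens) per residue."""
    by_name = {a.name: a for a in atoms}
    resname = atoms[0].residue_name
    entries: List[Tuple[str, str]] = []
    if BACKBONE_DONOR[0] in by_name:
        entries.append(BACKBONE_DONOR)
    for dname, ante in SIDECHAIN_DONORS.get(resname, {}).items():
        if dname in by_name:
            entries.append((dname, ante))
    out = []
    hydrogens = [a for a in atoms if not is_heavy(a)]
    for dname, ante in entries:
        donor = by_name[dname]
        attached = [
            h for h in hydrogens if np.linalg.norm(h.xyz - donor.xyz) <= _H_COVALENT_MAX
        ]
        out.append((donor, by_name.get(ante), attached))
    return out


def _acceptors_of(atoms: List[Atom]) -> List[Atom]:
    resname = atoms[0].residue_name
    wanted = set(BACKBONE_ACCEPTORS) | set(SIDECHAIN_ACCEPTORS.get(resname, ()))
    return [a for a in atoms if a.name in wanted]


def detect_hbonds(
    pose: Pose,
    site_a: SiteSelection,
    site_b: SiteSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> List[HBond]:
    """Hydrogen bonds between two sites of one pose, both directions searched.

    Returns every donor→acceptor pair satisfying the geometric criteria; the
    angle field carries the D–H···A angle when an explicit hydrogen was used,
    and None when the heavy-atom proxy applied.
    """
    res_a = _site_residues(pose, site_a)
    res_b = _site_residues(pose, site_b)
    bonds: List[HBond] = []
    seen = set()
    for donor_side, acceptor_side in ((res_a, res_b), (res_b, res_a)):
        acceptor_atoms = [a for atoms in acceptor_side.values() for a in _acceptors_of(atoms)]
        for atoms in donor_side.values():
            for donor, antecedent, hydrogens in _donors_of(atoms):
                for acc in acceptor_atoms:
                    d = float(np.linalg.norm(donor.xyz - acc.xyz))
                    if d > criteria.max_da_distance or d == 0.0:
                        continue
                    angle: Optional[float] = None
                    if hydrogens:
                        best = max(
                            _angle_deg(h.xyz, donor.xyz, acc.xyz) for h in hydrogens
                        )
                        if best < criteria.min_dha_angle:
                            continue
                        angle = best
                    elif antecedent is not None:
                        proxy = _angle_deg(donor.xyz, antecedent.xyz, acc.xyz)
                        if proxy < criteria.min_heavy_angle:
                            continue
                    key = (
                        donor.chain_id,
                        donor.residue_seq,
                        donor.name,
                        acc.chain_id,
                        acc.residue_seq,
                        acc.name,
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    bonds.append(
                        HBond(
                            donor=AtomRef(
                                donor.chain_id, donor.residue_seq, donor.residue_name, donor.name
                            ),
                            acceptor=AtomRef(
                                acc.chain_id, acc.residue_seq, acc.residue_name, acc.name
                            ),
                            distance=d,
                            angle=angle,
                            donor_is_sidechain=donor.is_sidechain,
                            acceptor_is_sidechain=acc.is_sidechain,
                        )
                    )
    bonds.sort(
        key=lambda b: (
            b.donor.chain_id,
            b.donor.residue_seq,
            b.donor.atom_name,
            b.acceptor.chain_id,
            b.acceptor.residue_seq,
            b.acceptor.atom_name,
        )
    )
    return bonds


def his_glu_pairs(hbonds: Sequence[HBond]) -> List[Tuple[AtomRef, AtomRef, str]]:
    """Deduplicated residue-level His↔Glu pairs from a bond list.

    Each pair is ordered by chain id (then residue) and rendered as a
    'Glu11-His35'-style label; chain attribution is preserved in the refs.
    """
    pairs = {}
    for b in hbonds:
        names = {b.donor.residue_name, b.acceptor.residue_name}
        if names != {"HIS", "GLU"}:
            continue
        first, second = sorted(
            (b.donor, b.acceptor), key=lambda r: (r.chain_id, r.residue_seq)
        )
        key = (first.chain_id, first.residue_seq, second.chain_id, second.residue_seq)
        if key not in pairs:
            ref1 = AtomRef(first.chain_id, first.residue_seq, first.residue_name, "")
            ref2 = AtomRef(second.chain_id, second.residue_seq, second.residue_name, "")
            label = (
                f"{first.residue_name.capitalize()}{first.residue_seq}-"
                f"{second.residue_name.capitalize()}{second.residue_seq}"
            )
            pairs[key] = (ref1, ref2, label)
    return [pairs[k] for k in sorted(pairs)]


def classify_orientation(
    pose: Pose,
    site_a: SiteSelection,
    site_b: SiteSelection,
    crosswise_threshold: float = 0.5,
) -> str:
    """Label the mutual orientation of two sites from their Cα axes.

    With u, v the Cα(last)−Cα(first) vectors of the sites and
    cosθ = u·v/(|u||v|): cosθ ≥ +T → 'parallel', cosθ ≤ −T → 'antiparallel',
    otherwise 'crosswise' (default T = 0.5, i.e. a ±60° parallel band).
    """
    if not (0 < crosswise_threshold <= 1):
        raise ValueError("crosswise_threshold must be in (0, 1]")

    def axis_vector(site: SiteSelection) -> np.ndarray:
        cas = sorted(
            (
                a
                for a in pose.atoms
                if a.chain_id == site.chain_id
                and site.first <= a.residue_seq <= site.last
                and a.name == "CA"
            ),
            key=lambda a: a.residue_seq,
        )
        if len(cas) < 2:
            raise SiteNotFoundError(
                f"site {site} needs ≥2 residues with CA atoms in model {pose.model_id}"
            )
        return cas[-1].xyz - cas[0].xyz

    u = axis_vector(site_a)
    v = axis_vector(site_b)
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    if cosang >= crosswise_threshold:
        return "parallel"
    if cosang <= -crosswise_threshold:
        return "antiparallel"
    return "crosswise"


@dataclass
class PoseTriageReport:
    """Triage outcome for one pose against the site–site H-bond filter."""

    pose_id: int
    bonds: List[HBond]
    n_bonds: int
    n_distinct_sidechain_atoms: int
    passed: bool
    orientation: str
    his_glu_pairs: List[str]

    def to_dict(self) -> dict:
        return {
            "pose_id": self.pose_id,
            "n_bonds": self.n_bonds,
            "n_distinct_sidechain_atoms": self.n_distinct_sidechain_atoms,
            "pass": self.passed,
            "orientation": self.orientation,
            "his_glu_pairs": self.his_glu_pairs,
            "bonds": [b.to_dict() for b in self.bonds],
        }


def _distinct_sidechain_atoms(
    bonds: Sequence[HBond], count_side: str, site_a: SiteSelection, site_b: SiteSelection
) -> int:
    atoms = set()
    for b in bonds:
        for ref, is_sc in (
            (b.donor, b.donor_is_sidechain),
            (b.acceptor, b.acceptor_is_sidechain),
        ):
            if not is_sc:
                continue
            if count_side == "siteA" and ref.chain_id != site_a.chain_id:
                continue
            if count_side == "siteB" and ref.chain_id != site_b.chain_id:
                continue
            atoms.add((ref.chain_id, ref.residue_seq, ref.atom_name))
    return len(atoms)


def filter_models(
    ensemble: PoseEnsemble,
    site_a: SiteSelection,
    site_b: SiteSelection,
    min_bonds: int = 3,
    min_distinct_sidechain_atoms: int = 3,
    criteria: HBondCriteria = HBondCriteria(),
    count_side: str = "both",
    crosswise_threshold: float = 0.5,
) -> Tuple[List[PoseTriageReport], List[Pose]]:
    """Apply the model-selection filter to every pose of an ensemble.

    A pose passes when it has at least ``min_bonds`` hydrogen bonds between
    the two sites AND those bonds involve at least
    ``min_distinct_sidechain_atoms`` distinct side-chain atoms (unique
    (chain, residue, atom-name) triples with the side-chain flag set).
    ``count_side`` selects which interface side contributes to the distinct
    count: 'both' (default), 'siteA' or 'siteB'.

    Returns per-pose reports and the passing pose subset, in input order.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if count_side not in ("both", "siteA", "siteB"):
        raise ValueError(f"unknown count_side {count_side!r}")
    reports: List[PoseTriageReport] = []
    passing: List[Pose] = []
    for pose in ensemble:
        bonds = detect_hbonds(pose, site_a, site_b, criteria)
        n_distinct = _distinct_sidechain_atoms(bonds, count_side, site_a, site_b)
        passed = len(bonds) >= min_bonds and n_distinct >= min_distinct_sidechain_atoms
        reports.append(
            PoseTriageReport(
                pose_id=pose.model_id,
                bonds=bonds,
                n_bonds=len(bonds),
                n_distinct_sidechain_atoms=n_distinct,
                passed=passed,
                orientation=classify_orientation(pose, site_a, site_b, crosswise_threshold),
                his_glu_pairs=[label for _, _, label in his_glu_pairs(bonds)],
            )
        )
        if passed:
            passing.append(pose)
    return reports, passing


def reports_to_tsv(reports: Sequence[PoseTriageReport], path: Union[str, Path]) -> None:
    """Summary TSV: pose_id, n_bonds, n_distinct_sidechain_atoms, pass, orientation, pairs."""
    with open(path, "w") as fh:
        fh.write("pose_id\tn_bonds\tn_distinct_sidechain_atoms\tpass\torientation\this_glu_pairs\n")
        for r in reports:
            fh.write(
                f"{r.pose_id}\t{r.n_bonds}\t{r.n_distinct_sidechain_atoms}\t"
                f"{r.passed}\t{r.orientation}\t{';'.join(r.his_glu_pairs)}\n"
            )


def reports_to_json(reports: Sequence[PoseTriageReport], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
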