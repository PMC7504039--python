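"""Synthetic inputs with recorded ground truth for every pipeline stage.

The pipeline's real-world inputs — protein sequences, docking-server pose
ensembles, MD trajectory frames, SPR sensorgrams — are emulated here by
deterministic, seeded generators that serialize their ground truth alongside
each artifact, so every downstream operation has an exact expected output.

Structures use idealized peptide geometry: extended backbones with 3.8 Å
Cα spacing and schematic side chains built from fixed templates.  Chemical
realism is deliberately absent — downstream code consumes only distances and
angles, and idealization makes the planted interactions exact.  The ligand
chain A is the amyloid-β 1–16 fragment (DAEFRHDSGYEVHHQK, so the EVHH site
occupies residues 11–14); the receptor chain B is a 16-residue fragment
numbered 30–45 carrying HAEE at 35–38.  Hydrogens are not generated, so
hydrogen-bond detection exercises the heavy-atom angle proxy.

Every generator self-validates: immediately after building an artifact it
runs the relevant detector and asserts the ground truth is realized, raising
:class:`GenerationError` otherwise (e.g. when coordinate jitter is large
enough to violate a planted schedule).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import sprkin
from .contacts import atomic_contacts, contact_profile
from .hbonds import HBondCriteria, classify_orientation, detect_hbonds
from .motifs import complement_pattern, scan_sequences
from .structio import Atom, Pose, PoseEnsemble, SiteSelection, write_ensemble
from .trajstab import BondSpec, bond_timeline, rebinding_events

__all__ = [
    "GenerationError",
    "GroundTruth",
    "SITE_EVHH",
    "SITE_HAEE",
    "POSE_KINDS",
    "gen_sequences",
    "alpha4_standin_sequence",
    "gen_pose_ensemble",
    "gen_trajectory",
    "gen_rebind_trajectory",
    "gen_sensorgrams",
]

SITE_EVHH = SiteSelection("A", 11, 14, "EVHH")
SITE_HAEE = SiteSelection("B", 35, 38, "HAEE")

LIGAND_SEQ = "DAEFRHDSGYEVHHQK"  # amyloid-β 1–16; EVHH at 11–14
RECEPTOR_SEQ = "AAAAAHAEEAAAAAAA"  # numbered 30–45; HAEE at 35–38
RECEPTOR_START = 30

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_STANDARD20 = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(RuntimeError):
    """A generator could not realize (or failed to self-validate) its ground truth."""


@dataclass
class GroundTruth:
    """Ground truth of one generated artifact; serialized as a JSON sidecar."""

    data: dict

    def save(self, artifact_path: Union[str, Path]) -> Path:
        path = Path(str(artifact_path) + ".truth.json")
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=_jsonable)
        return path

    @classmethod
    def load(cls, artifact_path: Union[str, Path]) -> "GroundTruth":
        with open(str(artifact_path) + ".truth.json") as fh:
            return cls(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_sequences(
    n: int,
    length: int,
    planted: Sequence[Tuple[str, int]] = (),
    seed: Optional[int] = None,
    out_path: Optional[Union[str, Path]] = None,
) -> Tuple[List[Tuple[str, str]], GroundTruth]:
    """Random protein sequences with literal motifs planted at recorded offsets.

    Background residues are uniform over the 20 standard codes; the background
    is NOT guaranteed free of accidental pattern matches, so the ground truth
    records planted intervals only.  Returns (id, sequence) pairs and the
    ground truth; ``out_path`` additionally writes FASTA plus a
    ``.truth.json`` sidecar.  Deterministic (byte-identical) under a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    total_planted = sum(count * len(m) for m, count in planted)
    if any(len(m) > length for m, _ in planted) or total_planted > length:
        raise GenerationError(f"cannot pack {planted!r} into length {length}")
    records: List[Tuple[str, str]] = []
    intervals: Dict[str, list] = {}
    for i in range(n):
        sid = f"synthetic_{i + 1}"
        seq = list(rng.choice(list(_STANDARD20), size=length))
        occupied: List[Tuple[int, int]] = []
        placed = []
        for motif, count in planted:
            for _ in range(count):
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - len(motif) + 1))
                    end = start + len(motif)
                    if all(end <= a or start >= b for a, b in occupied):
                        occupied.append((start, end))
                        seq[start:end] = list(motif)
                        placed.append({"motif": motif, "start": start + 1, "end": end})
                        break
                else:
                    raise GenerationError(
                        f"could not place motif {motif!r} without overlap in {sid}"
                    )
        records.append((sid, "".join(seq)))
        intervals[sid] = sorted(placed, key=lambda d: d["start"])
    # self-validation: every planted interval reads back as its motif
    for sid, seq in records:
        for item in intervals[sid]:
            got = seq[item["start"] - 1 : item["end"]]
            if got != item["motif"]:
                raise GenerationError(f"planted motif corrupted in {sid}: {got!r}")
    truth = GroundTruth(
        {"kind": "sequences", "seed": seed, "n": n, "length": length, "planted": intervals}
    )
    if out_path is not None:
        with open(out_path, "w") as fh:
            for sid, seq in records:
                fh.write(f">{sid}\n{seq}\n")
        truth.save(out_path)
    return records, truth


def alpha4_standin_sequence(seed: int = 20) -> Tuple[Tuple[str, str], GroundTruth]:
    """Synthetic stand-in for the human nAChR α4 subunit sequence.

    A 627-residue random sequence with HAEE planted at positions 35–38 and
    KAED at 579–582 — the two charge-complementary motifs of the EVHH query
    and the coordinates at which the real subunit carries them.  The
    background is resampled (deterministically) until the EVHH complement
    pattern matches nowhere else, so a scan yields exactly those two hits.
    This is a synthetic surrogate, not the UniProt sequence.
    """
    pattern = complement_pattern("EVHH", "parallel")
    length, h_start, k_start = 627, 35, 579
    for attempt in range(500):
        rng = np.random.default_rng((seed + attempt) % 2**31)
        seq = list(rng.choice(list(_STANDARD20), size=length))
        seq[h_start - 1 : h_start + 3] = list("HAEE")
        seq[k_start - 1 : k_start + 3] = list("KAED")
        record = ("alpha4_standin", "".join(seq))
        hits = scan_sequences(pattern, [record])
        if [(h.start, h.matched) for h in hits] == [(35, "HAEE"), (579, "KAED")]:
            truth = GroundTruth(
                {
                    "kind": "alpha4_standin",
                    "seed": seed,
                    "length": length,
                    "planted": [
                        {"motif": "HAEE", "start": 35, "end": 38},
                        {"motif": "KAED", "start": 579, "end": 582},
                    ],
                }
            )
            return record, truth
    raise GenerationError("could not build a clean stand-in sequence")


# ---------------------------------------------------------------------------
# idealized structures
# ---------------------------------------------------------------------------

_BACKBONE_TEMPLATE = [
    ("N", "N", (-1.2, 0.0, 0.8)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.0, 0.8)),
    ("O", "O", (1.2, 0.0, 2.0)),
]

_CB = ("CB", "C", (0.0, 0.0, -1.5))
_SIDECHAIN_TEMPLATES: Dict[str, list] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "O", (0.0, 0.0, -2.7))],
    "CYS": [_CB, ("SG", "S", (0.0, 0.0, -2.8))],
    "THR": [_CB, ("OG1", "O", (-0.8, 0.0, -2.6)), ("CG2", "C", (0.8, 0.0, -2.6))],
    "VAL": [_CB, ("CG1", "C", (-0.8, 0.0, -2.6)), ("CG2", "C", (0.8, 0.0, -2.6))],
    "LEU": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CD1", "C", (-0.8, 0.0, -3.6)),
            ("CD2", "C", (0.8, 0.0, -3.6))],
    "ILE": [_CB, ("CG1", "C", (-0.8, 0.0, -2.6)), ("CG2", "C", (0.8, 0.0, -2.6)),
            ("CD1", "C", (-0.8, 0.0, -3.9))],
    "MET": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("SD", "S", (0.0, 0.0, -4.2)),
            ("CE", "C", (0.0, 0.0, -5.5))],
    "PRO": [_CB, ("CG", "C", (0.8, 0.0, -2.4)), ("CD", "C", (-1.0, 0.0, -1.2))],
    "PHE": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CZ", "C", (0.0, 0.0, -5.0))],
    "TYR": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CZ", "C", (0.0, 0.0, -5.0)),
            ("OH", "O", (0.0, 0.0, -6.2))],
    "TRP": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("NE1", "N", (-1.0, 0.0, -4.2)),
            ("CE2", "C", (0.0, 0.0, -4.8))],
    "ASP": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("OD1", "O", (-1.0, 0.0, -3.6)),
            ("OD2", "O", (1.0, 0.0, -3.6))],
    "ASN": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("OD1", "O", (-1.0, 0.0, -3.6)),
            ("ND2", "N", (1.0, 0.0, -3.6))],
    "GLU": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CD", "C", (0.0, 0.0, -4.2)),
            ("OE1", "O", (-1.0, 0.0, -5.0)), ("OE2", "O", (1.0, 0.0, -5.0))],
    "GLN": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CD", "C", (0.0, 0.0, -4.2)),
            ("OE1", "O", (-1.0, 0.0, -5.0)), ("NE2", "N", (1.0, 0.0, -5.0))],
    "HIS": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("ND1", "N", (-1.1, 0.0, -3.6)),
            ("CD2", "C", (1.1, 0.0, -3.6)), ("CE1", "C", (-0.7, 0.0, -4.7)),
            ("NE2", "N", (0.7, 0.0, -4.7))],
    "LYS": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CD", "C", (0.0, 0.0, -4.2)),
            ("CE", "C", (0.0, 0.0, -5.5)), ("NZ", "N", (0.0, 0.0, -6.5))],
    "ARG": [_CB, ("CG", "C", (0.0, 0.0, -2.8)), ("CD", "C", (0.0, 0.0, -4.2)),
            ("NE", "N", (0.0, 0.0, -5.4)), ("CZ", "C", (0.0, 0.0, -6.4)),
            ("NH1", "N", (-1.0, 0.0, -7.1)), ("NH2", "N", (1.0, 0.0, -7.1))],
}

_CA_SPACING = 3.8
_STAGGER = 0.8  # side chains of even/odd residues offset ±0.8 Å along ŷ
_CHAIN_SEP = 20.0  # baseline inter-chain separation along ŷ


def _axes(orientation: str):
    """(chain axis, normal axis, 'up' axis) unit vectors for a chain direction."""
    y = np.array([0.0, 1.0, 0.0])
    if orientation == "parallel":
        return np.array([1.0, 0.0, 0.0]), y, np.array([0.0, 0.0, 1.0])
    if orientation == "antiparallel":
        return np.array([-1.0, 0.0, 0.0]), y, np.array([0.0, 0.0, 1.0])
    if orientation == "crosswise":
        return np.array([0.0, 0.0, 1.0]), y, np.array([1.0, 0.0, 0.0])
    raise ValueError(f"unknown orientation {orientation!r}")


def _build_chain(
    chain_id: str,
    sequence: str,
    start_seq: int,
    origin: np.ndarray,
    orientation: str = "parallel",
    serial_start: int = 1,
) -> List[Atom]:
    axis, normal, up = _axes(orientation)
    atoms: List[Atom] = []
    serial = serial_start
    for i, aa in enumerate(sequence):
        resname = _AA3[aa.upper()]
        seq = start_seq + i
        base = origin + axis * (_CA_SPACING * i)
        stagger = _STAGGER if seq % 2 == 0 else -_STAGGER
        for name, element, (dx, dy, dz) in _BACKBONE_TEMPLATE + _SIDECHAIN_TEMPLATES[resname]:
            pos = base + dx * axis + dy * normal + dz * up
            if dz < 0:  # side-chain atoms carry the parity stagger
                pos = pos + stagger * normal
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_seq=seq,
                    chain_id=chain_id,
                    xyz=pos,
                    is_sidechain=name not in ("N", "CA", "C", "O"),
                )
            )
            serial += 1
    return atoms


def _base_pose(model_id: int, orientation: str = "parallel") -> Pose:
    lig = _build_chain("A", LIGAND_SEQ, 1, np.zeros(3), "parallel")
    rec = _build_chain(
        "B",
        RECEPTOR_SEQ,
        RECEPTOR_START,
        np.array([0.0, _CHAIN_SEP, 0.0]),
        orientation,
        serial_start=len(lig) + 1,
    )
    return Pose(model_id=model_id, atoms=lig + rec)


def _atom_index(pose: Pose) -> Dict[Tuple[str, int, str], int]:
    return {(a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(pose.atoms)}


def _pos(pose: Pose, key: Tuple[str, int, str]) -> np.ndarray:
    return pose.atoms[_atom_index(pose)[key]].xyz


def _relocate(pose: Pose, key: Tuple[str, int, str], xyz: np.ndarray) -> None:
    idx = _atom_index(pose)[key]
    pose.atoms[idx] = pose.atoms[idx].moved_to(xyz)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# planted hydrogen bonds of a passing pose, mirroring the His–Glu contact
# combinations seen at the EVHH:HAEE interface: Glu11–His35, His13–Glu38,
# His14–Glu38.  Each entry: (moved B atom, anchor A atom, direction, extras)
# where the B atom lands at anchor + 2.9·direction and "extras" relocates the
# donor antecedent to keep the proxy angle wide open.
_HB_DIST = 2.9
_PLANTED_BONDS = {
    "b1": {  # donor NE2(B His35) → acceptor OE1(A Glu11)
        "spec": "A:GLU:11-B:HIS:35",
        "moved": ("B", 35, "NE2"),
        "anchor": ("A", 11, "OE1"),
        "direction": (-0.3, -1.0, 0.0),
        "antecedent": ("B", 35, "CE1"),
        "donor": ("B", 35, "NE2"),
        "acceptor": ("A", 11, "OE1"),
    },
    "b2": {  # donor NE2(A His13) → acceptor OE1(B Glu38)
        "spec": "A:HIS:13-B:GLU:38",
        "moved": ("B", 38, "OE1"),
        "anchor": ("A", 13, "NE2"),
        "direction": (0.3, -1.0, 0.0),
        "antecedent": None,
        "donor": ("A", 13, "NE2"),
        "acceptor": ("B", 38, "OE1"),
    },
    "b3": {  # donor ND1(A His14) → acceptor OE2(B Glu38)
        "spec": "A:HIS:14-B:GLU:38",
        "moved": ("B", 38, "OE2"),
        "anchor": ("A", 14, "ND1"),
        "direction": (-0.23, 1.0, -0.17),
        "antecedent": None,
        "donor": ("A", 14, "ND1"),
        "acceptor": ("B", 38, "OE2"),
    },
}

#: pose construction recipes available to :func:`gen_pose_ensemble`
POSE_KINDS = ("pass", "two_bonds", "one_bond", "backbone_only", "shared_atom",
              "detached", "contacts")


def _plant_bond(pose: Pose, name: str) -> dict:
    cfg = _PLANTED_BONDS[name]
    anchor = _pos(pose, cfg["anchor"])
    u = _unit(cfg["direction"])
    target = anchor + _HB_DIST * u
    _relocate(pose, cfg["moved"], target)
    if cfg["antecedent"] is not None:
        _relocate(pose, cfg["antecedent"], target + 1.4 * u)
    d, a = cfg["donor"], cfg["acceptor"]
    return {"spec": cfg["spec"], "donor": list(d), "acceptor": list(a)}


def _plant_backbone_bonds(pose: Pose, shared: bool) -> List[dict]:
    """Bonds through backbone donors: 3 distinct acceptors, or one shared OE1."""
    out = []
    if shared:
        anchor = _pos(pose, ("A", 11, "OE1"))
        for k, donor_res in enumerate((36, 37, 38)):
            u = _unit((-0.2 - 0.3 * k, 1.0, 0.0))
            _relocate(pose, ("B", donor_res, "N"), anchor + _HB_DIST * u)
            out.append(
                {
                    "spec": f"A:GLU:11-B:{_AA3[RECEPTOR_SEQ[donor_res - RECEPTOR_START]]}:{donor_res}",
                    "donor": ["B", donor_res, "N"],
                    "acceptor": ["A", 11, "OE1"],
                }
            )
    else:
        for k, (donor_res, acc_res) in enumerate(((36, 11), (37, 12), (38, 13))):
            anchor = _pos(pose, ("A", acc_res, "O"))
            target = anchor + _HB_DIST * np.array([0.0, 1.0, 0.0])
            _relocate(pose, ("B", donor_res, "N"), target)
            out.append(
                {
                    "spec": f"A:*:{acc_res}-B:*:{donor_res}",
                    "donor": ["B", donor_res, "N"],
                    "acceptor": ["A", acc_res, "O"],
                }
            )
    return out


_CONTACT_DIST = 3.7
_CB_POOL = [r for r in range(30, 46) if not 35 <= r <= 38]


def _plant_contacts(pose: Pose, planted: Dict[int, int]) -> Dict[int, int]:
    """Relocate inert receptor CB atoms within contact range of ligand residues.

    Each planted atom pairs with exactly one ligand atom (the backbone O of
    the target residue); carbons cannot hydrogen-bond, so contact-planted
    poses stay H-bond-free.
    """
    pool = iter(_CB_POOL)
    for res, k in sorted(planted.items()):
        anchor = _pos(pose, ("A", res, "O"))
        for j in range(k):
            try:
                donor_res = next(pool)
            except StopIteration:
                raise GenerationError(
                    f"too many planted contacts ({sum(planted.values())}); "
                    f"only {len(_CB_POOL)} inert receptor atoms available"
                ) from None
            u = _unit((0.2 * (j - (k - 1) / 2), 1.0, 0.25))
            _relocate(pose, ("B", donor_res, "CB"), anchor + _CONTACT_DIST * u)
    return dict(planted)


def _bond_key(bond) -> tuple:
    return (
        bond.donor.chain_id, bond.donor.residue_seq, bond.donor.atom_name,
        bond.acceptor.chain_id, bond.acceptor.residue_seq, bond.acceptor.atom_name,
    )


def gen_pose_ensemble(
    kinds: Sequence[str],
    seed: Optional[int] = None,
    orientations: Union[str, Sequence[str]] = "parallel",
    planted_contacts: Optional[Dict[int, int]] = None,
    jitter_sd: float = 0.0,
    criteria: HBondCriteria = HBondCriteria(),
    out_path: Optional[Union[str, Path]] = None,
) -> Tuple[PoseEnsemble, GroundTruth]:
    """Build a docking-style pose ensemble with exact planted interactions.

    ``kinds`` gives one recipe per pose:

    - ``pass`` — three His–Glu hydrogen bonds through six distinct side-chain
      atoms (satisfies the 3-bond/3-atom selection filter);
    - ``two_bonds`` / ``one_bond`` — fewer bonds than the filter requires;
    - ``backbone_only`` — three bonds through backbone atoms only (0 distinct
      side-chain atoms);
    - ``shared_atom`` — three bonds all sharing one side-chain acceptor
      (1 distinct side-chain atom, the bifurcated failure case);
    - ``detached`` — all inter-chain atom pairs > 6 Å apart;
    - ``contacts`` — atomic contacts planted at the residues given by
      ``planted_contacts`` (default 11–14), hydrogen-bond free.

    Ground truth records, per pose, the planted bond set, the expected filter
    verdict, the orientation and planted contact counts; generation fails if
    the detectors do not reproduce it exactly.
    """
    rng = np.random.default_rng(seed)
    if isinstance(orientations, str):
        orientations = [orientations] * len(kinds)
    if len(orientations) != len(kinds):
        raise ValueError("orientations must match kinds length")
    if planted_contacts is None:
        planted_contacts = {11: 3, 12: 2, 13: 3, 14: 2}

    poses: List[Pose] = []
    per_pose_truth: List[dict] = []
    for i, (kind, orient) in enumerate(zip(kinds, orientations)):
        pose = _base_pose(model_id=i + 1, orientation=orient)
        bonds: List[dict] = []
        contacts: Dict[int, int] = {}
        if kind == "pass":
            bonds = [_plant_bond(pose, b) for b in ("b1", "b2", "b3")]
        elif kind == "two_bonds":
            bonds = [_plant_bond(pose, b) for b in ("b1", "b2")]
        elif kind == "one_bond":
            bonds = [_plant_bond(pose, "b1")]
        elif kind == "backbone_only":
            bonds = _plant_backbone_bonds(pose, shared=False)
        elif kind == "shared_atom":
            bonds = _plant_backbone_bonds(pose, shared=True)
        elif kind == "contacts":
            contacts = _plant_contacts(pose, planted_contacts)
        elif kind != "detached":
            raise ValueError(f"unknown pose kind {kind!r}; choose from {POSE_KINDS}")
        if jitter_sd > 0:
            pose.atoms = [
                a.moved_to(a.xyz + rng.normal(0.0, jitter_sd, 3)) for a in pose.atoms
            ]
        sidechain_atoms = set()
        for b in bonds:
            for key in ("donor", "acceptor"):
                if b[key][2] not in ("N", "CA", "C", "O"):
                    sidechain_atoms.add(tuple(b[key]))
        expected_pass = len(bonds) >= 3 and len(sidechain_atoms) >= 3
        per_pose_truth.append(
            {
                "pose_id": i + 1,
                "kind": kind,
                "orientation": orient,
                "planted_bonds": bonds,
                "expected_pass": expected_pass,
                "n_distinct_sidechain_atoms": len(sidechain_atoms),
                "planted_contacts": contacts,
            }
        )
        poses.append(pose)

    ensemble = PoseEnsemble(poses=poses, ligand_chain="A", receptor_chain="B",
                            source=str(out_path or "<synthetic>"))
    _validate_ensemble(ensemble, per_pose_truth, criteria)
    truth = GroundTruth(
        {
            "kind": "pose_ensemble",
            "seed": seed,
            "jitter_sd": jitter_sd,
            "site_a": str(SITE_EVHH),
            "site_b": str(SITE_HAEE),
            "poses": per_pose_truth,
            "n_expected_pass": sum(p["expected_pass"] for p in per_pose_truth),
        }
    )
    if out_path is not None:
        write_ensemble(ensemble, out_path)
        truth.save(out_path)
    return ensemble, truth


def _validate_ensemble(
    ensemble: PoseEnsemble, per_pose_truth: List[dict], criteria: HBondCriteria
) -> None:
    for pose, truth in zip(ensemble, per_pose_truth):
        detected = detect_hbonds(pose, SITE_EVHH, SITE_HAEE, criteria)
        got = {_bond_key(b) for b in detected}
        want = {tuple(b["donor"]) + tuple(b["acceptor"]) for b in truth["planted_bonds"]}
        if got != want:
            raise GenerationError(
                f"pose {truth['pose_id']} ({truth['kind']}): detected bonds "
                f"{sorted(got)} != planted {sorted(want)} (jitter too large or "
                "geometry infeasible)"
            )
        orient = classify_orientation(pose, SITE_EVHH, SITE_HAEE)
        if orient != truth["orientation"]:
            raise GenerationError(
                f"pose {truth['pose_id']}: orientation {orient} != planned "
                f"{truth['orientation']}"
            )
        if truth["planted_contacts"]:
            prof = contact_profile(
                PoseEnsemble([pose], "A", "B"), profiled_chain="A", partner_chain="B"
            )
            counts = dict(zip(prof.axis, prof.counts))
            for res in prof.axis:
                expected = truth["planted_contacts"].get(res, 0)
                if counts[res] != expected:
                    raise GenerationError(
                        f"pose {truth['pose_id']}: residue {res} has {counts[res]} "
                        f"contacts, planted {expected}"
                    )


def _plant_site_contacts(pose: Pose, residues: Sequence[int]) -> None:
    """Put site–site atomic contacts on given ligand residues (11–14).

    Uses the inert CB carbons of the receptor site residues 35–38 (ligand
    residue r pairs with receptor residue r+24), so contact registers between
    the two sites without creating hydrogen bonds.
    """
    for r in residues:
        anchor = _pos(pose, ("A", r, "O"))
        u = _unit((0.0, 1.0, 0.25))
        _relocate(pose, ("B", r + 24, "CB"), anchor + _CONTACT_DIST * u)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(
    bond_schedule: Dict[str, Sequence[bool]],
    jitter_sd: float = 0.05,
    seed: Optional[int] = None,
    out_path: Optional[Union[str, Path]] = None,
) -> Tuple[PoseEnsemble, GroundTruth]:
    """Trajectory frames realizing a boolean per-bond schedule.

    ``bond_schedule`` maps planted-bond names (``b1``, ``b2``, ``b3`` — the
    three His–Glu interface bonds) to equal-length boolean arrays; in "on"
    frames the bond sits at 2.9 Å donor–acceptor distance, in "off" frames
    the mobile atom is displaced 8 Å away.  Gaussian coordinate jitter of
    ``jitter_sd`` Å is added everywhere; generation fails if the jitter
    breaks the schedule (self-check against the H-bond detector).
    """
    names = list(bond_schedule)
    unknown = set(names) - set(_PLANTED_BONDS)
    if unknown:
        raise ValueError(f"unknown bond names {sorted(unknown)}; available: b1, b2, b3")
    lengths = {len(v) for v in bond_schedule.values()}
    if len(lengths) != 1:
        raise ValueError("all schedules must have equal length")
    n_frames = lengths.pop()
    if n_frames < 1:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(seed)
    frames: List[Pose] = []
    for f in range(n_frames):
        pose = _base_pose(model_id=f + 1, orientation="parallel")
        for name in names:
            cfg = _PLANTED_BONDS[name]
            anchor = _pos(pose, cfg["anchor"])
            u = _unit(cfg["direction"])
            target = anchor + _HB_DIST * u
            if not bond_schedule[name][f]:
                target = target + np.array([0.0, 8.0 * np.sign(u[1] or 1.0), 0.0])
            _relocate(pose, cfg["moved"], target)
            if cfg["antecedent"] is not None:
                _relocate(pose, cfg["antecedent"], target + 1.4 * u)
        if jitter_sd > 0:
            pose.atoms = [
                a.moved_to(a.xyz + rng.normal(0.0, jitter_sd, 3)) for a in pose.atoms
            ]
        frames.append(pose)
    ensemble = PoseEnsemble(frames, "A", "B", source=str(out_path or "<synthetic>"))

    specs = [BondSpec.parse(_PLANTED_BONDS[n]["spec"]) for n in names]
    timeline = bond_timeline(ensemble, specs)
    expected = np.array([list(map(bool, bond_schedule[n])) for n in names])
    if not np.array_equal(timeline.presence, expected):
        raise GenerationError(
            "realized bond timeline deviates from the schedule "
            f"(jitter_sd={jitter_sd} too large?)"
        )
    truth = GroundTruth(
        {
            "kind": "trajectory",
            "seed": seed,
            "jitter_sd": jitter_sd,
            "n_frames": n_frames,
            "bonds": {
                n: {
                    "spec": _PLANTED_BONDS[n]["spec"],
                    "schedule": [bool(v) for v in bond_schedule[n]],
                    "persistence": float(np.mean(bond_schedule[n])),
                }
                for n in names
            },
        }
    )
    if out_path is not None:
        write_ensemble(ensemble, out_path)
        truth.save(out_path)
    return ensemble, truth


def gen_rebind_trajectory(
    n_frames: int,
    gaps: Sequence[Tuple[int, int, Sequence[int]]],
    initial_residues: Sequence[int] = (13,),
    jitter_sd: float = 0.02,
    seed: Optional[int] = None,
    out_path: Optional[Union[str, Path]] = None,
) -> Tuple[PoseEnsemble, GroundTruth]:
    """Trajectory with scheduled detachment/rebinding of the ligand site.

    ``gaps`` lists (start_frame, length, regained_window_residues) with
    0-based start frames; outside the gaps the receptor contacts the ligand
    site, and after each gap the contact is regained through the given EVHH
    residues (the participating residues of that rebinding event).  Frame 0
    must be a contact frame.  Ground truth records the event boundaries and
    per-residue participation fractions; generation self-checks against the
    event detector.
    """
    gaps = sorted(gaps, key=lambda g: g[0])
    contact = np.ones(n_frames, dtype=bool)
    for start, length, residues in gaps:
        if start < 1 or length < 1 or start + length > n_frames:
            raise GenerationError(
                f"gap ({start}, {length}) must fit in (1, {n_frames}) with frame 0 in contact"
            )
        if not set(residues) <= {11, 12, 13, 14}:
            raise GenerationError(f"window residues {residues} outside the tracked site 11–14")
        contact[start : start + length] = False
    # residues active during each contact run: initial run, then per-gap windows
    window_residues = [tuple(sorted(initial_residues))]
    for _, _, residues in gaps:
        window_residues.append(tuple(sorted(residues)))

    rng = np.random.default_rng(seed)
    frames: List[Pose] = []
    run_idx = 0
    for f in range(n_frames):
        if f > 0 and contact[f] and not contact[f - 1]:
            run_idx += 1
        pose = _base_pose(model_id=f + 1, orientation="parallel")
        if contact[f]:
            residues = window_residues[min(run_idx, len(window_residues) - 1)]
            _plant_site_contacts(pose, residues)
        if jitter_sd > 0:
            pose.atoms = [
                a.moved_to(a.xyz + rng.normal(0.0, jitter_sd, 3)) for a in pose.atoms
            ]
        frames.append(pose)
    ensemble = PoseEnsemble(frames, "A", "B", source=str(out_path or "<synthetic>"))

    expected_events = []
    for (start, length, _), residues in zip(gaps, window_residues[1:]):
        if start + length < n_frames:  # regained contact exists
            expected_events.append(
                {
                    "start_frame": start + 1,
                    "end_frame": start + length + 1,
                    "residues": list(residues),
                }
            )
    n_ev = len(expected_events)
    participation = {
        r: (round(sum(1 for e in expected_events if r in e["residues"]) / n_ev, 3)
            if n_ev else None)
        for r in (11, 12, 13, 14)
    }

    events, got_part = rebinding_events(ensemble, SITE_EVHH, SITE_HAEE, gap_min=1)
    got = [
        {"start_frame": e.start_frame, "end_frame": e.end_frame, "residues": list(e.residues)}
        for e in events
    ]
    if got != expected_events or got_part != participation:
        raise GenerationError(
            f"realized rebinding events {got} / participation {got_part} deviate "
            f"from schedule {expected_events} / {participation}"
        )
    truth = GroundTruth(
        {
            "kind": "rebind_trajectory",
            "seed": seed,
            "n_frames": n_frames,
            "contact_timeline": [bool(v) for v in contact],
            "events": expected_events,
            "participation": {str(r): p for r, p in participation.items()},
            "min_gap_len": min((g[1] for g in gaps), default=0),
        }
    )
    if out_path is not None:
        write_ensemble(ensemble, out_path)
        truth.save(out_path)
    return ensemble, truth


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

def gen_sensorgrams(
    k_on: float = 0.37,
    k_off: float = 4e-5,
    rmax: float = 1000.0,
    concentrations: Sequence[float] = sprkin.PAPER_CONCENTRATIONS_M,
    t_assoc: float = sprkin.DEFAULT_T_ASSOC,
    t_total: float = sprkin.DEFAULT_T_TOTAL,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    out_path: Optional[Union[str, Path]] = None,
):
    """Simulated SPR sensorgrams plus ground-truth sidecar (see sprkin).

    Defaults reproduce the study conditions: the 0–2000 µM analyte dilution
    series, a 300 s association phase and 120 s dissociation phase.
    """
    sensorgrams = sprkin.simulate_sensorgram(
        k_on, k_off, rmax, concentrations, t_assoc, t_total, dt, noise_sd, seed
    )
    truth = GroundTruth(
        {
            "kind": "sensorgrams",
            "seed": seed,
            "k_on": k_on,
            "k_off": k_off,
            "rmax": rmax,
            "noise_sd": noise_sd,
            "t_assoc": t_assoc,
            "t_total": t_total,
            "dt": dt,
            "concentrations_M": list(concentrations),
        }
    )
    if out_path is not None:
        sprkin.sensorgrams_to_dataframe(sensorgrams).to_csv(out_path, index=False)
        truth.save(out_path)
    return sensorgrams, truth
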