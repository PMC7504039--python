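"""Interface stability over trajectory frames.

Trajectory frames arrive as a multi-model PDB with constant atom
composition.  For a set of residue-level bond specifications (e.g.
Glu11(A)↔His35(B)) this module builds a boolean presence matrix over frames,
computes per-bond persistence (fraction of frames present), issues
stable/broken verdicts, and detects detachment/rebinding events — runs of
total site–site contact absence followed by regained contact — together with
per-residue participation statistics over the regained-contact windows.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .contacts import DEFAULT_CONTACT_CUTOFF, atomic_contacts
from .hbonds import HBondCriteria, detect_hbonds
from .structio import Pose, PoseEnsemble, SiteSelection

__all__ = [
    "BondSpec",
    "BondTimeline",
    "RebindEvent",
    "bond_timeline",
    "persistence",
    "stability_verdict",
    "rebinding_events",
]


@dataclass(frozen=True)
class BondSpec:
    """A residue-level bond between two chains, e.g. 'A:GLU:11-B:HIS:35'."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    resname_a: Optional[str] = None
    resname_b: Optional[str] = None

    @classmethod
    def parse(cls, text: str) -> "BondSpec":
        try:
            left, right = text.split("-")
            ca, rna, ra = left.split(":")
            cb, rnb, rb = right.split(":")
            return cls(ca, int(ra), cb, int(rb), rna.upper() or None, rnb.upper() or None)
        except Exception as exc:
            raise ValueError(
                f"cannot parse bond spec {text!r}; expected 'A:GLU:11-B:HIS:35'"
            ) from exc

    def __str__(self) -> str:
        return (
            f"{self.chain_a}:{self.resname_a or '*'}:{self.residue_a}-"
            f"{self.chain_b}:{self.resname_b or '*'}:{self.residue_b}"
        )


@dataclass
class BondTimeline:
    """Presence matrix (bond × frame) computed under one fixed criteria set."""

    specs: List[BondSpec]
    frame_ids: List[int]
    presence: np.ndarray  # bool, shape (n_specs, n_frames)
    criteria: HBondCriteria
    times: Optional[List[float]] = None

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.specs), len(self.frame_ids)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.specs)} specs × {len(self.frame_ids)} frames"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("frame\t" + "\t".join(str(s) for s in self.specs) + "\n")
            for j, fid in enumerate(self.frame_ids):
                fh.write(
                    f"{fid}\t" + "\t".join(str(bool(v)) for v in self.presence[:, j]) + "\n"
                )


@dataclass(frozen=True)
class RebindEvent:
    """One detachment→rebinding event.

    ``start_frame`` is the first frame of the contact-absent run,
    ``end_frame`` the frame at which site–site contact is regained;
    ``residues`` are the tracked-site residues contacting the partner during
    the regained-contact window.
    """

    start_frame: int
    end_frame: int
    residues: Tuple[int, ...]

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ValueError("event start must precede contact regain")


def _single_residue_site(chain: str, residue: int) -> SiteSelection:
    return SiteSelection(chain, residue, residue)


def bond_timeline(
    frames: PoseEnsemble,
    bond_specs: Sequence[BondSpec],
    criteria: HBondCriteria = HBondCriteria(),
) -> BondTimeline:
    """Per-frame presence of each residue-level bond.

    A bond is present in a frame when at least one atomic hydrogen bond
    satisfying ``criteria`` exists between the two residues.  Requires
    constant atom composition across frames (trajectory contract).
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    frames.assert_constant_composition()
    specs = list(bond_specs)
    presence = np.zeros((len(specs), len(frames)), dtype=bool)
    for j, pose in enumerate(frames):
        for i, spec in enumerate(specs):
            bonds = detect_hbonds(
                pose,
                _single_residue_site(spec.chain_a, spec.residue_a),
                _single_residue_site(spec.chain_b, spec.residue_b),
                criteria,
            )
            presence[i, j] = bool(bonds)
    return BondTimeline(
        specs=specs,
        frame_ids=[p.model_id for p in frames],
        presence=presence,
        criteria=criteria,
    )


def persistence(timeline: BondTimeline) -> np.ndarray:
    """Fraction of frames each bond is present, in [0, 1]."""
    if timeline.n_frames < 1:
        raise ValueError("timeline has no frames")
    return timeline.presence.mean(axis=1)


def stability_verdict(
    timeline: BondTimeline,
    min_persistence: float = 0.9,
    require_final_window: int = 10,
) -> List[str]:
    """'stable' or 'broken' per bond.

    Stable means persistence ≥ ``min_persistence`` AND the bond is present in
    every frame of the final ``require_final_window`` frames (a bond that
    breaks at the end is broken regardless of its earlier occupancy).
    """
    if require_final_window > timeline.n_frames:
        raise ValueError("final window longer than the trajectory")
    fractions = persistence(timeline)
    out = []
    for i in range(len(timeline.specs)):
        final_ok = bool(timeline.presence[i, timeline.n_frames - require_final_window :].all())
        out.append("stable" if fractions[i] >= min_persistence and final_ok else "broken")
    return out


def _site_contact_state(
    pose: Pose,
    site_a: SiteSelection,
    site_b: SiteSelection,
    criteria: HBondCriteria,
    contact_cutoff: float,
    mode: str,
) -> Tuple[bool, set]:
    """(any site–site contact?, tracked-site residues involved)."""
    residues: set = set()
    bonds = detect_hbonds(pose, site_a, site_b, criteria)
    for b in bonds:
        for ref in (b.donor, b.acceptor):
            if ref.chain_id == site_a.chain_id and site_a.first <= ref.residue_seq <= site_a.last:
                residues.add(ref.residue_seq)
    if mode == "hbond_or_contact":
        atoms_a = [
            a
            for a in pose.atoms
            if a.chain_id == site_a.chain_id and site_a.first <= a.residue_seq <= site_a.last
        ]
        atoms_b = [
            a
            for a in pose.atoms
            if a.chain_id == site_b.chain_id and site_b.first <= a.residue_seq <= site_b.last
        ]
        for c in atomic_contacts(atoms_a, atoms_b, contact_cutoff):
            residues.add(c.atom_a.residue_seq)
    elif mode != "hbond_only":
        raise ValueError(f"unknown contact mode {mode!r}")
    return bool(residues), residues


def rebinding_events(
    frames: PoseEnsemble,
    site_a: SiteSelection,
    site_b: SiteSelection,
    criteria: HBondCriteria = HBondCriteria(),
    gap_min: int = 5,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: str = "hbond_or_contact",
) -> Tuple[List[RebindEvent], Dict[int, Optional[float]]]:
    """Detachment/rebinding events and per-residue participation fractions.

    Site–site "contact" in a frame means ≥1 hydrogen bond or (by default)
    ≥1 atomic contact at ``contact_cutoff`` between the two sites.  An event
    is a maximal run of ≥ ``gap_min`` contact-absent frames, preceded by at
    least one contact frame and followed by regained contact.  The tracked
    site is ``site_a``: the participation fraction of residue r is the share
    of events whose regained-contact window (the maximal contact run starting
    at the regain frame) involves r.  With zero events every fraction is
    None ('n/a').
    """
    if gap_min < 1:
        raise ValueError("gap_min must be ≥ 1")
    if len(frames) == 0:
        raise ValueError("no frames")
    frames.assert_constant_composition()
    states = [
        _site_contact_state(pose, site_a, site_b, criteria, contact_cutoff, mode)
        for pose in frames
    ]
    present = [s[0] for s in states]
    frame_ids = [p.model_id for p in frames]
    n = len(present)

    events: List[RebindEvent] = []
    i = 0
    seen_contact = False
    while i < n:
        if present[i]:
            seen_contact = True
            i += 1
            continue
        # absent run [i, j)
        j = i
        while j < n and not present[j]:
            j += 1
        if seen_contact and (j - i) >= gap_min and j < n:
            # regained-contact window: maximal present run starting at j
            k = j
            window_res: set = set()
            while k < n and present[k]:
                window_res |= states[k][1]
                k += 1
            events.append(
                RebindEvent(
                    start_frame=frame_ids[i],
                    end_frame=frame_ids[j],
                    residues=tuple(sorted(window_res)),
                )
            )
        i = j

    tracked_residues = sorted(
        {
            a.residue_seq
            for a in frames.poses[0].atoms
            if a.chain_id == site_a.chain_id and site_a.first <= a.residue_seq <= site_a.last
        }
    )
    participation: Dict[int, Optional[float]] = {}
    for r in tracked_residues:
        if not events:
            participation[r] = None
        else:
            participation[r] = round(
                sum(1 for e in events if r in e.residues) / len(events), 3
            )
    return events, participation


def events_to_json(
    events: Sequence[RebindEvent],
    participation: Dict[int, Optional[float]],
    path: Union[str, Path],
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_events": len(events),
                "events": [
                    {
                        "start_frame": e.start_frame,
                        "end_frame": e.end_frame,
                        "residues": list(e.residues),
                    }
                    for e in events
                ],
                "participation": {
                    str(r): ("n/a" if f is None else f) for r, f in participation.items()
                },
            },
            fh,
            indent=2,
        )
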