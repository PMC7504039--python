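"""Atomic contacts and per-residue contact profiles across a pose ensemble.

An atomic contact is a heavy-atom pair, one atom from each binding partner,
within a distance cutoff (default 4.0 Å, inclusive).  Summing contacts per
residue of one chain over every pose of a docking ensemble gives a contact
profile — the histogram used to locate the preferred binding site on a
peptide (e.g. the EVHH cluster on amyloid-β).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Pose, PoseEnsemble, is_heavy

__all__ = ["Contact", "ContactProfile", "atomic_contacts", "contact_profile", "top_site"]

DEFAULT_CONTACT_CUTOFF = 4.0  # Å, conventional heavy-atom contact threshold


@dataclass(frozen=True)
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float


@dataclass
class ContactProfile:
    """Per-residue contact counts of the profiled chain, summed over poses."""

    axis: List[int]            # 1-based residue positions, ascending
    counts: List[int]
    residue_names: List[str]
    chain_id: str
    cutoff: float
    n_poses: int

    def total(self) -> int:
        return int(sum(self.counts))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue": self.axis, "residue_name": self.residue_names, "count": self.counts}
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, highlight: Tuple[int, int] = None):
        """Bar plot of the profile; optionally highlight a residue interval."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        colors = [
            "crimson" if highlight and highlight[0] <= r <= highlight[1] else "steelblue"
            for r in self.axis
        ]
        ax.bar(self.axis, self.counts, color=colors)
        ax.set_xlabel(f"residue (chain {self.chain_id})")
        ax.set_ylabel("atomic contacts")
        ax.set_title(f"contacts ≤ {self.cutoff:g} Å over {self.n_poses} poses")
        return ax


def atomic_contacts(
    group_a: Sequence[Atom],
    group_b: Sequence[Atom],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_hydrogens: bool = False,
) -> List[Contact]:
    """All atom pairs (one per group) within ``cutoff`` Å (inclusive).

    Hydrogens are excluded by default; each qualifying pair is returned once.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not group_a or not group_b:
        raise ValueError("both atom groups must be non-empty")
    a = list(group_a) if include_hydrogens else [x for x in group_a if is_heavy(x)]
    b = list(group_b) if include_hydrogens else [x for x in group_b if is_heavy(x)]
    if not a or not b:
        return []
    xa = np.array([x.xyz for x in a])
    xb = np.array([x.xyz for x in b])
    tree = cKDTree(xb)
    out: List[Contact] = []
    for i, neighbours in enumerate(tree.query_ball_point(xa, r=cutoff)):
        for j in sorted(neighbours):
            d = float(np.linalg.norm(xa[i] - xb[j]))
            out.append(Contact(a[i], b[j], d))
    return out


def contact_profile(
    ensemble: PoseEnsemble,
    profiled_chain: str,
    partner_chain: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_hydrogens: bool = False,
) -> ContactProfile:
    """Per-residue contact counts of ``profiled_chain`` against ``partner_chain``.

    The axis covers every residue present in the profiled chain (union over
    poses); counts sum contact pairs over all poses, attributed to the
    profiled-chain residue of each pair.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    counts: dict = {}
    names: dict = {}
    for pose in ensemble:
        prof_atoms = pose.chain_atoms(profiled_chain)
        part_atoms = pose.chain_atoms(partner_chain)
        for a in prof_atoms:
            counts.setdefault(a.residue_seq, 0)
            names.setdefault(a.residue_seq, a.residue_name)
        for c in atomic_contacts(prof_atoms, part_atoms, cutoff, include_hydrogens):
            counts[c.atom_a.residue_seq] += 1
    axis = sorted(counts)
    return ContactProfile(
        axis=axis,
        counts=[counts[r] for r in axis],
        residue_names=[names[r] for r in axis],
        chain_id=profiled_chain,
        cutoff=cutoff,
        n_poses=len(ensemble),
    )


def top_site(profile: ContactProfile, window: int) -> Tuple[int, int]:
    """Contiguous window of residues with maximal summed counts.

    Ties break toward the smallest start (deterministic).  Returns the
    1-based inclusive residue interval.
    """
    n = len(profile.axis)
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    best_sum, best_start = -1, 0
    for i in range(n - window + 1):
        s = sum(profile.counts[i : i + window])
        if s > best_sum:
            best_sum, best_start = s, i
    return profile.axis[best_start], profile.axis[best_start + window - 1]
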