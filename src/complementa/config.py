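"""Run configuration: one YAML-serializable object exposing every default.

Every geometric threshold and filter setting that the analyses default to is
visible and overridable here, so a run re-executed from its saved config and
seed reproduces identical tabular outputs.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml

from .hbonds import HBondCriteria

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # site selections ("chain:first-last")
    site_a: str = "A:11-14"
    site_b: str = "B:35-38"
    # contacts
    contact_cutoff: float = 4.0
    include_hydrogens: bool = False
    # hydrogen-bond geometry
    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0
    min_heavy_angle: float = 90.0
    # model filter
    min_bonds: int = 3
    min_distinct_sidechain_atoms: int = 3
    count_side: str = "both"
    # orientation
    crosswise_threshold: float = 0.5
    # trajectory statistics
    gap_min: int = 5
    min_persistence: float = 0.9
    final_window: int = 10
    # SPR
    t_assoc: float = 300.0
    t_total: float = 420.0
    spr_noise_sd: float = 0.5
    spr_k_on: float = 0.37
    spr_k_off: float = 4e-5
    spr_rmax: float = 1000.0
    # run control
    seed: int = 1
    outdir: str = "complementa_out"

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(
            max_da_distance=self.max_da_distance,
            min_dha_angle=self.min_dha_angle,
            min_heavy_angle=self.min_heavy_angle,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        # typed validation: every field must match its declared scalar type
        for f in fields(cls):
            val = getattr(cfg, f.name)
            expected = {"float": (int, float), "int": (int,), "str": (str,), "bool": (bool,)}
            for tname, types in expected.items():
                if f.type == tname and not isinstance(val, types):
                    raise ValueError(
                        f"config key {f.name!r} must be {tname}, got {type(val).__name__}"
                    )
        return cfg
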