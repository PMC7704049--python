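"""Validated analysis configuration.

Every pipeline parameter has a default matching the protein-G-style
production settings; configurations load from YAML with strict key checking
so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # contact map / substructures
    d_c: float = 6.5  # A, substructure-map cutoff
    native_d_c: float = 6.0  # A, native-contact-count cutoff
    min_sep: int = 3  # substructure map
    native_min_sep: int = 8  # native-contact count
    c: int = 7  # minimum island size
    h: int = 5  # Manhattan hop radius
    f: float = 1.7  # formation factor
    # unfolding-rate pipeline
    s: float = 0.0  # rare-configuration reassignment threshold
    m: float = 0.1  # HMM misassignment probability
    T_A: float = 1e8  # kinetic-clustering threshold, MC steps
    dt: float = 5e5  # snapshot interval, MC steps
    min_events: int = 5  # Arrhenius minimum transition events per temperature
    bootstrap: int = 1000
    # equilibrium analysis
    burn_in: float = 0.125  # fraction of each trajectory discarded
    pmf_bootstrap: int = 200
    # assembly
    zero_transitions: List[Tuple[str, str]] = field(default_factory=list)
    condition_ii: List[Tuple[str, str]] = field(default_factory=list)
    # nonnative analysis
    relaxed_nonnative_clusters: List[str] = field(default_factory=list)
    nonnative_hamming: int = 10
    nonnative_min_freq: float = 0.10
    nonnative_T_window: Tuple[float, float] = (0.80, 0.90)  # in units of T_M
    # misc
    seed: int = 0
    target_T: Optional[float] = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        checks = [
            (self.d_c > 0, "d_c must be positive"),
            (self.native_d_c > 0, "native_d_c must be positive"),
            (self.min_sep >= 1, "min_sep must be >= 1"),
            (self.native_min_sep >= 1, "native_min_sep must be >= 1"),
            (self.c >= 1, "c must be >= 1"),
            (self.h >= 1, "h must be >= 1"),
            (self.f >= 1, "f must be >= 1"),
            (0 <= self.s < 1, "s must be in [0, 1)"),
            (0 <= self.m < 1, "m must be in [0, 1)"),
            (self.T_A > 0, "T_A must be positive"),
            (self.dt > 0, "dt must be positive"),
            (self.min_events >= 1, "min_events must be >= 1"),
            (self.bootstrap >= 1, "bootstrap must be >= 1"),
            (0 <= self.burn_in < 1, "burn_in must be in [0, 1)"),
            (self.nonnative_hamming >= 1, "nonnative_hamming must be >= 1"),
            (0 <= self.nonnative_min_freq <= 1, "nonnative_min_freq must be in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        self.zero_transitions = [tuple(p) for p in self.zero_transitions]
        self.condition_ii = [tuple(p) for p in self.condition_ii]
        self.nonnative_T_window = tuple(self.nonnative_T_window)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
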