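"""Run configuration: validated defaults reproducing the published settings.

Defaults: BLOSUM62-derived alignment scores with affine gaps (open 10,
extend 0.5), consensus thresholds upper 0.5 / lower 0.25 / column occupancy
0.5, consensus truncation at 440, footprint cutoff 6.0 Å with inclusive
boundary, site-specific PTM-ablation rule.  Config files are INI-style
``key = value`` pairs (a single ``[tubnum]`` section or no section header).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, fields
from pathlib import Path

from .consensus import MAX_CORE_LENGTH
from .numbering import AlignmentParams
from .ptm import ABLATION_RULES

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    upper_threshold: float = 0.5
    lower_threshold: float = 0.25
    occupancy_threshold: float = 0.5
    max_len: int = MAX_CORE_LENGTH
    footprint_cutoff: float = 6.0
    boundary: str = "inclusive"
    ablation_rule: str = "site-specific"
    assign_margin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be positive")
        if not (self.upper_threshold > self.lower_threshold > 0):
            raise ValueError("need upper_threshold > lower_threshold > 0")
        if not (0 < self.occupancy_threshold <= 1):
            raise ValueError("occupancy_threshold must be in (0, 1]")
        if self.max_len < 1:
            raise ValueError("max_len must be positive")
        if self.footprint_cutoff <= 0:
            raise ValueError("footprint_cutoff must be positive")
        if self.boundary not in ("inclusive", "exclusive"):
            raise ValueError(f"boundary must be inclusive|exclusive, got {self.boundary!r}")
        if self.ablation_rule not in ABLATION_RULES:
            raise ValueError(f"ablation_rule must be one of {ABLATION_RULES}")

    @property
    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(self.matrix, self.gap_open, self.gap_extend)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an INI-style file plus overrides."""
    values: dict = {}
    if path is not None:
        parser = configparser.ConfigParser()
        text = Path(path).read_text()
        if not text.lstrip().startswith("["):
            text = "[tubnum]\n" + text
        parser.read_string(text)
        section = parser["tubnum"] if parser.has_section("tubnum") else parser[parser.sections()[0]]
        field_types = {f.name: f.type for f in fields(RunConfig)}
        for key, raw in section.items():
            if key not in field_types:
                raise ValueError(f"unknown config key {key!r}")
            ftype = field_types[key]
            if ftype in ("int",):
                values[key] = int(raw)
            elif ftype in ("float",):
                values[key] = float(raw)
            else:
                values[key] = raw
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
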