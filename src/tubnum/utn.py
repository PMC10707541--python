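"""Universal tubulin numbering (UTN) labels.

A UTN label identifies a residue relative to a family consensus sequence:
either a *core* position (an integer column index, 1..440 for the packaged
consensus profiles) or an *insertion* relative to the consensus.  Insertions
are written ``<anchor>i<ordinal>/<run_length>``: the residue follows core
position ``anchor`` and is member ``ordinal`` of an inserted run of
``run_length`` residues.  A single residue inserted after core position 40 is
therefore ``40i1/1``; a three-residue insert after 112 reads ``112i1/3``,
``112i2/3``, ``112i3/3``.  Insertions never shift the numbering of downstream
core positions.  ``anchor == 0`` denotes residues before core position 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["UTNLabel", "core_label", "insertion_label", "format_label", "parse_label"]

_INSERTION_RE = re.compile(r"^(\d+)i(\d+)/(\d+)$")
_CORE_RE = re.compile(r"^(\d+)$")


@dataclass(frozen=True, order=True)
class UTNLabel:
    """A universal tubulin numbering label.

    ``kind`` is ``"core"`` or ``"insertion"``.  For a core label only
    ``core_index`` is set (1-based consensus column).  For an insertion,
    ``core_index`` is the anchor (the last core position preceding the run;
    0 for an N-terminal overhang), and ``ordinal``/``run_length`` place the
    residue within the inserted run.
    """

    core_index: int
    ordinal: int = 0
    run_length: int = 0

    def __post_init__(self) -> None:
        if self.core_index < 0:
            raise ValueError(f"negative UTN index: {self.core_index}")
        if self.is_insertion:
            if not (1 <= self.ordinal <= self.run_length):
                raise ValueError(
                    f"insertion ordinal {self.ordinal} outside run 1..{self.run_length}"
                )
        elif self.ordinal or self.run_length:
            raise ValueError("core labels carry no ordinal/run_length")

    @property
    def kind(self) -> str:
        return "insertion" if self.run_length else "core"

    @property
    def is_insertion(self) -> bool:
        return self.run_length > 0

    @property
    def anchor(self) -> int:
        """Anchor core position of an insertion (== core_index)."""
        return self.core_index

    def __str__(self) -> str:
        return format_label(self)


def core_label(index: int) -> UTNLabel:
    if index < 1:
        raise ValueError(f"core UTN index must be >= 1, got {index}")
    return UTNLabel(index)


def insertion_label(anchor: int, ordinal: int, run_length: int) -> UTNLabel:
    return UTNLabel(anchor, ordinal, run_length)


def format_label(label: UTNLabel) -> str:
    """Render a label in the ``"41"`` / ``"40i1/1"`` notation."""
    if label.is_insertion:
        return f"{label.core_index}i{label.ordinal}/{label.run_length}"
    return str(label.core_index)


def parse_label(text: str) -> UTNLabel:
    """Parse ``"41"`` or ``"40i1/1"`` back into a :class:`UTNLabel`."""
    text = text.strip()
    m = _CORE_RE.match(text)
    if m:
        return core_label(int(m.group(1)))
    m = _INSERTION_RE.match(text)
    if m:
        return insertion_label(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    raise ValueError(f"not a UTN label: {text!r}")
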