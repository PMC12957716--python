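"""Canonical hippocampal-subfield labels.

The analysis operates on 38 regions: 19 anatomical subfield segments per
hemisphere, as produced by atlas-based hippocampal segmentation.  Seven
structures are split into head and body segments (CA1, CA3, CA4, dentate
gyrus, molecular layer, presubiculum, subiculum); five are kept whole
(parasubiculum, fimbria, HATA, hippocampal tail, hippocampal fissure).

Every table and matrix in this package uses :data:`CANONICAL_ROSTER` as its
row/column order, so the roster is the single source of truth for node
identity and ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Structure(str, Enum):
    """Anatomical subfield structure."""

    CA1 = "ca1"
    CA3 = "ca3"
    CA4 = "ca4"
    DENTATE_GYRUS = "dentate_gyrus"
    HATA = "hata"
    HIPPOCAMPAL_TAIL = "hippocampal_tail"
    FIMBRIA = "fimbria"
    HIPPOCAMPAL_FISSURE = "hippocampal_fissure"
    MOLECULAR_LAYER = "molecular_layer"
    PARASUBICULUM = "parasubiculum"
    PRESUBICULUM = "presubiculum"
    SUBICULUM = "subiculum"


class Part(str, Enum):
    HEAD = "head"
    BODY = "body"
    WHOLE = "whole"


class Hemisphere(str, Enum):
    LEFT = "L"
    RIGHT = "R"


#: Structures segmented into separate head and body regions.
SPLIT_STRUCTURES = frozenset(
    {
        Structure.CA1,
        Structure.CA3,
        Structure.CA4,
        Structure.DENTATE_GYRUS,
        Structure.MOLECULAR_LAYER,
        Structure.PRESUBICULUM,
        Structure.SUBICULUM,
    }
)

_DISPLAY = {
    Structure.CA1: "CA1",
    Structure.CA3: "CA3",
    Structure.CA4: "CA4",
    Structure.DENTATE_GYRUS: "Dentate gyrus",
    Structure.HATA: "HATA",
    Structure.HIPPOCAMPAL_TAIL: "Hippocampal tail",
    Structure.FIMBRIA: "Fimbria",
    Structure.HIPPOCAMPAL_FISSURE: "Hippocampal fissure",
    Structure.MOLECULAR_LAYER: "Molecular layer",
    Structure.PARASUBICULUM: "Parasubiculum",
    Structure.PRESUBICULUM: "Presubiculum",
    Structure.SUBICULUM: "Subiculum",
}
_DISPLAY_INV = {v: k for k, v in _DISPLAY.items()}


@dataclass(frozen=True, order=True)
class SubfieldLabel:
    """Identity of one subfield region: structure x head/body x hemisphere."""

    structure: Structure
    part: Part
    hemisphere: Hemisphere

    def __post_init__(self) -> None:
        if self.structure in SPLIT_STRUCTURES:
            if self.part is Part.WHOLE:
                raise ValueError(
                    f"{self.structure.value} is segmented into head/body; "
                    "part 'whole' is invalid"
                )
        elif self.part is not Part.WHOLE:
            raise ValueError(
                f"{self.structure.value} has no head/body split; "
                f"part {self.part.value!r} is invalid"
            )

    def render(self) -> str:
        """Unique human-readable name, e.g. ``"CA1 head L"`` or ``"HATA R"``."""
        base = _DISPLAY[self.structure]
        if self.part is not Part.WHOLE:
            base = f"{base} {self.part.value}"
        return f"{base} {self.hemisphere.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "SubfieldLabel":
        """Inverse of :meth:`render`; raises ``ValueError`` on unknown labels."""
        tokens = text.strip().rsplit(" ", 1)
        if len(tokens) != 2 or tokens[1] not in ("L", "R"):
            raise ValueError(f"cannot parse subfield label {text!r}")
        body, hemi = tokens
        part = Part.WHOLE
        for p in (Part.HEAD, Part.BODY):
            suffix = f" {p.value}"
            if body.endswith(suffix):
                part = p
                body = body[: -len(suffix)]
                break
        structure = _DISPLAY_INV.get(body)
        if structure is None:
            raise ValueError(f"unknown subfield structure in label {text!r}")
        return cls(structure, part, Hemisphere(hemi))


def _build_roster() -> tuple[SubfieldLabel, ...]:
    order = [
        Structure.CA1,
        Structure.CA3,
        Structure.CA4,
        Structure.DENTATE_GYRUS,
        Structure.HATA,
        Structure.HIPPOCAMPAL_TAIL,
        Structure.FIMBRIA,
        Structure.HIPPOCAMPAL_FISSURE,
        Structure.MOLECULAR_LAYER,
        Structure.PARASUBICULUM,
        Structure.PRESUBICULUM,
        Structure.SUBICULUM,
    ]
    roster: list[SubfieldLabel] = []
    for structure in order:
        parts = (Part.BODY, Part.HEAD) if structure in SPLIT_STRUCTURES else (Part.WHOLE,)
        for part in parts:
            for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
                roster.append(SubfieldLabel(structure, part, hemi))
    return tuple(roster)


#: The 38 canonical subfield regions, fixing row/column order everywhere.
CANONICAL_ROSTER: tuple[SubfieldLabel, ...] = _build_roster()

#: Rendered names in canonical order (CSV headers, matrix labels).
CANONICAL_NAMES: tuple[str, ...] = tuple(lbl.render() for lbl in CANONICAL_ROSTER)

N_SUBFIELDS = len(CANONICAL_ROSTER)

LEFT_INDICES: tuple[int, ...] = tuple(
    i for i, lbl in enumerate(CANONICAL_ROSTER) if lbl.hemisphere is Hemisphere.LEFT
)
RIGHT_INDICES: tuple[int, ...] = tuple(
    i for i, lbl in enumerate(CANONICAL_ROSTER) if lbl.hemisphere is Hemisphere.RIGHT
)


def roster_index(label: SubfieldLabel | str) -> int:
    """Position of a label (object or rendered name) in the canonical roster."""
    if isinstance(label, str):
        label = SubfieldLabel.parse(label)
    return CANONICAL_ROSTER.index(label)
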