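"""Diagnosis labels for cervical dysplasia grading.

Slides are graded on the ordered two-tier scale NNeo < LSIL < HSIL
(non-neoplastic, low- and high-grade squamous intraepithelial lesion).
Non-representative slides -- those containing no exocervical squamous
epithelium -- carry the unordered sentinel label OTHERS and never enter
ordinal computations.
"""

from __future__ import annotations

import enum


class OrdinalLabel(enum.IntEnum):
    """Ordered dysplasia grade; the integer value is the ordinal rank."""

    NNEO = 1
    LSIL = 2
    HSIL = 3

    @property
    def short_name(self) -> str:
        return _SHORT[self]

    @classmethod
    def from_name(cls, name: str) -> "OrdinalLabel":
        key = name.strip().lower()
        try:
            return _FROM_NAME[key]
        except KeyError:
            raise ValueError(f"unknown ordinal label {name!r}") from None


#: Sentinel for non-representative slides (no epithelium, not on the scale).
OTHERS = "others"

#: Sentinel for annotation regions explicitly excluded from training.
UNCERTAIN = "uncertain"

ORDERED_CLASSES = (OrdinalLabel.NNEO, OrdinalLabel.LSIL, OrdinalLabel.HSIL)
CLASS_NAMES = ("NNeo", "LSIL", "HSIL")
ALL_CLASS_NAMES = CLASS_NAMES + (OTHERS,)

_SHORT = {
    OrdinalLabel.NNEO: "NNeo",
    OrdinalLabel.LSIL: "LSIL",
    OrdinalLabel.HSIL: "HSIL",
}
_FROM_NAME = {
    "nneo": OrdinalLabel.NNEO,
    "non-neoplastic": OrdinalLabel.NNEO,
    "lsil": OrdinalLabel.LSIL,
    "hsil": OrdinalLabel.HSIL,
}


def parse_label(name: str):
    """Parse a manifest label into an OrdinalLabel or the OTHERS sentinel."""
    if name.strip().lower() == OTHERS:
        return OTHERS
    return OrdinalLabel.from_name(name)


def label_name(label) -> str:
    """Canonical string for an OrdinalLabel or the OTHERS sentinel."""
    if label == OTHERS:
        return OTHERS
    return OrdinalLabel(label).short_name
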