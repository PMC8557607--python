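"""Fixed nine-class tissue taxonomy for colorectal IHC slides.

The class↔index mapping below is frozen: every label image, classifier
probability vector and serialized artifact in this package orders classes
by these indices. Changing the order would silently corrupt saved models
and masks, so treat it as part of the on-disk format.
"""

from __future__ import annotations

from enum import IntEnum


class TileClass(IntEnum):
    """One of the nine colorectal tissue types distinguished on a slide."""

    TUMOR_EPITHELIUM = 0
    STROMA = 1
    ADIPOSE = 2
    BACKGROUND = 3
    DEBRIS = 4
    LYMPHOCYTES = 5
    MUCUS = 6
    MUSCLE = 7
    NORMAL_MUCOSA = 8

    @classmethod
    def from_name(cls, name: str) -> "TileClass":
        key = name.strip().lower()
        try:
            return cls[key.upper()]
        except KeyError:
            valid = ", ".join(c.name.lower() for c in cls)
            raise ValueError(f"unknown tissue class {name!r}; valid classes: {valid}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


#: Class names in index order; the canonical column/row order for confusion
#: matrices and probability vectors.
CLASS_NAMES: tuple[str, ...] = tuple(c.label for c in TileClass)

N_CLASSES = len(CLASS_NAMES)
assert N_CLASSES == 9
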