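"""Tissue-class vocabulary shared by every pipeline stage.

A label map is a plain ``numpy`` integer array whose values are members of
:class:`TissueClass` or the reserved :data:`BACKGROUND` label.  BACKGROUND
marks non-tissue pixels (glass, padding); it is never counted as tissue in
Dice evaluation or PTS scoring.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "TissueClass",
    "BACKGROUND",
    "FOREGROUND_CLASSES",
    "N_CLASSES",
    "CLASS_NAMES",
    "validate_labelmap",
]


class TissueClass(IntEnum):
    """The seven foreground tissue classes of colorectal H&E histology."""

    TUMOR = 1        # colon cancer epithelium
    STROMA = 2
    LYMPHOCYTES = 3
    MUCUS = 4
    ADIPOSE = 5
    MUSCLE = 6       # smooth muscle
    NORMAL = 7       # normal colon mucosa


#: Reserved non-tissue label, excluded from Dice evaluation and PTS scoring.
BACKGROUND: int = 0

FOREGROUND_CLASSES: tuple[TissueClass, ...] = tuple(TissueClass)
N_CLASSES: int = len(FOREGROUND_CLASSES)

CLASS_NAMES: dict[int, str] = {int(c): c.name.lower() for c in TissueClass}
CLASS_NAMES[BACKGROUND] = "background"

_VALID_LABELS = frozenset({BACKGROUND} | {int(c) for c in TissueClass})


def validate_labelmap(labels: np.ndarray) -> np.ndarray:
    """Check that ``labels`` is a 2-D integer array over the label set.

    Returns the array unchanged so the call can be used inline.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"label map must be integer-typed, got {labels.dtype}")
    present = set(np.unique(labels).tolist())
    bad = present - _VALID_LABELS
    if bad:
        raise ValueError(f"label map contains values outside the label set: {sorted(bad)}")
    return labels
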