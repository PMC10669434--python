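"""Multi-hot disease labels for OCT B-scans.

Four classes: age-related macular degeneration (AMD), epiretinal membrane
(ERM), macular edema (ME), and Normal.  An image may carry several diseases
at once; by dataset-construction convention Normal is set exactly when no
disease is present.  The classifier nevertheless predicts all four outputs
independently through sigmoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLASS_NAMES = ("amd", "erm", "me", "normal")
NUM_CLASSES = len(CLASS_NAMES)


@dataclass(frozen=True)
class MultiHotLabel:
    amd: int = 0
    erm: int = 0
    me: int = 0
    normal: int = 0

    def __post_init__(self) -> None:
        for name in CLASS_NAMES:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"label field {name} must be 0 or 1")
        diseased = self.amd or self.erm or self.me
        if bool(self.normal) == bool(diseased):
            raise ValueError("normal must be 1 exactly when no disease is present")

    @classmethod
    def from_diseases(cls, amd: int = 0, erm: int = 0, me: int = 0) -> "MultiHotLabel":
        normal = int(not (amd or erm or me))
        return cls(amd=int(amd), erm=int(erm), me=int(me), normal=normal)

    def as_array(self) -> np.ndarray:
        return np.array([self.amd, self.erm, self.me, self.normal], dtype=np.int64)


def labels_to_array(labels) -> np.ndarray:
    """Stack MultiHotLabels (or raw 4-vectors) into an (N, 4) int array."""
    rows = [lab.as_array() if isinstance(lab, MultiHotLabel) else np.asarray(lab, dtype=np.int64)
            for lab in labels]
    out = np.stack(rows)
    if out.ndim != 2 or out.shape[1] != NUM_CLASSES:
        raise ValueError(f"expected (N, {NUM_CLASSES}) labels")
    return out
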