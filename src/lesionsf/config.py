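"""Pipeline configuration shared across modules.

All knobs of the analysis live here with their defaults; the object
serializes losslessly to and from JSON so that a run can be reproduced
from its config file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # asymmetry sampling
    n_lines: int = 45                 # splitting lines over 180 degrees
    # segmentation
    smooth_radius: int = 5            # disk radius for opening/closing, px
    min_area: int = 500               # smallest acceptable lesion, px
    contour_sigma: float = 1.5        # Gaussian smoothing before marching squares, px
    # hair removal
    hair_removal_enabled: bool = True
    hair_strel_length: int = 15       # linear structuring element length, px
    # size-function comparison
    cornerline_penalty: float = 2.0   # distance cap when component counts differ
    min_persistence: float = 0.005    # prune cornerpoints below this (normalized units)
    # classifier
    svm_c: float = 1.0
    svm_gamma: float = 1.0 / 69.0
    svm_coef0: float = 1.0
    svm_degree: int = 3
    target_sensitivity: float = 0.95
    target_specificity: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 4:
            raise ValueError("n_lines must be >= 4")
        if self.hair_strel_length < 3:
            raise ValueError("hair_strel_length must be >= 3")
        if self.svm_degree != 3:
            raise ValueError("classifier kernel degree is fixed at 3")
        if not (0 < self.target_sensitivity <= 1 and 0 < self.target_specificity <= 1):
            raise ValueError("target rates must lie in (0, 1]")
        if self.cornerline_penalty <= 0 or self.min_persistence < 0:
            raise ValueError("invalid penalty/persistence settings")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls(**json.loads(s))

    def digest(self) -> str:
        """Short stable hash of the configuration, for log lines."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
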