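"""Run configuration shared by the extraction and statistics stages."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a pipeline run.

    The resolved configuration is serialized verbatim into every output
    bundle so results can be traced back to their parameters.
    """

    #: number of gray levels for GLCM/GLDS quantization (2..256)
    quant_levels: int = 32
    #: co-occurrence pixel-pair distance in pixels
    glcm_distance: int = 1
    #: co-occurrence orientations in degrees; matrices are averaged over these
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    #: displacement vectors (drow, dcol) pooled for difference statistics
    glds_displacements: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))
    #: number of equally spaced width-sampling stations along the tendon axis
    morph_stations: int = 100
    #: "otsu" or "fixed:<k>" with k an integer threshold in [0, 255]
    bone_threshold: str = "otsu"
    #: connected components smaller than this many pixels are discarded
    bone_min_fragment_px: int = 5
    #: ICC form driving the screening rule: "oneway", "agreement" or "consistency"
    icc_form: str = "agreement"
    #: variables with screening ICC below this are rejected
    icc_threshold: float = 0.75
    #: mixed-model integration: "ghq" (Gauss-Hermite) or "laplace"
    glmm_method: str = "ghq"
    #: number of quadrature nodes for the "ghq" method
    glmm_nodes: int = 25
    #: standardize covariates before model fitting
    standardize: bool = False
    #: base seed for stochastic steps (synthetic generation only)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.quant_levels <= 256:
            raise ValueError(f"quant_levels must be in [2, 256], got {self.quant_levels}")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if self.morph_stations < 2:
            raise ValueError("morph_stations must be >= 2")
        if self.bone_min_fragment_px < 1:
            raise ValueError("bone_min_fragment_px must be >= 1")
        if self.icc_form not in ("oneway", "agreement", "consistency"):
            raise ValueError(f"unknown icc_form {self.icc_form!r}")
        if self.glmm_method not in ("ghq", "laplace"):
            raise ValueError(f"unknown glmm_method {self.glmm_method!r}")
        if self.bone_threshold != "otsu":
            _parse_fixed_threshold(self.bone_threshold)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if "glcm_angles" in raw:
            raw["glcm_angles"] = tuple(raw["glcm_angles"])
        if "glds_displacements" in raw:
            raw["glds_displacements"] = tuple(tuple(d) for d in raw["glds_displacements"])
        return cls(**raw)


def _parse_fixed_threshold(spec: str) -> int:
    if not spec.startswith("fixed:"):
        raise ValueError(f"bone_threshold must be 'otsu' or 'fixed:<k>', got {spec!r}")
    k = int(spec.split(":", 1)[1])
    if not 0 <= k <= 255:
        raise ValueError(f"fixed threshold must be in [0, 255], got {k}")
    return k
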