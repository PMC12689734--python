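"""Configuration: one object bundling every stage's parameters.

YAML configs accept both the package's snake_case keys and the original
tool-level spellings of the parameter tables (``rNode.a``, ``tNode.w``,
``Goicp.MSEThresh``, ``nbMaxIterations``, ``minRMSDecrease``, ``Down sample
size``, ...) so published parameter listings can be pasted directly.
Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contraction import ContractionParams
from .features import SegmentationParams
from .registration import GoIcpParams, IcpParams

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    contraction: ContractionParams = field(default_factory=ContractionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    goicp: GoIcpParams = field(default_factory=GoIcpParams)
    icp: IcpParams = field(default_factory=IcpParams)
    direction: str = "ct_to_us"
    seed: int = 0
    profile: str = "phantom"

    def __post_init__(self) -> None:
        if self.direction not in ("ct_to_us", "us_to_ct"):
            raise ValueError("direction must be ct_to_us or us_to_ct")
        if self.profile not in ("phantom", "human"):
            raise ValueError("profile must be phantom or human")
        if self.profile == "human" and self.contraction.w_attract0 == 4.0:
            self.contraction.w_attract0 = 10.0


# alias -> (section, canonical field)
_ALIASES = {
    # contraction (skeleton-contraction parameter table)
    "down sample size": ("contraction", "voxel_edge"),
    "nearest neighbor points k": ("contraction", "k_neighbors"),
    "initial contraction weight": ("contraction", "w_contract0"),
    "initial attraction weight": ("contraction", "w_attract0"),
    "max interaction steps": ("contraction", "max_iter"),
    "termination ratio": ("contraction", "termination_ratio"),
    # coarse registration parameter table
    "goicp.msethresh": ("goicp", "mse_thresh"),
    "goicp.trimfraction": ("goicp", "trim_fraction"),
    # fine registration parameter table
    "nbmaxiterations": ("icp", "max_iter"),
    "adjustscale": ("icp", "adjust_scale"),
    "filteroutfarthestpoints": ("icp", "filter_farthest"),
    "randomsamplinglimit": ("icp", "random_sampling_limit"),
    "finaloverlapratio": ("icp", "final_overlap_ratio"),
    "maxthreadcount": ("icp", "max_workers"),
    "minrmsdecrease": ("icp", "min_rms_decrease"),
}

_SECTION_CLASSES = {
    "contraction": ContractionParams,
    "segmentation": SegmentationParams,
    "goicp": GoIcpParams,
    "icp": IcpParams,
}

_TOP_LEVEL = {"direction", "seed", "profile"}


def _apply_rnode_tnode(goicp_kwargs: dict, key: str, value) -> bool:
    """Map rNode.*/tNode.* table entries onto cube centre/width tuples."""
    lk = key.lower()
    if lk.startswith("rnode.") or lk.startswith("tnode."):
        prefix, comp = lk.split(".")
        which = "rot" if prefix == "rnode" else "trans"
        if comp == "w":
            goicp_kwargs[f"{which}_cube_width"] = float(value)
        elif comp in ("a", "b", "c", "x", "y", "z"):
            idx = {"a": 0, "b": 1, "c": 2, "x": 0, "y": 1, "z": 2}[comp]
            default = getattr(GoIcpParams(), f"{which}_cube_center")
            center = list(goicp_kwargs.get(f"{which}_cube_center", default))
            center[idx] = float(value)
            goicp_kwargs[f"{which}_cube_center"] = tuple(center)
        else:
            return False
        return True
    return False


def load_config(path: str | Path | None = None, data: dict | None = None) -> Config:
    """Build a Config from a YAML file or a mapping; unknown keys raise."""
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data = data or {}

    sections: dict[str, dict] = {name: {} for name in _SECTION_CLASSES}
    top: dict = {}

    def place(key: str, value, section_hint: str | None = None) -> None:
        lk = str(key).lower()
        if section_hint == "goicp" or section_hint is None:
            if _apply_rnode_tnode(sections["goicp"], str(key), value):
                return
        if lk in _ALIASES:
            sec, fieldname = _ALIASES[lk]
            sections[sec][fieldname] = value
            return
        if section_hint is not None:
            cls = _SECTION_CLASSES[section_hint]
            if lk in cls.__dataclass_fields__:
                sections[section_hint][lk] = value
                return
            raise KeyError(f"unknown key '{key}' in section '{section_hint}'")
        if lk in _TOP_LEVEL:
            top[lk] = value
            return
        for sec, cls in _SECTION_CLASSES.items():
            if lk in cls.__dataclass_fields__:
                sections[sec][lk] = value
                return
        raise KeyError(f"unknown config key '{key}'")

    for key, value in data.items():
        if str(key).lower() in _SECTION_CLASSES and isinstance(value, dict):
            for k2, v2 in value.items():
                place(k2, v2, section_hint=str(key).lower())
        else:
            place(key, value)

    return Config(
        contraction=ContractionParams(**sections["contraction"]),
        segmentation=SegmentationParams(**sections["segmentation"]),
        goicp=GoIcpParams(**sections["goicp"]),
        icp=IcpParams(**sections["icp"]),
        **top,
    )
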