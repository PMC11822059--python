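"""Run configuration: defaults, YAML round-trip, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .construct_builder import HS_DEFAULT, MISMATCH_K_DEFAULT, PBS_DEFAULT
from .guide_search import (
    DCN_HARD_MIN,
    DCN_WINDOW_DEFAULT,
    DCN_WINDOW_PERMISSIVE,
    DCN_WINDOW_RELAXED,
)

#: Standard SpCas9 sgRNA scaffold (DNA alphabet); override via config
#: to match any lab-specific scaffold variant.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)


@dataclass(frozen=True)
class RunConfig:
    scaffold: str = DEFAULT_SCAFFOLD
    dcn_window: tuple[int, int] = DCN_WINDOW_DEFAULT
    dcn_hard_min: int = DCN_HARD_MIN
    pbs_len: int = PBS_DEFAULT
    hs_len: int = HS_DEFAULT
    mismatch_scheme: str = "consecutive"
    mismatch_k: int = MISMATCH_K_DEFAULT
    mismatch_side: str = "auto"
    helper: str = "auto"  # auto | on | off
    helper_min_separation: int = 25
    quant_window: int = 10
    strand: str = "auto"  # auto | + | -
    u6_g: bool = False
    seed: int = 1729
    max_designs: int = 10

    def __post_init__(self) -> None:
        if self.helper not in ("auto", "on", "off"):
            raise ValueError("helper policy must be auto/on/off")
        if self.strand not in ("auto", "+", "-"):
            raise ValueError("strand must be auto/+/-")
        if self.mismatch_scheme not in ("none", "consecutive", "every3", "every5"):
            raise ValueError(f"unknown mismatch scheme {self.mismatch_scheme!r}")

    def with_window_preset(self, preset: str) -> "RunConfig":
        windows = {
            "default": DCN_WINDOW_DEFAULT,
            "relaxed": DCN_WINDOW_RELAXED,
            "permissive": DCN_WINDOW_PERMISSIVE,
        }
        return replace(self, dcn_window=windows[preset])

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["dcn_window"] = list(self.dcn_window)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        if "dcn_window" in doc:
            doc["dcn_window"] = tuple(doc["dcn_window"])
        return cls(**doc)
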