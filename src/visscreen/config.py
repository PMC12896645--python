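"""Configuration schema for the whole pipeline.

Every tunable threshold of the method lives here with its default:
adapter-trimming error rate, minimum read length, MAPQ cutoff, VIS merge
window, detection threshold, the two p-value tiers of the screen, and the
CPM positivity threshold of the single-cell validation.  A single YAML/JSON
document mirroring :class:`PipelineConfig` configures a run; command-line
flags override individual fields.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "TrimConfig",
    "VISConfig",
    "ScreenConfig",
    "ScrnaConfig",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


@dataclass
class TrimConfig:
    """Adapter/linker trimming contract.

    ``error_rate`` is the fraction of the *matched adapter length* allowed as
    edit errors (substitutions and indels); a match with distance d is
    accepted iff ``d <= floor(error_rate * matched_len)``.
    """

    ltr_adapter: str = "TGTGGAAAATCTCTAGCAGT"
    linker_adapter: str = "AGATCGGAAGAGCACACGTC"
    error_rate: float = 0.25
    min_read_len: int = 36
    discard_untrimmed: bool = True
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")
        if not self.ltr_adapter or not self.linker_adapter:
            raise ValueError("adapters must be non-empty")


@dataclass
class VISConfig:
    """Integration-site calling parameters."""

    window_bp: int = 1000          # reads within this gap chain into one locus
    mapq_min: int = 20             # alignments below this MAPQ are dropped
    min_reads_detect: int = 1      # locus counts as detected in a sample at >= this depth

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if self.min_reads_detect < 1:
            raise ValueError("min_reads_detect must be >= 1")


@dataclass
class ScreenConfig:
    """Thresholds and group structure of the resistance screen.

    Two significance tiers are used throughout: ``p_significant`` (0.05)
    marks conventional significance, ``p_exploratory`` (0.10) the relaxed
    hypothesis-generating tier applied to both the detection-frequency
    (Fisher) and read-depth-coverage (t) tests.
    """

    p_exploratory: float = 0.10
    p_significant: float = 0.05
    discovery_treatments: tuple[str, ...] = ("tamoxifen", "fulvestrant", "ribociclib")
    candidate_treatments: tuple[str, ...] = ("fulvestrant", "ribociclib")
    verification_treatments: tuple[str, ...] = (
        "abemaciclib",
        "palbociclib",
        "fulvestrant+ribociclib",
    )
    control_label: str = "NC"
    # candidate loci must be enriched (or exclusive to treatment); set False to
    # admit depleted loci as candidates too.
    require_enriched: bool = True
    # coverage t-test: include undetected samples as RPM 0 (fixed group sizes);
    # False restricts to detected samples only.
    coverage_include_undetected: bool = True
    welch: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_significant <= self.p_exploratory < 1):
            raise ValueError("need 0 < p_significant <= p_exploratory < 1")


@dataclass
class ScrnaConfig:
    """Single-cell fraction-positive validation parameters."""

    cpm_threshold: float = 1.0     # a cell is positive for a gene at CPM >= this
    yates: bool = False            # continuity correction off by default
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be > 0")


@dataclass
class PipelineConfig:
    trim: TrimConfig = field(default_factory=TrimConfig)
    vis: VISConfig = field(default_factory=VISConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    scrna: ScrnaConfig = field(default_factory=ScrnaConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _build(cls, data: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("discovery_treatments", "candidate_treatments", "verification_treatments"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    cfg = PipelineConfig()
    for section, cls in (
        ("trim", TrimConfig),
        ("vis", VISConfig),
        ("screen", ScreenConfig),
        ("scrna", ScrnaConfig),
    ):
        if section in data:
            setattr(cfg, section, _build(cls, data[section]))
    unknown = set(data) - {"trim", "vis", "screen", "scrna"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    doc = json.loads(json.dumps(cfg.to_dict()))  # plain types for yaml
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
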