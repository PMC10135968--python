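"""Run configuration: analysis conventions gathered in one place.

The configuration file is INI-style (key = value under sections), e.g.::

    [energy]
    RT = 0.5925

    [statistics]
    z_quantile = 1.96

    [protocol]
    correction_threshold = 0.01
    direct_threshold = 0.02

    [sites]
    NS-1738 = 2
    propofol = 4

    [run]
    seed = 1
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import CLAMP_EPSILON, RT_DEFAULT, SITE_COUNTS
from .cycle import Z_95
from .normalize import (
    CONSTITUTIVE_CORRECTION_THRESHOLD,
    CONSTITUTIVE_DIRECT_THRESHOLD,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    RT: float = RT_DEFAULT
    z_quantile: float = Z_95
    clamp_epsilon: float = CLAMP_EPSILON
    correction_threshold: float = CONSTITUTIVE_CORRECTION_THRESHOLD
    direct_threshold: float = CONSTITUTIVE_DIRECT_THRESHOLD
    site_counts: dict[str, int] = field(default_factory=lambda: dict(SITE_COUNTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.RT > 0:
            raise ValueError("RT must be > 0")
        if not self.correction_threshold <= self.direct_threshold:
            raise ValueError("constitutive thresholds must be ordered")

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        payload = {
            "RT": self.RT,
            "z_quantile": self.z_quantile,
            "clamp_epsilon": self.clamp_epsilon,
            "correction_threshold": self.correction_threshold,
            "direct_threshold": self.direct_threshold,
            "site_counts": dict(sorted(self.site_counts.items())),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from an INI file; defaults where keys are absent."""
    cfg = RunConfig()
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    parser.optionxform = str  # compound names are case-sensitive
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    if parser.has_option("energy", "RT"):
        cfg.RT = parser.getfloat("energy", "RT")
    if parser.has_option("statistics", "z_quantile"):
        cfg.z_quantile = parser.getfloat("statistics", "z_quantile")
    if parser.has_option("statistics", "clamp_epsilon"):
        cfg.clamp_epsilon = parser.getfloat("statistics", "clamp_epsilon")
    if parser.has_option("protocol", "correction_threshold"):
        cfg.correction_threshold = parser.getfloat("protocol", "correction_threshold")
    if parser.has_option("protocol", "direct_threshold"):
        cfg.direct_threshold = parser.getfloat("protocol", "direct_threshold")
    if parser.has_section("sites"):
        for compound, value in parser.items("sites"):
            cfg.site_counts[compound] = int(value)
    if parser.has_option("run", "seed"):
        cfg.seed = parser.getint("run", "seed")
    cfg.__post_init__()
    return cfg
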