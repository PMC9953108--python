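"""Run configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline thresholds.

    All comparison thresholds are strict: cluster gaps must be *less than*
    ``cluster_max_gap``, BBH identity/coverage must be *greater than* their
    minima.
    """

    cluster_max_gap: int = 200  # bp; intergenic distance must be < this
    break_on_intervening: bool = True  # non-TCS gene between two TCS genes breaks a chain
    bbh_identity_min: float = 40.0  # %, strict >
    bbh_coverage_min: float = 75.0  # %, strict >
    domain_evalue_max: float = 1e-4  # inclusion threshold for domain hits
    tm_window: int = 19  # Kyte-Doolittle window length (residues)
    tm_threshold: float = 1.6  # mean hydropathy marking a candidate segment
    gain_penalty: float = 2.0  # parsimony cost of a gain (loss costs 1)
    duplicate_identity_min: float = 95.0  # %, within-genome duplication flag
    precision: int = 1  # decimals for printed ratios/fractions
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cluster_max_gap",
            "bbh_identity_min",
            "bbh_coverage_min",
            "domain_evalue_max",
            "tm_window",
            "tm_threshold",
            "gain_penalty",
            "duplicate_identity_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.precision < 0:
            raise ValueError("precision must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
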