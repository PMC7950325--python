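"""Pipeline configuration: every tunable threshold as a named default,
round-tripping losslessly through YAML.

Defaults follow the printed acquisition/search settings of the experiment
the pipeline models: 4.5 ppm linear precursor tolerance, 20 ppm linear MS2
tolerance, 10 ppm cross-link precursor tolerance, 0.02 m/z cross-link MS2
tolerance, score threshold 50, MS1 intensity floor 2000, two missed
tryptic cleavages.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import yaml

from .chem import Modification, STANDARD_MODIFICATIONS
from .digest import DigestSpec


@dataclass(frozen=True)
class PipelineConfig:
    digest: DigestSpec = field(default_factory=DigestSpec)
    modifications: tuple[Modification, ...] = tuple(STANDARD_MODIFICATIONS.values())
    max_variable_mods: int = 3
    linear_precursor_tol_ppm: float = 4.5
    linear_ms2_tol_ppm: float = 20.0
    xl_precursor_tol_ppm: float = 10.0
    xl_ms2_tol_mz: float = 0.02
    score_threshold: float = 50.0
    intensity_floor: float = 2000.0
    target_fdr: float = 0.05
    require_replicates: int = 2
    label_shift_tolerance: float = 0.015
    min_change_percent: float = 10.0
    charge_min: int = 2
    charge_max: int = 6
    peptide_mass_cap: float = 6000.0
    pair_mass_cap: float = 8000.0
    link_rules: tuple[str, ...] = ("YY", "WW", "YW")
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["digest"] = asdict(self.digest)
        d["modifications"] = [m.to_dict() for m in self.modifications]
        d["link_rules"] = list(self.link_rules)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "digest" in d:
            d["digest"] = DigestSpec(**d["digest"])
        if "modifications" in d:
            d["modifications"] = tuple(Modification.from_dict(m) for m in d["modifications"])
        if "link_rules" in d:
            d["link_rules"] = tuple(d["link_rules"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(d)
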