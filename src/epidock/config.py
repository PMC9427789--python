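"""Run configuration: thresholds, chain roles and I/O paths.

Defaults encode the pipeline's standard operating points: the 20% RSA
exposure rule, the 800 A^2 minimum interface area, 0.1 A^2 interface
membership threshold, 100-fold censoring bound and the 0.5/0.2 blockage
grade cuts. A config is echoed verbatim into every output directory so a
run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # exposure / scan design
    rsa_threshold_percent: float = 20.0
    rsa_reference_set: str = "tien2013_theoretical"
    scan_flank: int = 2
    # SASA
    probe_radius: float = 1.4
    sasa_points: int = 960
    # fold changes
    censor_bound: float = 100.0
    spot_concentration_policy: str = "higher"   # of the two printed spot concs
    # interface / ranking
    delta_sasa_threshold: float = 0.1
    min_bsa: float = 800.0
    cdr_percent_range: Tuple[float, float] = (50.0, 95.0)
    blockage_high: float = 0.5
    blockage_medium: float = 0.2
    region_denominator: str = "antibody"
    # chain roles
    antigen_chains: Tuple[str, ...] = ("A",)
    heavy_chain: str = "H"
    light_chain: str = "L"
    receptor_chains: Tuple[str, ...] = ("R",)
    superposition_atom: str = "CA"
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def echo(self, out_dir: Path | str) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "config.yaml"
        path.write_text(self.to_yaml())
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cdr_percent_range", "antigen_chains", "receptor_chains"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)
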