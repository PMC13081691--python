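"""Scoring thresholds and run configuration.

Defaults follow the screening protocol: PAE and inter-residue distance
cutoffs of 15 Å for ipSAE, the permissive weighted-score filter at 0.40,
the pDockQ accept cutoff at 0.23, and the interface-lDDT network threshold
at 0.80.  All values can be overridden from a flat YAML file whose keys
mirror the field names; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ScoringConfig:
    # ipSAE family
    pae_cutoff: float = 15.0           # Å, strict "<" comparison
    dist_cutoff: float = 15.0          # Å, inter-residue distance cutoff
    # weighted ipTM+pTM
    weighted_weights: tuple[float, float] = (0.8, 0.2)
    weighted_permissive: float = 0.40
    weighted_bands: tuple[float, float] = (0.60, 0.80)
    # ipTM banding
    iptm_bands: tuple[float, float] = (0.60, 0.75)
    # ipSAE classification
    ipsae_false_max: float = 0.20
    ipsae_true_min: float = 0.40
    # pDockQ bands: accept / medium / high
    pdockq_bands: tuple[float, float, float] = (0.23, 0.49, 0.80)
    # masked interface-pTM bands
    actifptm_bands: tuple[float, float, float] = (0.60, 0.70, 0.80)
    # similarity network
    lddt_edge_threshold: float = 0.80
    # contact definitions
    interface_contact_cutoff: float = 5.0   # Å heavy-atom (PISA-like)
    cb_contact_cutoff: float = 8.0          # Å Cβ–Cβ (pDockQ)
    # membrane proximity
    membrane_proximity_cutoff: float = 3.5  # Å to the leaflet plane

    def __post_init__(self) -> None:
        for name in (
            "pae_cutoff", "dist_cutoff", "interface_contact_cutoff",
            "cb_contact_cutoff", "membrane_proximity_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("weighted_bands", "iptm_bands", "pdockq_bands",
                     "actifptm_bands"):
            bands = tuple(getattr(self, name))
            if any(b <= a for a, b in zip(bands, bands[1:])):
                raise ValueError(f"{name} must be strictly increasing: {bands}")
            setattr(self, name, bands)
        self.weighted_weights = tuple(self.weighted_weights)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "ScoringConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def load_yaml(cls, path: str | Path) -> "ScoringConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


@dataclass
class RunConfig:
    """Full run configuration: scoring thresholds plus I/O and seed."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0
    outdir: Path = Path(".")
    verbosity: int = 1
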