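"""Run configuration: a fully serialisable description of one scenario.

A :class:`RunConfig` captures geometry, cluster distribution, physics and
chemistry parameters, membrane policy, beam and master seed, and is
round-trippable through YAML with a stable content hash, so every summary
output is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .chemistry import ChemistryParams, MembranePolicy
from .source import BeamSpec, EmissionModel
from .transport import TransportModel

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """One simulation scenario.

    ``layout_mode`` is ``single`` or one of the two-cell modes
    (``compressed``/``touching``/``separated`` along ``layout_axis``);
    clusters always belong to the primary cell.
    """

    seed: int = 0
    material: str = "gold"
    n_protons: int = 1000
    # cluster distribution
    n_clusters: int = 1000
    cluster_diameter_um: float = 0.2
    n_np_per_cluster: int = 100
    region: str = "perinuclear"
    shell_width_um: float = 1.0
    # geometry / layout
    layout_mode: str = "single"
    layout_axis: str = "z"
    layout_gap_um: float = 1.0
    # physics and chemistry parameter blocks
    beam: BeamSpec = field(default_factory=BeamSpec)
    emission: EmissionModel = field(default_factory=EmissionModel)
    transport_model: TransportModel = field(default_factory=TransportModel)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    policy: MembranePolicy = field(default_factory=MembranePolicy)
    voxel_spacing_um: float | None = None

    def __post_init__(self):
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.material not in ("gold", "water"):
            raise ValueError("material must be 'gold' or 'water'")
        if self.layout_mode not in ("single", "compressed", "touching", "separated"):
            raise ValueError(f"unknown layout mode {self.layout_mode!r}")

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("beam", BeamSpec),
            ("emission", EmissionModel),
            ("transport_model", TransportModel),
            ("chemistry", ChemistryParams),
            ("policy", MembranePolicy),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
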