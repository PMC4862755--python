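"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .intervals import GenomicInterval


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    ``p_subthreshold`` is the inclusion cut-off for sub-threshold SNPs
    (p < 1e-4), ``p_gws`` the genome-wide significance line (5e-8), and
    ``exclusion_radius_bp`` the buffer removed around known loci (1 Mb).
    """

    seed: int = 0
    p_subthreshold: float = 1e-4
    p_gws: float = 5e-8
    exclusion_radius_bp: int = 1_000_000
    n_perm: int = 100_000
    r2_expand: float = 0.8
    r2_prune: float = 0.2
    masked_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.p_gws < self.p_subthreshold < 1:
            raise ValueError(
                f"need 0 < p_gws < p_subthreshold < 1, got "
                f"{self.p_gws}, {self.p_subthreshold}"
            )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.exclusion_radius_bp < 0:
            raise ValueError("exclusion_radius_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        masks = [
            GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))
            for m in raw.pop("masked_regions", [])
        ]
        return cls(masked_regions=masks, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["masked_regions"] = [
            {"chrom": m.chrom, "start": m.start, "end": m.end}
            for m in self.masked_regions
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
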