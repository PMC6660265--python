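"""Run configuration: one structured YAML file, round-trip safe.

Defaults are the standard analysis conditions: a 5,000-nt upstream
window (-4,900..+100 on the no-zero axis), core/proximal/distal region
boundaries at -900 and -2,900, an HRE-HAS gap of 7-15 nt, 80% identity
with 50% coverage for homology calls, 40-nt (10+30) fragments around
each HRE for de novo motif input, and 500-nt profile bins.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

from .gene_filter import DEFAULT_MITO_PATTERN, HomologyParams
from .motif_scan import LinkSpec, RegionScheme
from .promoter_extract import WindowSpec


@dataclass
class RunConfig:
    rel_start: int = -4900
    rel_end: int = 100
    core_floor: int = -900
    proximal_floor: int = -2900
    min_gap: int = 7
    max_gap: int = 15
    min_identity_pct: float = 80.0
    min_coverage_frac: float = 0.5
    homology_backend: str = "builtin"
    mito_pattern: str = DEFAULT_MITO_PATTERN
    meme_up: int = 10
    meme_down: int = 30
    bin_width: int = 500
    seed: int = 0

    def window(self) -> WindowSpec:
        return WindowSpec(self.rel_start, self.rel_end)

    def link_spec(self) -> LinkSpec:
        return LinkSpec(self.min_gap, self.max_gap)

    def scheme(self) -> RegionScheme:
        return RegionScheme(
            core_floor=self.core_floor,
            proximal_floor=self.proximal_floor,
            distal_floor=self.rel_start,
            ceiling=self.rel_end,
        )

    def homology(self) -> HomologyParams:
        return HomologyParams(
            self.min_identity_pct, self.min_coverage_frac, self.homology_backend
        )

    def half_spec(self) -> tuple[int, int]:
        return (self.meme_up, self.meme_down)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        # validate eagerly so a bad file fails at load time, naming the key
        try:
            cfg.window(), cfg.link_spec(), cfg.homology(), cfg.scheme()
        except ValueError as exc:
            raise ValueError(f"config value out of range: {exc}") from None
        return cfg
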