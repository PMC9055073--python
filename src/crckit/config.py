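"""Run configuration with published-methods defaults.

Every threshold used by the pipeline lives here and can be overridden from
a YAML/JSON document.  Defaults follow the source study's methods: variant
hard filters VAF >= 8%, depth >= 8, alt reads >= 2; common variants removed
at population MAF > 0.05 (strict); hypermutation at TMB >= 10 muts/Mb;
signature refitting restricted to samples with >= 20 SNVs and signatures
kept when present in > 1% of samples; consensus NMF over K = 2..6 with 10
runs; immunoediting gate Z < -1.645; HLA-LOH rule p < 0.01, allele copy
number < 0.5, CI upper < 0.7; mitochondrial blacklist positions
{310, 523, 524, 3107}; mScore-high = top 10%.

The exome panel size in Mb (TMB denominator) is not published; the default
of 35 Mb is a typical whole-exome target size and should be set to the
actual panel for real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """All pipeline thresholds in one overridable document."""

    panel_size_mb: float = 35.0
    tmb_threshold: float = 10.0
    vaf_min: float = 0.08
    depth_min: int = 8
    altreads_min: int = 2
    pop_af_max: float = 0.05
    min_snvs_signature: int = 20
    signature_prevalence_min: float = 0.01
    nmf_k_min: int = 2
    nmf_k_max: int = 6
    nmf_runs: int = 10
    nmf_k_override: int | None = None
    min_nonsilent_rates: int = 10
    immunoedit_z_cut: float = -1.645
    hla_p_cut: float = 0.01
    hla_cn_cut: float = 0.5
    hla_ci_cut: float = 0.7
    mt_blacklist: frozenset[int] = frozenset({310, 523, 524, 3107})
    mscore_top_fraction: float = 0.10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be positive")
        if not (2 <= self.nmf_k_min <= self.nmf_k_max <= 10):
            raise ValueError("NMF K range must lie within [2, 10]")
        if not 0 < self.mscore_top_fraction < 1:
            raise ValueError("mscore_top_fraction must be in (0, 1)")
        for name in ("vaf_min", "pop_af_max", "signature_prevalence_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        self.mt_blacklist = frozenset(int(p) for p in self.mt_blacklist)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mt_blacklist"] = sorted(self.mt_blacklist)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
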