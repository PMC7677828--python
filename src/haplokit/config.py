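"""Pipeline configuration with JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"

    # synthetic cohort
    n_sites: int = 19
    n_hap2_diffs: int = 15
    strata: dict = field(
        default_factory=lambda: {"EA": [773, 576], "AA": [182, 181], "AS": [160, 160]}
    )
    haplotype_log_or: dict = field(
        default_factory=lambda: {"HAP3": 0.4054651081081644, "HAP2": 0.0}
    )  # log 1.5
    reference_haplotype: str = "HAP1"
    mutation_rate: float = 0.0
    region_kb: float = 102.0

    # QC
    min_call_rate: float = 0.85
    min_depth: float = 25.0
    common_maf: float = 0.05
    hwe_alpha: float = 1e-3
    hwe_method: str = "exact"
    hwe_per_stratum: bool = True

    # association
    gc_common_only: bool = True
    peak_variant: str = ""

    # haplotypes
    tag_dprime: float = 0.8

    # expression / DE
    n_genes: int = 200
    effect_per_score: float = 1.0
    noise_sd: float = 0.5
    expr_baseline: float = 10.0
    de_background_rpkm: float = 2.0
    de_t_alpha: float = 0.05
    de_assoc_alpha: float = 1e-4
    de_min_fold: float = 1.5
    de_f_alpha: float = 0.05

    # serology
    n_antigens: int = 90
    serology_fold_threshold: float = 5.0

    # inputs (optional; simulate stage fills them in when absent)
    vcf: str = ""
    sample_sheet: str = ""
    expression: str = ""
    serology: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
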