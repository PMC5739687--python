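"""Run-level configuration for the analysis stages.

A :class:`RunConfig` gathers every tunable threshold the pipeline applies:
the FDR level and p-value gate of the differential stages, the proteome
validity-filter mode, the left-censored imputation parameters, the GSEA
settings and the mtDNA prioritization thresholds.  Configurations can be
loaded from / dumped to YAML so an analysis is fully described by one file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

FILTER_MODES = ("each_group_min3", "one_group_full6")
FLOOR_POLICIES = ("per_metabolite_loq", "global_min_positive")


@dataclass
class ImputationParams:
    """Width/downshift of the left-shifted Gaussian used for missing values."""

    width_factor: float = 0.3
    downshift_factor: float = 1.8

    def validate(self) -> None:
        if self.width_factor <= 0 or self.downshift_factor <= 0:
            raise ValueError("imputation factors must be strictly positive")


@dataclass
class GseaParams:
    min_size: int = 5
    n_perm: int = 1000
    weight: float = 1.0
    p_threshold: float = 0.01
    fdr_threshold: float = 0.15  # Results gate; Methods alternatively use 0.25

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0 < self.p_threshold < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("GSEA significance gates must lie in (0, 1)")


@dataclass
class MtdnaThresholds:
    """Prioritization thresholds for mtDNA variants.

    A variant is prioritized when its cross-population nucleotide variability
    falls below ``variability_cutoff`` (conserved site) and its pathogenicity
    score exceeds the class-specific threshold: ``ds_nonsyn`` for
    non-synonymous protein variants, ``ds_trna`` / ``ds_rrna`` for tRNA and
    rRNA loci.  ``hf_tolerance`` and ``detection_limit`` govern the
    germline/somatic call from paired heteroplasmic fractions.
    """

    variability_cutoff: float = 0.0026
    ds_nonsyn: float = 0.43
    ds_trna: float = 0.35
    ds_rrna: float = 0.60
    hf_tolerance: float = 0.10
    detection_limit: float = 0.005

    def validate(self) -> None:
        for name in ("variability_cutoff", "ds_nonsyn", "ds_trna", "ds_rrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.detection_limit < 1:
            raise ValueError("detection_limit must lie in [0, 1)")
        if not 0 < self.hf_tolerance <= 1:
            raise ValueError("hf_tolerance must lie in (0, 1]")


@dataclass
class RunConfig:
    seed: int = 0
    fdr_level: float = 0.05
    p_cutoff: float = 0.01
    filter_mode: str = "each_group_min3"
    floor_policy: str = "per_metabolite_loq"
    imputation: ImputationParams = field(default_factory=ImputationParams)
    gsea: GseaParams = field(default_factory=GseaParams)
    mtdna: MtdnaThresholds = field(default_factory=MtdnaThresholds)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.filter_mode not in FILTER_MODES:
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.floor_policy not in FLOOR_POLICIES:
            raise ValueError(f"unknown floor_policy {self.floor_policy!r}")
        self.imputation.validate()
        self.gsea.validate()
        self.mtdna.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "imputation" in kwargs:
            kwargs["imputation"] = ImputationParams(**kwargs["imputation"])
        if "gsea" in kwargs:
            kwargs["gsea"] = GseaParams(**kwargs["gsea"])
        if "mtdna" in kwargs:
            kwargs["mtdna"] = MtdnaThresholds(**kwargs["mtdna"])
        return cls(**kwargs)
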