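"""Configuration models for the simulator and the analysis pipeline.

All tunable thresholds of the analysis live in :class:`Thresholds` with the
values used throughout as defaults, so every filter is auditable and can be
overridden from a config file or the command line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: Fixed order of the six predicted-severity bins used everywhere.
BIN_ORDER = ("PTV_LOEUF", "PTV_other", "DmisB", "DmisA", "Mis_low", "Synonymous")

#: Bins that count as potentially damaging SNVs (pdSNVs).
PDSNV_BINS = frozenset({"PTV_LOEUF", "DmisB", "DmisA"})

# Default mix of de novo variants over the six severity bins. Calibrated to
# the bin distribution observed in ASD probands of family cohorts
# (PTV in constrained genes ~5%, other PTV ~7%, damaging missense ~18%,
# low-MPC missense ~43%, synonymous ~26%); renormalized to sum to one.
_RAW_MIX = (0.051, 0.07, 0.069, 0.113, 0.43, 0.26)
DEFAULT_BIN_MIX = tuple(x / sum(_RAW_MIX) for x in _RAW_MIX)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic family cohort.

    Defaults emulate a 116-family ASD cohort: ~22% multiplex families,
    ~0.76 male fraction among affected children, a mean of 1.24 rare coding
    de novo variants per child, and ~0.5 unaffected siblings per family.
    """

    n_families: int = Field(default=116, ge=1)
    fraction_multiplex: float = Field(default=25 / 116, ge=0.0, le=1.0)
    p_affected_male: float = Field(default=110 / 144, ge=0.0, le=1.0)
    sibling_rate: float = Field(default=0.5, ge=0.0)
    de_novo_rate_per_child: float = Field(default=1.24, ge=0.0)
    missing_parent_families: int = Field(default=0, ge=0)
    background_variants_per_family: int = Field(default=40, ge=0)
    planted_bin_mix: tuple[float, float, float, float, float, float] = DEFAULT_BIN_MIX
    quality_fail_fraction: float = Field(default=0.15, ge=0.0, le=1.0)

    # CNV generator
    cnv_boundary_jitter_sd: float = Field(default=500.0, ge=0.0)
    cnv_dropout: float = Field(default=0.05, ge=0.0, le=1.0)
    inherited_cnvs_per_family: float = Field(default=2.0, ge=0.0)
    de_novo_cnv_rate_per_child: float = Field(default=0.1, ge=0.0)
    wgs_family_fraction: float = Field(default=105 / 116, ge=0.0, le=1.0)
    probe_spacing_bp: int = Field(default=2_000, ge=1)

    # recessive / X-linked planting (expected events across the cohort)
    n_biallelic_events: int = Field(default=0, ge=0)
    n_xlinked_events: int = Field(default=0, ge=0)

    # PRS generator
    n_prs_snps: int = Field(default=300, ge=1)
    prs_overtransmission: float = 0.2
    mz_twin_families: int = Field(default=0, ge=0)

    seed: int = 0

    @field_validator("planted_bin_mix")
    @classmethod
    def _mix_is_distribution(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(x < 0 for x in v):
            raise ValueError("planted_bin_mix entries must be non-negative")
        total = sum(v)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("planted_bin_mix must sum to 1")
        return tuple(x / total for x in v)


class Thresholds(BaseModel):
    """Every filter threshold of the analysis, with its default.

    SNV quality/rarity: retain coding variants with DP >= 10, GQ >= 20,
    PASS, MAF <= 0.1% (monoallelic model) or <= 1% (biallelic model).
    De novo rule (strict inequalities): DP > 9 in child and both parents,
    child GQ > 20, child allele balance > 0.25, parental alternate read
    count == 0, called by both callers.
    """

    # SNV filtering
    min_dp: int = 10
    min_gq: int = 20
    maf_monoallelic: float = 0.001
    maf_biallelic: float = 0.01

    # de novo rule (strict inequalities as stated)
    denovo_min_dp_exclusive: int = 9
    denovo_min_gq_exclusive: int = 20
    denovo_min_ab_exclusive: float = 0.25
    denovo_max_parent_ao: int = 0

    # severity tiers
    loeuf_constrained: float = 0.6
    mpc_dmisb: float = 2.0
    mpc_dmisa: float = 1.0
    pext_constitutive: float = 0.9
    pext_low: float = 0.1

    # CNV consensus (array)
    reciprocal_overlap: float = 0.5
    consensus_min_callers: int = 2
    consensus_min_confidence: float = 10.0
    consensus_min_size: int = 1_000
    consensus_min_probes: int = 3

    # CNV rare/stringent filter
    cnv_min_size: int = 10_000
    cnv_min_probes: int = 5
    segdup_centromere_max_frac: float = 0.5
    parent_freq_max: float = 0.01
    cn_stable_min_frac: float = 0.75
    rgd_min_locus_cov: float = 0.4

    # pdCNV prioritization
    large_cnv_size: int = 3_000_000
    phaplo_min: float = 0.55
    ptriplo_min: float = 0.68

    # PRS
    prs_maf_min: float = 0.01
    prs_info_min: float = 0.8
    clump_r2: float = 0.1
    clump_radius_bp: int = 250_000
    prs_p_threshold: float = 0.01
    prs_log_or_weights: bool = True

    # enrichment
    fdr_q: float = 0.01


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration: input paths, thresholds, output."""

    out_dir: Path
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = SimulationConfig()
    thresholds: Thresholds = Thresholds()
    verbosity: int = 1

    # Input paths; when ``simulate`` is true they are filled in by the
    # simulation stage, otherwise they must point at existing files.
    vcf_caller_a: Optional[Path] = None
    vcf_caller_b: Optional[Path] = None
    ped_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    gene_table_path: Optional[Path] = None
    excluded_bed: Optional[Path] = None
    rgd_bed: Optional[Path] = None
    segdup_bed: Optional[Path] = None
    centromere_bed: Optional[Path] = None
    cn_stable_bed: Optional[Path] = None
    exon_bed: Optional[Path] = None
    par_bed: Optional[Path] = None
    cnv_calls_path: Optional[Path] = None
    gwas_path: Optional[Path] = None
    dosage_path: Optional[Path] = None
    truth_path: Optional[Path] = None
    terms_path: Optional[Path] = None
    edges_path: Optional[Path] = None
    wgs_families_path: Optional[Path] = None

    @model_validator(mode="after")
    def _sync_seed(self) -> "PipelineConfig":
        # the pipeline seed drives the simulation unless set explicitly
        if self.simulate and "seed" not in self.simulation.model_fields_set:
            object.__setattr__(self.simulation, "seed", self.seed)
        return self
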