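"""Centralized thresholds and sample metadata handling.

Every numeric cutoff used by the analysis stages lives in a single
:class:`ThresholdConfig` object so that a run is fully described by
(inputs, config, seed).  The defaults reproduce the settings of the
genome-resolved oral-microbiome workflow this package implements:
a genome is "detected" in a metagenome when more than half of its
nucleotide positions are covered, near-identical bins are collapsed at
>= 99.8% ANI over at least half of the shorter genome, functions are
called enriched below q = 0.05, and single-nucleotide variants require
more than 20x coverage and a minor-allele frequency of at least 10%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = [
    "ThresholdConfig",
    "SAMPLE_COLUMNS",
    "validate_samples",
    "read_samples",
]

#: required columns of a sample-metadata table
SAMPLE_COLUMNS = ("sample_id", "subject_id", "site", "total_reads", "nonhuman_reads")


@dataclass
class ThresholdConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    Attributes
    ----------
    detection_presence_threshold
        Breadth-of-coverage (fraction of positions covered by >= 1 read)
        above which a genome is called present in a sample.
    presence_comparator
        ``"strict_greater"`` (detection > threshold, the default) or
        ``"at_least"`` (detection >= threshold).
    mcg_alpha
        Alpha of the coverage-classifier mode; it implies a presence
        threshold of ``0.5 + mcg_alpha`` (0.6 at the default 0.1).
    ani_redundancy_threshold
        Percent ANI at or above which two bins are candidate duplicates.
    ani_min_alignment_fraction_shorter
        Minimum fraction of the *shorter* genome covered by the
        alignment for a pair to count as redundant.
    ani_reporting_min_alignment_fraction
        Separate, looser cutoff (on both genomes) used only when
        reporting ANI summaries, not for dereplication.
    snv_min_coverage
        Per-sample coverage that every sample must strictly exceed for a
        position to be assessable.
    snv_maf_threshold
        Minor-allele frequency at or above which a position is variable.
    enrichment_q_threshold
        A function is enriched when its q-value is strictly below this.
    core_occurrence_fraction
        A function is "core" when present in at least this fraction of
        genomes.
    unknown_bin_length
        Surrogate genome length (bp) for the UNKNOWN bin when estimating
        relative abundances.
    outlier_mad_multiplier
        Positions with |coverage - median| > multiplier * MAD are
        outliers for the non-outlier mean coverage.
    zeros_are_outliers
        Drop zero-coverage positions before the robust mean.
    fdr_method
        ``"storey"`` (q-values with estimated pi0) or ``"bh"``.
    storey_lambda
        Lambda tuning parameter of the pi0 estimate.
    random_seed
        Seed forwarded to the synthetic-data generators.
    """

    detection_presence_threshold: float = 0.5
    presence_comparator: str = "strict_greater"
    mcg_alpha: float = 0.1
    ani_redundancy_threshold: float = 99.8
    ani_min_alignment_fraction_shorter: float = 0.5
    ani_reporting_min_alignment_fraction: float = 0.25
    snv_min_coverage: int = 20
    snv_maf_threshold: float = 0.10
    enrichment_q_threshold: float = 0.05
    core_occurrence_fraction: float = 0.9
    unknown_bin_length: int = 2_000_000
    outlier_mad_multiplier: float = 2.5
    zeros_are_outliers: bool = True
    fdr_method: str = "storey"
    storey_lambda: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detection_presence_threshold",
            "mcg_alpha",
            "snv_maf_threshold",
            "enrichment_q_threshold",
            "core_occurrence_fraction",
            "storey_lambda",
            "ani_min_alignment_fraction_shorter",
            "ani_reporting_min_alignment_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if not 0.0 <= self.ani_redundancy_threshold <= 100.0:
            raise ValueError("ani_redundancy_threshold must be in [0, 100]")
        if self.snv_min_coverage < 1:
            raise ValueError("snv_min_coverage must be >= 1")
        if self.unknown_bin_length <= 0:
            raise ValueError("unknown_bin_length must be positive")
        if self.outlier_mad_multiplier <= 0:
            raise ValueError("outlier_mad_multiplier must be positive")
        if self.presence_comparator not in ("strict_greater", "at_least"):
            raise ValueError(
                "presence_comparator must be 'strict_greater' or 'at_least'"
            )
        if self.fdr_method not in ("storey", "bh"):
            raise ValueError("fdr_method must be 'storey' or 'bh'")

    @property
    def mcg_presence_threshold(self) -> float:
        """Presence threshold implied by the coverage-classifier mode."""
        return 0.5 + self.mcg_alpha

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table and return it unchanged.

    Requires the columns in :data:`SAMPLE_COLUMNS`, unique sample ids,
    and ``nonhuman_reads <= total_reads`` (microbial reads are the total
    minus those mapping to the human genome).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups}")
    bad = samples["nonhuman_reads"] > samples["total_reads"]
    if bad.any():
        raise ValueError(
            "nonhuman_reads exceeds total_reads for samples: "
            f"{samples.loc[bad, 'sample_id'].tolist()}"
        )
    return samples


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_samples(df)
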