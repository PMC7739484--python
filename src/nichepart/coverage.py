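"""Genome detection, coverage statistics, and site-specificity calls.

The central quantity is *detection* (breadth of coverage): the fraction
of a genome's nucleotide positions covered by at least one read in a
sample.  A genome is called present when its detection exceeds a
threshold (default 0.5), coverage depth is summarized robustly as the
*non-outlier mean coverage*, and depth is made comparable across
samples of unequal sequencing effort by a per-sample normalization
factor.  Presence patterns across body sites then yield prevalence,
site-association chi-squared tests, and a specialist/cosmopolitan
classification per genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig, validate_samples

__all__ = [
    "compute_detection",
    "call_presence",
    "call_presence_matrix",
    "non_outlier_mean",
    "normalization_factors",
    "normalized_coverage",
    "relative_abundance",
    "prevalence",
    "site_association_test",
    "classify_specificity",
]

UNKNOWN_BIN = "UNKNOWN"


def compute_detection(coverage_vector: np.ndarray) -> float:
    """Fraction of positions covered by at least one read."""
    v = np.asarray(coverage_vector)
    if v.size == 0:
        raise ValueError("coverage vector is empty")
    if (v < 0).any():
        raise ValueError("coverage counts must be non-negative")
    return float(np.count_nonzero(v >= 1) / v.size)


def call_presence(detection: float, cfg: ThresholdConfig) -> bool:
    """Presence call from a detection value under the configured comparator."""
    t = cfg.detection_presence_threshold
    if cfg.presence_comparator == "at_least":
        return bool(detection >= t)
    return bool(detection > t)


def call_presence_matrix(detection: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Vectorized :func:`call_presence` over a genome x sample detection matrix."""
    t = cfg.detection_presence_threshold
    if cfg.presence_comparator == "at_least":
        return detection >= t
    return detection > t


def non_outlier_mean(coverage_vector: np.ndarray, cfg: ThresholdConfig) -> float:
    """Mean coverage over non-outlier positions.

    Positions whose coverage deviates from the median by more than
    ``outlier_mad_multiplier`` times the median absolute deviation (MAD)
    are excluded.  With ``zeros_are_outliers`` (the default), zero
    positions are dropped before the median and MAD are computed.  When
    the MAD is zero, only positions equal to the median qualify; when no
    position qualifies at all, the result is 0.
    """
    v = np.asarray(coverage_vector, dtype=float)
    if v.size == 0:
        raise ValueError("coverage vector is empty")
    if cfg.zeros_are_outliers:
        v = v[v > 0]
        if v.size == 0:
            return 0.0
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if mad == 0.0:
        keep = v == med
    else:
        keep = np.abs(v - med) <= cfg.outlier_mad_multiplier * mad
    if not keep.any():
        return 0.0
    return float(v[keep].mean())


def normalization_factors(samples: pd.DataFrame) -> pd.Series:
    """Per-sample depth-normalization factors.

    Each sample's read count is divided by the read count of the largest
    sample, so every factor lies in (0, 1] and the deepest sample gets 1.
    """
    validate_samples(samples)
    reads = samples.set_index("sample_id")["total_reads"].astype(float)
    if (reads <= 0).any():
        bad = reads.index[reads <= 0].tolist()
        raise ValueError(f"samples with zero reads: {bad}")
    return reads / reads.max()


def normalized_coverage(non_outlier_mean_value: float, factor: float) -> float:
    """Depth-adjusted coverage: non-outlier mean divided by the sample factor."""
    if factor <= 0:
        raise ValueError(f"normalization factor must be positive, got {factor}")
    return non_outlier_mean_value / factor


def relative_abundance(
    mapped_reads: pd.DataFrame,
    samples: pd.DataFrame,
    genome_lengths: pd.Series,
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Length-normalized relative abundances, including an UNKNOWN bin.

    For each genome the fraction of a sample's non-human reads it
    recruited is divided by the genome length; reads recruited by no
    genome form the UNKNOWN bin, whose length is unknowable and is set
    to ``cfg.unknown_bin_length`` (default 2 Mbp).  The length-corrected
    values are renormalized so each sample column sums to 1.

    Parameters
    ----------
    mapped_reads
        Genome x sample read counts.
    samples
        Sample metadata with ``nonhuman_reads``.
    genome_lengths
        bp length per genome id (indexed like ``mapped_reads`` rows).
    """
    validate_samples(samples)
    nonhuman = samples.set_index("sample_id")["nonhuman_reads"].astype(float)
    nonhuman = nonhuman.reindex(mapped_reads.columns)
    if nonhuman.isna().any():
        raise ValueError(
            f"samples missing metadata: {nonhuman.index[nonhuman.isna()].tolist()}"
        )
    total_mapped = mapped_reads.sum(axis=0)
    over = total_mapped > nonhuman
    if over.any():
        raise ValueError(
            "mapped reads exceed non-human reads in samples: "
            f"{total_mapped.index[over].tolist()}"
        )
    lengths = genome_lengths.reindex(mapped_reads.index).astype(float)
    if lengths.isna().any():
        raise ValueError(
            f"genomes missing lengths: {lengths.index[lengths.isna()].tolist()}"
        )
    counts = mapped_reads.copy()
    counts.loc[UNKNOWN_BIN] = nonhuman - total_mapped
    lengths.loc[UNKNOWN_BIN] = float(cfg.unknown_bin_length)
    raw = counts.div(nonhuman, axis=1).div(lengths, axis=0)
    return raw.div(raw.sum(axis=0), axis=1)


def _site_of(samples: pd.DataFrame) -> pd.Series:
    return samples.set_index("sample_id")["site"]


def prevalence(
    presence: pd.DataFrame, samples: pd.DataFrame, level: str = "sample"
) -> pd.DataFrame:
    """Per-genome, per-site detection prevalence.

    At ``level="sample"`` this is the fraction of a site's samples in
    which the genome is present; at ``level="subject"`` a subject counts
    as positive at a site when the genome is present in at least one of
    that subject's samples from the site.
    """
    validate_samples(samples)
    unknown = set(presence.columns) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"presence matrix has unknown sample ids: {sorted(unknown)}")
    meta = samples.set_index("sample_id").loc[list(presence.columns)]
    if level == "sample":
        grouped = presence.T.groupby(meta["site"]).mean().T
    elif level == "subject":
        by_subject = (
            presence.T.groupby([meta["site"], meta["subject_id"]]).any().T
        )
        grouped = by_subject.T.groupby(level="site").mean().T
    else:
        raise ValueError(f"level must be 'sample' or 'subject', got {level!r}")
    grouped.columns.name = None
    return grouped


def site_association_test(
    presence_row: pd.Series, samples: pd.DataFrame, site_a: str, site_b: str
) -> tuple[float, int, float]:
    """Pearson chi-squared test of detection rates between two sites.

    Builds the 2x2 detected/not x site table and computes the Pearson
    statistic without continuity correction (1 df).  Degenerate margins
    (the genome detected everywhere or nowhere) give (0, 1, 1).
    """
    validate_samples(samples)
    site = _site_of(samples).reindex(presence_row.index)
    counts = {}
    for s in (site_a, site_b):
        mask = site == s
        if not mask.any():
            raise ValueError(f"no samples at site {s!r}")
        det = presence_row[mask].astype(bool)
        counts[s] = (int(det.sum()), int((~det).sum()))
    table = np.array([counts[site_a], counts[site_b]])
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), 1, float(p)


def classify_specificity(
    presence: pd.DataFrame, samples: pd.DataFrame, chi2_sites: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Classify each genome as site-specific, cosmopolitan, or not detected.

    A genome detected in one or more samples of exactly one site is a
    specialist for that site (``site_specific:<site>``); detection in
    two or more sites makes it cosmopolitan.  When the data contain
    exactly two sites (or ``chi2_sites`` is given), a chi-squared
    site-association test is attached per genome.
    """
    validate_samples(samples)
    meta = samples.set_index("sample_id").loc[list(presence.columns)]
    sites = sorted(meta["site"].unique())
    per_site = presence.T.groupby(meta["site"]).sum().T  # genome x site counts
    if chi2_sites is None and len(sites) == 2:
        chi2_sites = (sites[0], sites[1])

    rows = []
    for genome_id, counts in per_site.iterrows():
        positive = [s for s in sites if counts[s] > 0]
        if not positive:
            label = "not_detected"
        elif len(positive) == 1:
            label = f"site_specific:{positive[0]}"
        else:
            label = "cosmopolitan"
        row = {"genome_id": genome_id, "class": label}
        for s in sites:
            row[f"n_detected_{s}"] = int(counts[s])
        if chi2_sites is not None:
            chi2, _, p = site_association_test(
                presence.loc[genome_id], samples, *chi2_sites
            )
            row["chi2_stat"] = chi2
            row["chi2_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
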