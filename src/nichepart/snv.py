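"""Subpopulation detection from per-position allele counts.

A genome population recruited from several metagenomes can hide
habitat-specific subpopulations.  Positions with sufficient coverage in
*every* sample (strictly more than 20x by default) are assessed for
single-nucleotide variation: a position is *variable* within a sample
group when the frequency of the minor allele (the less-common base)
reaches 10% in at least one of the group's samples.  Groups with no
variable position are called monoclonal; groups with any are mixed.

Positions are 0-based within a named reference contig; tables exported
from 1-based coordinates must be shifted by the caller.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ThresholdConfig

__all__ = [
    "BASES",
    "filter_positions",
    "minor_allele_frequency",
    "call_variability",
    "classify_population",
]

BASES = ("A", "C", "G", "T")
SNV_COLUMNS = ("position", "sample_id", "coverage") + BASES


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNV_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"SNV table missing columns: {missing}")
    counts = records[list(BASES)].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative allele counts")
    if not np.array_equal(counts.sum(axis=1), records["coverage"].to_numpy()):
        raise ValueError("allele counts do not sum to coverage")
    return records


def filter_positions(
    records: pd.DataFrame, sample_set: Iterable[str], cfg: ThresholdConfig
) -> list[int]:
    """Positions with coverage strictly above ``snv_min_coverage`` in
    every sample of ``sample_set``.

    Every (position, sample) pair must be present in ``records``;
    missing pairs are an error rather than an implicit zero.
    """
    _check_records(records)
    samples = sorted(set(sample_set))
    if not samples:
        raise ValueError("sample set is empty")
    sub = records[records["sample_id"].isin(samples)]
    cov = sub.pivot_table(
        index="position", columns="sample_id", values="coverage", aggfunc="first"
    )
    missing_cols = set(samples) - set(cov.columns)
    if missing_cols:
        raise ValueError(f"samples absent from SNV table: {sorted(missing_cols)}")
    cov = cov[samples]
    if cov.isna().any().any():
        pos = cov.index[cov.isna().any(axis=1)][0]
        sample = cov.columns[cov.loc[pos].isna()][0]
        raise ValueError(f"missing record for position {pos}, sample {sample!r}")
    keep = (cov > cfg.snv_min_coverage).all(axis=1)
    return sorted(int(p) for p in cov.index[keep])


def minor_allele_frequency(allele_counts: Mapping[str, int] | np.ndarray) -> float:
    """Frequency of the second-most-frequent base.

    Ties are broken by the fixed base order A < C < G < T so results
    are deterministic.  For biallelic data this equals one minus the
    dominant-base frequency; with more than two alleles it is the
    frequency of the runner-up base specifically.
    """
    if isinstance(allele_counts, Mapping):
        counts = np.array([allele_counts.get(b, 0) for b in BASES], dtype=float)
    else:
        counts = np.asarray(allele_counts, dtype=float)
        if counts.size != 4:
            raise ValueError("expected counts for the four bases A, C, G, T")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero coverage at position")
    # stable sort on (count desc, base order asc)
    order = np.lexsort((np.arange(4), -counts))
    return float(counts[order[1]] / total)


def call_variability(
    records: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    cfg: ThresholdConfig,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position variability calls and per-group summaries.

    For each position and sample group, the group's minor-allele
    frequency is the maximum per-sample MAF over the group's samples
    (``pooled=True`` instead sums allele counts across the group's
    samples first).  A position is variable when that frequency reaches
    ``snv_maf_threshold``.

    Records should be pre-filtered with :func:`filter_positions` over
    the union of all groups' samples.

    Returns
    -------
    (calls, summary): ``calls`` has one row per (position, group) with
    ``max_maf`` and ``variable``; ``summary`` has one row per group with
    the variable-position count, the fraction of tested positions, and
    the median ``max_maf`` among variable positions (NaN when none).
    """
    _check_records(records)
    call_rows = []
    summary_rows = []
    for group in sorted(groups):
        sample_ids = sorted(set(groups[group]))
        if not sample_ids:
            raise ValueError(f"group {group!r} has no samples")
        sub = records[records["sample_id"].isin(sample_ids)]
        if sub.empty:
            raise ValueError(f"no records for samples of group {group!r}")
        counts = sub.groupby("position")[list(BASES)].sum() if pooled else None
        mafs: dict[int, float] = {}
        if pooled:
            for pos, row in counts.iterrows():
                mafs[int(pos)] = minor_allele_frequency(row.to_numpy())
        else:
            for row in sub.itertuples(index=False):
                maf = minor_allele_frequency(
                    np.array([row.A, row.C, row.G, row.T], dtype=float)
                )
                pos = int(row.position)
                if maf > mafs.get(pos, -1.0):
                    mafs[pos] = maf
        n_tested = len(mafs)
        n_variable = 0
        variable_mafs = []
        for pos in sorted(mafs):
            variable = mafs[pos] >= cfg.snv_maf_threshold
            if variable:
                n_variable += 1
                variable_mafs.append(mafs[pos])
            call_rows.append(
                {
                    "position": pos,
                    "group": group,
                    "max_maf": mafs[pos],
                    "variable": variable,
                }
            )
        summary_rows.append(
            {
                "group": group,
                "n_tested": n_tested,
                "n_variable": n_variable,
                "fraction_variable": n_variable / n_tested if n_tested else 0.0,
                "median_variable_maf": (
                    float(np.median(variable_mafs)) if variable_mafs else np.nan
                ),
            }
        )
    return pd.DataFrame(call_rows), pd.DataFrame(summary_rows)


def classify_population(summary: pd.DataFrame) -> pd.DataFrame:
    """Label each group monoclonal (no variable positions) or mixed."""
    if "n_variable" not in summary.columns:
        raise ValueError("summary must carry an 'n_variable' column")
    return pd.DataFrame(
        {
            "group": summary["group"],
            "population": np.where(
                summary["n_variable"] > 0, "mixed", "monoclonal"
            ),
        }
    )
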