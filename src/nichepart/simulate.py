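"""Synthetic study generator with planted ground truth.

Every input table the analysis stages consume can be generated here
with known truth, so the whole pipeline is testable without external
data.  The default :class:`SimulationSpec` emulates the statistical
structure of the study design this package targets: seven subjects
sampled at two oral sites (tongue and plaque) on five days; genome
populations that are mostly site specialists with a few cosmopolitan
or absent ones; near-identical genome bins planted as redundancy
groups at >= 99.8% ANI; a pangenome with core, clade-specific, and
singleton gene clusters whose annotation rates fall from >90% (core)
to 29% (singletons); and a two-habitat SNV table where one habitat is
monoclonal and the other hides a 40% subpopulation at ~2% of the
well-covered positions.

Coverage depth is Poisson — the simplest model sufficient to exercise
detection thresholds — and nonspecific read recruitment is modeled as
a random fraction of singly covered positions.  Genome lengths default
to 20-50 kb: detection and coverage statistics are length-invariant in
expectation, and this scale keeps per-position simulation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .coverage import non_outlier_mean

__all__ = [
    "SimulationSpec",
    "CohortSim",
    "CoverageSim",
    "AniSim",
    "PangenomeSim",
    "SnvSim",
    "simulate_cohort",
    "simulate_coverage",
    "simulate_ani",
    "simulate_pangenome",
    "simulate_snv_table",
]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults emulate the target design."""

    # cohort
    n_subjects: int = 7
    samples_per_subject_per_site: int = 5
    sites: Sequence[str] = ("tongue", "plaque")
    n_genomes: int = 30
    genome_length_range: tuple[int, int] = (20_000, 50_000)
    site_occupancy: Mapping[str, Mapping[str, float]] | None = None
    occupancy_present: float = 0.9  # per-sample presence probability of a specialist
    # coverage
    coverage_depth_mean: float = 20.0
    nonspecific_mapping_fraction: float = 0.05
    # dereplication
    n_redundancy_groups: int = 3
    redundancy_group_size: int = 3
    within_group_ani_range: tuple[float, float] = (99.85, 99.98)
    # pangenome
    n_clades: int = 4
    genomes_per_clade: int = 10
    n_core_gcs: int = 205
    n_clade_gcs_per_clade: int = 60
    n_singleton_gcs: int = 500
    p_in: float = 0.9
    p_out: float = 0.1
    annotation_rate_core: float = 0.9
    annotation_rate_accessory: float = 0.55
    annotation_rate_singleton: float = 0.29
    # SNVs
    n_snv_positions: int = 2_000
    snv_variable_fraction: float = 0.02
    subpop_frequency: float = 0.40
    snv_depth_mean: float = 100.0
    snv_samples_per_group: int = 6
    sequencing_error_rate: float = 0.01
    third_allele: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "occupancy_present", "nonspecific_mapping_fraction", "p_in", "p_out",
            "annotation_rate_core", "annotation_rate_accessory",
            "annotation_rate_singleton", "snv_variable_fraction",
            "sequencing_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if not 0.0 <= self.subpop_frequency <= 0.5:
            raise ValueError("subpop_frequency must be in [0, 0.5]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for planted enrichment")
        for name in (
            "n_subjects", "samples_per_subject_per_site", "n_genomes",
            "n_clades", "genomes_per_clade", "n_snv_positions",
            "snv_samples_per_group",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_redundancy_groups < 0 or self.redundancy_group_size < 2:
            raise ValueError("invalid redundancy-group layout")
        if self.n_redundancy_groups * self.redundancy_group_size > self.n_genomes:
            raise ValueError("redundancy groups exceed genome count")
        lo, hi = self.within_group_ani_range
        if not (99.8 <= lo <= hi <= 100.0):
            raise ValueError("within_group_ani_range must lie within [99.8, 100]")
        if not 1 <= self.genome_length_range[0] <= self.genome_length_range[1]:
            raise ValueError("invalid genome_length_range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


class CohortSim(NamedTuple):
    samples: pd.DataFrame
    genomes: pd.DataFrame
    truth: pd.DataFrame
    occupancy: dict[str, dict[str, float]]


class CoverageSim(NamedTuple):
    detection: pd.DataFrame
    non_outlier_mean: pd.DataFrame
    mapped_reads: pd.DataFrame
    presence_truth: pd.DataFrame
    vectors: dict[str, pd.DataFrame] | None


class AniSim(NamedTuple):
    pairs: pd.DataFrame
    truth: pd.DataFrame


class PangenomeSim(NamedTuple):
    gene_clusters: pd.DataFrame
    annotations: pd.DataFrame
    groups: pd.DataFrame
    truth: pd.DataFrame


class SnvSim(NamedTuple):
    records: pd.DataFrame
    groups: pd.DataFrame
    truth: pd.DataFrame


def _default_occupancy(spec: SimulationSpec) -> dict[str, dict[str, float]]:
    """Mostly specialists, a few cosmopolitan and absent genomes.

    With the default 30 genomes and two sites: 12 specialists per site,
    4 cosmopolitan, 2 absent everywhere.
    """
    n = spec.n_genomes
    sites = list(spec.sites)
    ids = [f"g{i:03d}" for i in range(1, n + 1)]
    n_specialist_total = int(round(0.8 * n))
    per_site = n_specialist_total // len(sites)
    n_cosmo = max(0, int(round(0.13 * n)))
    occupancy: dict[str, dict[str, float]] = {}
    k = 0
    for site in sites:
        for _ in range(per_site):
            if k >= n:
                break
            occupancy[ids[k]] = {
                s: (spec.occupancy_present if s == site else 0.0) for s in sites
            }
            k += 1
    for _ in range(n_cosmo):
        if k >= n:
            break
        occupancy[ids[k]] = {s: spec.occupancy_present for s in sites}
        k += 1
    while k < n:  # remainder: absent everywhere
        occupancy[ids[k]] = {s: 0.0 for s in sites}
        k += 1
    return occupancy


def _truth_class(occ: Mapping[str, float]) -> str:
    positive = [s for s, p in occ.items() if p > 0]
    if not positive:
        return "not_detected"
    if len(positive) == 1:
        return f"site_specific:{positive[0]}"
    return "cosmopolitan"


def simulate_cohort(spec: SimulationSpec) -> CohortSim:
    """Sample metadata, genome records, and per-genome truth labels.

    Deterministic given ``spec.seed``.  Subject read depths emulate
    shotgun metagenomes of ~15-30 M reads with 5-45% human
    contamination.
    """
    if spec.n_genomes < 1 or spec.n_subjects < 1:
        raise ValueError("need at least one genome and one subject")
    rng = spec.rng(1)
    sample_rows = []
    for i in range(1, spec.n_subjects + 1):
        subject = f"subj{i:02d}"
        for site in spec.sites:
            for day in range(1, spec.samples_per_subject_per_site + 1):
                total = int(rng.integers(15_000_000, 30_000_000))
                human_fraction = rng.uniform(0.05, 0.45)
                sample_rows.append(
                    {
                        "sample_id": f"{subject}_{site}_d{day}",
                        "subject_id": subject,
                        "site": site,
                        "total_reads": total,
                        "nonhuman_reads": int(total * (1.0 - human_fraction)),
                    }
                )
    samples = pd.DataFrame(sample_rows)

    occupancy = {
        g: dict(o) for g, o in (spec.site_occupancy or _default_occupancy(spec)).items()
    }
    genome_rows = []
    for gid in occupancy:
        genome_rows.append(
            {
                "genome_id": gid,
                "length": int(rng.integers(*spec.genome_length_range, endpoint=True)),
                "completion": float(np.round(rng.uniform(70, 100), 2)),
                "redundancy": float(np.round(rng.uniform(0, 9), 2)),
            }
        )
    genomes = pd.DataFrame(genome_rows)
    truth = pd.DataFrame(
        {
            "genome_id": list(occupancy),
            "truth_class": [_truth_class(occupancy[g]) for g in occupancy],
        }
    )
    return CohortSim(samples, genomes, truth, occupancy)


def simulate_coverage(
    spec: SimulationSpec,
    cohort: CohortSim,
    keep_vectors: bool = False,
    cfg: ThresholdConfig | None = None,
) -> CoverageSim:
    """Per-genome, per-sample coverage with planted presence.

    When a genome is present in a sample, per-position coverage is
    i.i.d. Poisson(``coverage_depth_mean``); when absent, a random
    ``nonspecific_mapping_fraction`` of positions receive coverage 1
    (spurious recruitment).  Detection of present genomes therefore
    concentrates near ``1 - exp(-depth)`` ~ 1, and of absent genomes
    near the nonspecific fraction, well below any presence threshold.

    Set ``keep_vectors=True`` to retain the position x sample coverage
    matrices (memory grows with genome length x sample count).
    """
    cfg = cfg or ThresholdConfig()
    rng = spec.rng(2)
    sample_ids = cohort.samples["sample_id"].tolist()
    site_of = cohort.samples.set_index("sample_id")["site"]
    genome_ids = cohort.genomes["genome_id"].tolist()
    lengths = cohort.genomes.set_index("genome_id")["length"]

    detection = pd.DataFrame(index=genome_ids, columns=sample_ids, dtype=float)
    nom = pd.DataFrame(index=genome_ids, columns=sample_ids, dtype=float)
    mapped = pd.DataFrame(index=genome_ids, columns=sample_ids, dtype=float)
    presence = pd.DataFrame(index=genome_ids, columns=sample_ids, dtype=bool)
    vectors: dict[str, pd.DataFrame] | None = {} if keep_vectors else None

    for gid in genome_ids:
        L = int(lengths[gid])
        occ = cohort.occupancy[gid]
        present = np.array(
            [rng.random() < occ[site_of[s]] for s in sample_ids], dtype=bool
        )
        mat = np.zeros((L, len(sample_ids)), dtype=np.int64)
        if present.any():
            mat[:, present] = rng.poisson(
                spec.coverage_depth_mean, size=(L, int(present.sum()))
            )
        if (~present).any():
            mat[:, ~present] = (
                rng.random((L, int((~present).sum())))
                < spec.nonspecific_mapping_fraction
            ).astype(np.int64)
        detection.loc[gid] = np.count_nonzero(mat, axis=0) / L
        nom.loc[gid] = [non_outlier_mean(mat[:, j], cfg) for j in range(len(sample_ids))]
        mapped.loc[gid] = mat.sum(axis=0)
        presence.loc[gid] = present
        if keep_vectors:
            vectors[gid] = pd.DataFrame(mat, columns=sample_ids)
    for df in (detection, nom, mapped, presence):
        df.index.name = "genome_id"
    return CoverageSim(detection, nom, mapped, presence, vectors)


def simulate_ani(spec: SimulationSpec, genomes: pd.DataFrame) -> AniSim:
    """Pairwise ANI table with planted redundancy groups.

    The first ``n_redundancy_groups * redundancy_group_size`` genomes
    form the planted groups.  Within a group every pair satisfies the
    redundancy rule (ANI in ``within_group_ani_range``, alignment
    fraction of the shorter genome >= 0.5); all other pairs fail it,
    either by ANI below 99.8 or — for a random tenth of them — by high
    ANI with insufficient alignment fraction.
    """
    rng = spec.rng(3)
    ids = genomes["genome_id"].astype(str).tolist()
    k = spec.n_redundancy_groups * spec.redundancy_group_size
    if k > len(ids):
        raise ValueError("not enough genomes for the planted groups")
    group_of: dict[str, int] = {}
    truth_rows = []
    for g in range(spec.n_redundancy_groups):
        members = ids[g * spec.redundancy_group_size : (g + 1) * spec.redundancy_group_size]
        for gid in members:
            group_of[gid] = g
            truth_rows.append({"genome_id": gid, "truth_group": f"tgroup_{g + 1:03d}"})
    lo, hi = spec.within_group_ani_range
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            same = a in group_of and b in group_of and group_of[a] == group_of[b]
            if same:
                ani = float(rng.uniform(lo, hi)) if hi > lo else lo
                frac = float(rng.uniform(0.5, 0.95))
            elif rng.random() < 0.1:
                # near-identical but poorly aligned: must not form an edge
                ani = float(rng.uniform(99.8, 100.0))
                frac = float(rng.uniform(0.05, 0.45))
            else:
                ani = float(rng.uniform(90.0, 99.6))
                frac = float(rng.uniform(0.05, 0.95))
            rows.append(
                {
                    "genome_a": a,
                    "genome_b": b,
                    "ani": ani,
                    "alignment_fraction_shorter": frac,
                }
            )
    return AniSim(pd.DataFrame(rows), pd.DataFrame(truth_rows))


def simulate_pangenome(spec: SimulationSpec) -> PangenomeSim:
    """Gene-cluster matrix, annotations, clade map, and enrichment truth.

    Core GCs occur in every genome; each clade's accessory GCs occur
    with probability ``p_in`` inside and ``p_out`` outside the clade;
    singleton GCs occur in exactly one genome.  Annotations are drawn
    at the per-category rates, each annotated GC carrying its own
    function accession (every tenth core annotation reuses the previous
    accession so some functions span two GCs).  Functions annotating
    clade-specific GCs are recorded as truth-enriched.
    """
    rng = spec.rng(4)
    genome_ids = [f"p{i:03d}" for i in range(1, spec.n_clades * spec.genomes_per_clade + 1)]
    clade_of = {
        gid: f"clade{(i // spec.genomes_per_clade) + 1}"
        for i, gid in enumerate(genome_ids)
    }
    clades = [f"clade{c + 1}" for c in range(spec.n_clades)]
    n_genomes = len(genome_ids)

    gc_rows: dict[str, np.ndarray] = {}
    ann_rows = []
    truth_rows = []

    core_ids = [f"GC_core_{i:05d}" for i in range(1, spec.n_core_gcs + 1)]
    last_core_accession = None
    for i, gc in enumerate(core_ids):
        gc_rows[gc] = np.ones(n_genomes, dtype=np.int64)
        if rng.random() < spec.annotation_rate_core:
            if last_core_accession is not None and (i + 1) % 10 == 0:
                accession = last_core_accession  # shared across two GCs
            else:
                accession = f"COG_core_{i + 1:05d}"
            ann_rows.append({"gene_cluster_id": gc, "accession": accession})
            last_core_accession = accession

    clade_mask = {c: np.array([clade_of[g] == c for g in genome_ids]) for c in clades}
    for c in clades:
        for i in range(1, spec.n_clade_gcs_per_clade + 1):
            gc = f"GC_{c}_{i:05d}"
            occ = np.where(
                clade_mask[c],
                rng.random(n_genomes) < spec.p_in,
                rng.random(n_genomes) < spec.p_out,
            ).astype(np.int64)
            if occ.sum() == 0:  # every GC must occur somewhere
                occ[np.flatnonzero(clade_mask[c])[0]] = 1
            gc_rows[gc] = occ
            if rng.random() < spec.annotation_rate_accessory:
                accession = f"COG_{c}_{i:05d}"
                ann_rows.append({"gene_cluster_id": gc, "accession": accession})
                truth_rows.append(
                    {"accession": accession, "truth_clade": c, "truth_enriched": True}
                )

    for i in range(1, spec.n_singleton_gcs + 1):
        gc = f"GC_sing_{i:05d}"
        occ = np.zeros(n_genomes, dtype=np.int64)
        occ[(i - 1) % n_genomes] = 1
        gc_rows[gc] = occ
        if rng.random() < spec.annotation_rate_singleton:
            ann_rows.append(
                {"gene_cluster_id": gc, "accession": f"COG_sing_{i:05d}"}
            )

    gene_clusters = pd.DataFrame.from_dict(gc_rows, orient="index", columns=genome_ids)
    gene_clusters.index.name = "gene_cluster_id"
    groups = pd.DataFrame(
        {"genome_id": genome_ids, "group": [clade_of[g] for g in genome_ids]}
    )
    return PangenomeSim(
        gene_clusters,
        pd.DataFrame(ann_rows, columns=["gene_cluster_id", "accession"]),
        groups,
        pd.DataFrame(truth_rows, columns=["accession", "truth_clade", "truth_enriched"]),
    )


def simulate_snv_table(spec: SimulationSpec) -> SnvSim:
    """Per-position allele counts for a monoclonal and a mixed habitat.

    Every sample's coverage at a position is Poisson(``snv_depth_mean``)
    conditioned to be >= 1.  Monoclonal samples draw the reference base
    with probability 1 - error; in the mixed group, a planted fraction
    of positions carries a subpopulation allele at frequency
    ``subpop_frequency``.  With ``third_allele`` a second alternative
    base joins at half the subpopulation frequency to exercise the
    multi-allele minor-frequency rule.
    """
    rng = spec.rng(5)
    bases = ["A", "C", "G", "T"]
    groups = {
        "mixed": [f"mx_s{i:02d}" for i in range(1, spec.snv_samples_per_group + 1)],
        "monoclonal": [f"mc_s{i:02d}" for i in range(1, spec.snv_samples_per_group + 1)],
    }
    n_planted = int(round(spec.n_snv_positions * spec.snv_variable_fraction))
    planted = set(
        rng.choice(spec.n_snv_positions, size=n_planted, replace=False).tolist()
    )
    e = spec.sequencing_error_rate
    f = spec.subpop_frequency
    rows = []
    truth_rows = []
    for pos in range(spec.n_snv_positions):
        ref, alt, alt2 = rng.choice(4, size=3, replace=False)
        is_planted = pos in planted
        truth_rows.append(
            {
                "position": pos,
                "planted_variable": is_planted,
                "true_minor_frequency": f if is_planted else 0.0,
            }
        )
        for group, sample_ids in groups.items():
            mixed_here = is_planted and group == "mixed"
            probs = np.full(4, e / 3.0)
            if mixed_here:
                f2 = f / 2.0 if spec.third_allele else 0.0
                probs[ref] = (1.0 - f - f2) * (1.0 - e) + (f + f2) * e / 3.0
                probs[alt] = f * (1.0 - e) + (1.0 - f) * e / 3.0
                if spec.third_allele:
                    probs[alt2] = f2 * (1.0 - e) + (1.0 - f2) * e / 3.0
            else:
                probs[ref] = 1.0 - e
            probs /= probs.sum()
            for sid in sample_ids:
                cov = 0
                while cov < 1:
                    cov = int(rng.poisson(spec.snv_depth_mean))
                counts = rng.multinomial(cov, probs)
                rows.append(
                    {
                        "contig": "contig_1",
                        "position": pos,
                        "sample_id": sid,
                        "coverage": cov,
                        **{b: int(counts[j]) for j, b in enumerate(bases)},
                    }
                )
    records = pd.DataFrame(rows)
    group_table = pd.DataFrame(
        [
            {"sample_id": sid, "group": g}
            for g, sids in groups.items()
            for sid in sids
        ]
    )
    return SnvSim(records, group_table, pd.DataFrame(truth_rows))
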