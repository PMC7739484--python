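"""Collapse near-identical genome bins into redundancy groups.

Independent assembly and binning of metagenomes from similar habitats
recovers multiple near-identical genomes.  Two bins are treated as
redundant when their average nucleotide identity (ANI) is at least
99.8% over an alignment covering at least half of the shorter genome;
redundancy groups are the connected components of the resulting graph,
and each group is represented by the member with the highest
"completion minus redundancy" (ties: longest genome, then smallest id).
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .config import ThresholdConfig

__all__ = ["filter_bins", "redundancy_edges", "dereplicate", "choose_representative"]

GENOME_COLUMNS = ("genome_id", "length", "completion", "redundancy")


def filter_bins(
    genomes: pd.DataFrame, min_length: float = 500_000, max_scg_redundancy: float = 10.0
) -> pd.DataFrame:
    """Keep bins of length >= ``min_length`` bp with single-copy-core-gene
    redundancy strictly below ``max_scg_redundancy`` percent."""
    keep = (genomes["length"] >= min_length) & (
        genomes["redundancy"] < max_scg_redundancy
    )
    return genomes[keep].reset_index(drop=True)


def redundancy_edges(
    pairs: pd.DataFrame, cfg: ThresholdConfig
) -> list[tuple[str, str]]:
    """Pairs that satisfy the redundancy rule.

    A pair qualifies when ``ani >= ani_redundancy_threshold`` (percent)
    and ``alignment_fraction_shorter >= ani_min_alignment_fraction_shorter``
    — both inclusive.  Self-pairs are ignored with a warning.
    """
    edges: list[tuple[str, str]] = []
    for row in pairs.itertuples(index=False):
        a, b = str(row.genome_a), str(row.genome_b)
        if a == b:
            warnings.warn(f"ignoring self-pair for genome {a!r}", stacklevel=2)
            continue
        if (
            row.ani >= cfg.ani_redundancy_threshold
            and row.alignment_fraction_shorter >= cfg.ani_min_alignment_fraction_shorter
        ):
            edges.append((a, b))
    return edges


def choose_representative(members: pd.DataFrame) -> str:
    """Representative of a redundancy group.

    Maximizes completion minus redundancy; ties broken by greater
    length, remaining ties by lexicographically smallest genome id.
    """
    members = members.reset_index(drop=True)
    ranked = members.assign(
        _quality=members["completion"] - members["redundancy"]
    ).sort_values(
        by=["_quality", "length", "genome_id"], ascending=[False, False, True]
    )
    return str(ranked["genome_id"].iloc[0])


def dereplicate(
    genomes: pd.DataFrame, pairs: pd.DataFrame, cfg: ThresholdConfig
) -> tuple[list[str], pd.DataFrame]:
    """Resolve redundancy groups and select representatives.

    Parameters
    ----------
    genomes
        Table with columns ``genome_id``, ``length``, ``completion``,
        ``redundancy``.
    pairs
        ANI table with columns ``genome_a``, ``genome_b``, ``ani``,
        ``alignment_fraction_shorter``.

    Returns
    -------
    (non_redundant_ids, groups) where ``groups`` has one row per member
    of a multi-genome group with columns ``group_id``, ``genome_id``,
    ``representative``, ``is_representative``.  The non-redundant set is
    sorted: singletons plus one representative per group.
    """
    missing = [c for c in GENOME_COLUMNS if c not in genomes.columns]
    if missing:
        raise ValueError(f"genome table missing columns: {missing}")
    ids = genomes["genome_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate genome_id in genome table")
    known = set(ids)
    referenced = set(pairs["genome_a"].astype(str)) | set(pairs["genome_b"].astype(str))
    unknown = referenced - known
    if unknown:
        raise ValueError(f"ANI pairs reference unknown genomes: {sorted(unknown)}")

    graph = nx.Graph()
    graph.add_nodes_from(known)
    graph.add_edges_from(redundancy_edges(pairs, cfg))

    by_id = genomes.assign(genome_id=ids).set_index("genome_id", drop=False)
    nonredundant: list[str] = []
    group_rows = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    group_number = 0
    for component in components:
        if len(component) == 1:
            nonredundant.append(component[0])
            continue
        group_number += 1
        members = by_id.loc[component]
        rep = choose_representative(members)
        nonredundant.append(rep)
        for gid in component:
            group_rows.append(
                {
                    "group_id": f"group_{group_number:04d}",
                    "genome_id": gid,
                    "representative": rep,
                    "is_representative": gid == rep,
                }
            )
    groups = pd.DataFrame(
        group_rows, columns=["group_id", "genome_id", "representative", "is_representative"]
    )
    return sorted(nonredundant), groups
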