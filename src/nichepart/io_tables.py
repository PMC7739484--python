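"""Tabular I/O for every pipeline artifact, plus the pipeline driver.

All artifacts are plain TSV with a mandatory header.  Matrices are
accepted both *wide* (rows = entities, columns = samples) and *long*
(``row_id``, ``col_id``, ``value`` triplets); readers and writers are
exact inverses on valid inputs.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ThresholdConfig, read_samples

__all__ = ["read_matrix", "write_matrix", "run_pipeline", "PIPELINE_STAGES"]

LONG_COLUMNS = ("row_id", "col_id", "value")

PIPELINE_STAGES = ("simulate", "detect", "derep", "enrich", "snv")


def read_matrix(path: str | Path, orientation: str = "wide") -> pd.DataFrame:
    """Read a labeled numeric matrix from TSV.

    Parameters
    ----------
    path
        TSV file with a header row.
    orientation
        ``"wide"``: first column holds row labels, remaining columns are
        numeric.  ``"long"``: exactly the columns ``row_id``, ``col_id``,
        ``value``; duplicated (row, col) pairs are rejected.

    Returns
    -------
    DataFrame with row index = entity labels and columns = sample labels.
    """
    if orientation == "wide":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns.name = None
        for col in df.columns:
            values = pd.to_numeric(df[col], errors="coerce")
            bad = values.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                )
            if values.isna().any():
                row = df.index[values.isna().to_numpy().nonzero()[0][0]]
                raise ValueError(f"missing cell at row {row!r}, column {col!r} in {path}")
            df[col] = values
        return df.astype(float)
    if orientation == "long":
        df = pd.read_csv(path, sep="\t", dtype={"row_id": str, "col_id": str})
        if list(df.columns) != list(LONG_COLUMNS):
            raise ValueError(
                f"long matrix must have columns {LONG_COLUMNS}, got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["row_id", "col_id"])
        if dup.any():
            r, c = df.loc[dup.idxmax(), ["row_id", "col_id"]]
            raise ValueError(f"duplicate (row, column) pair ({r!r}, {c!r}) in {path}")
        values = pd.to_numeric(df["value"], errors="coerce")
        if values.isna().any():
            i = int(values.isna().to_numpy().nonzero()[0][0])
            raise ValueError(
                f"non-numeric or missing value at (row {df['row_id'].iat[i]!r}, "
                f"column {df['col_id'].iat[i]!r}) in {path}"
            )
        df["value"] = values
        wide = df.pivot(index="row_id", columns="col_id", values="value")
        if wide.isna().any().any():
            raise ValueError(f"long matrix in {path} is not a complete grid")
        wide.index.name = None
        wide.columns.name = None
        # preserve first-appearance order
        wide = wide.loc[
            pd.unique(df["row_id"]),
            pd.unique(df["col_id"]),
        ]
        return wide.astype(float)
    raise ValueError(f"orientation must be 'wide' or 'long', got {orientation!r}")


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, orientation: str = "wide"
) -> None:
    """Write a labeled matrix to TSV; inverse of :func:`read_matrix`."""
    matrix = matrix.copy()
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    if orientation == "wide":
        out = matrix.copy()
        out.index.name = out.index.name or "id"
        out.to_csv(path, sep="\t", float_format="%.10g")
    elif orientation == "long":
        long = matrix.stack().rename("value").reset_index()
        long.columns = list(LONG_COLUMNS)
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"orientation must be 'wide' or 'long', got {orientation!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(inputs: Mapping[str, str | Path], stage: str, names: Iterable[str]) -> None:
    for name in names:
        if name not in inputs:
            raise ValueError(f"stage {stage!r} requires input {name!r}")
        if not Path(inputs[name]).exists():
            raise FileNotFoundError(
                f"stage {stage!r}: input {name!r} not found at {inputs[name]}"
            )


def run_pipeline(
    config: ThresholdConfig,
    inputs: Mapping[str, str | Path],
    stages: Iterable[str],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Run the requested stages and write one TSV per stage product.

    Outputs are a pure function of (inputs, config, seed).  A
    ``run_log.json`` records the configuration, the seed, a SHA-256
    checksum of every input file, and per-stage output row counts.

    Parameters
    ----------
    config
        Thresholds for every stage.
    inputs
        Map of input name -> TSV path.  Stage requirements:
        ``detect``: ``coverage`` (detection matrix genome x sample, or a
        per-position coverage table), ``samples``; ``derep``:
        ``genomes``, ``ani``; ``enrich``: ``gene_clusters``,
        ``annotations``, ``groups``; ``snv``: ``snv``, ``snv_groups``;
        ``simulate``: none.
    stages
        Subset of :data:`PIPELINE_STAGES`.
    out_dir
        Output directory, created if needed.
    seed
        Overrides ``config.random_seed`` for the simulate stage.

    Returns
    -------
    Map of stage -> list of files written.
    """
    from . import coverage as cov
    from . import dereplication as derep_mod
    from . import enrichment as enrich_mod
    from . import simulate as sim_mod
    from . import snv as snv_mod

    stages = list(stages)
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.random_seed if seed is None else seed
    inputs = dict(inputs)
    written: dict[str, list[str]] = {}
    row_counts: dict[str, dict[str, int]] = {}

    def save(stage: str, name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        if index:
            df = df.copy()
            df.index = df.index.astype(str)
            df.index.name = df.index.name or "id"
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        written.setdefault(stage, []).append(str(path))
        row_counts.setdefault(stage, {})[name] = int(df.shape[0])

    for stage in stages:
        if stage == "simulate":
            spec = sim_mod.SimulationSpec(seed=seed)
            cohort = sim_mod.simulate_cohort(spec)
            save("simulate", "samples", cohort.samples)
            save("simulate", "genomes", cohort.genomes)
            save("simulate", "truth_genomes", cohort.truth)
            covsim = sim_mod.simulate_coverage(spec, cohort)
            save("simulate", "detection", covsim.detection, index=True)
            save("simulate", "coverage", covsim.non_outlier_mean, index=True)
            save("simulate", "mapped_reads", covsim.mapped_reads, index=True)
            ani = sim_mod.simulate_ani(spec, cohort.genomes)
            save("simulate", "ani", ani.pairs)
            save("simulate", "truth_redundancy_groups", ani.truth)
            pan = sim_mod.simulate_pangenome(spec)
            save("simulate", "gene_clusters", pan.gene_clusters, index=True)
            save("simulate", "annotations", pan.annotations)
            save("simulate", "genome_groups", pan.groups)
            save("simulate", "truth_enriched_functions", pan.truth)
            snvsim = sim_mod.simulate_snv_table(spec)
            save("simulate", "snv", snvsim.records)
            save("simulate", "snv_groups", snvsim.groups)
            save("simulate", "truth_snv_positions", snvsim.truth)
            # downstream stages may consume simulated outputs directly
            for name in (
                "samples", "detection", "coverage", "mapped_reads", "ani",
                "genomes", "gene_clusters", "annotations", "snv",
            ):
                inputs.setdefault(name, out / f"{name}.tsv")
            inputs.setdefault("groups", out / "genome_groups.tsv")
            inputs.setdefault("snv_groups", out / "snv_groups.tsv")
        elif stage == "detect":
            _require(inputs, stage, ("coverage", "samples"))
            detection_source = inputs.get("detection", inputs["coverage"])
            detection = read_matrix(detection_source, "wide")
            samples = read_samples(inputs["samples"])
            presence = cov.call_presence_matrix(detection, config)
            save("detect", "presence", presence.astype(int), index=True)
            calls = cov.classify_specificity(presence, samples)
            save("detect", "specificity_calls", calls)
            prev = cov.prevalence(presence, samples, level="sample")
            save("detect", "prevalence_sample", prev, index=True)
            prev_subj = cov.prevalence(presence, samples, level="subject")
            save("detect", "prevalence_subject", prev_subj, index=True)
        elif stage == "derep":
            _require(inputs, stage, ("genomes", "ani"))
            genomes = pd.read_csv(inputs["genomes"], sep="\t")
            pairs = pd.read_csv(inputs["ani"], sep="\t")
            nonredundant, groups = derep_mod.dereplicate(genomes, pairs, config)
            save("derep", "nonredundant_genomes",
                 pd.DataFrame({"genome_id": nonredundant}))
            save("derep", "redundancy_groups", groups)
        elif stage == "enrich":
            _require(inputs, stage, ("gene_clusters", "annotations", "groups"))
            gc = read_matrix(inputs["gene_clusters"], "wide")
            ann = pd.read_csv(inputs["annotations"], sep="\t")
            groups_df = pd.read_csv(inputs["groups"], sep="\t")
            groups = groups_df.set_index(groups_df.columns[0])[
                groups_df.columns[1]
            ]
            occurrence = enrich_mod.build_function_occurrence(gc, ann)
            save("enrich", "function_occurrence", occurrence.astype(int), index=True)
            results = enrich_mod.enrichment_analysis(occurrence, groups, config)
            save("enrich", "enrichment_results", results)
        elif stage == "snv":
            _require(inputs, stage, ("snv", "snv_groups"))
            records = pd.read_csv(inputs["snv"], sep="\t")
            gdf = pd.read_csv(inputs["snv_groups"], sep="\t")
            groups = {
                g: set(sub["sample_id"]) for g, sub in gdf.groupby("group")
            }
            all_samples = set(gdf["sample_id"])
            kept = snv_mod.filter_positions(records, all_samples, config)
            records = records[records["position"].isin(kept)]
            calls, summary = snv_mod.call_variability(records, groups, config)
            labels = snv_mod.classify_population(summary)
            summary = summary.merge(labels, on="group")
            save("snv", "variability_calls", calls)
            save("snv", "group_summary", summary)

    log = {
        "config": config.to_dict(),
        "seed": seed,
        "stages": stages,
        "input_checksums": {
            name: _sha256(Path(p)) for name, p in inputs.items() if Path(p).exists()
        },
        "row_counts": row_counts,
    }
    log_path = out / "run_log.json"
    with io.open(log_path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    written.setdefault("log", []).append(str(log_path))
    return written
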