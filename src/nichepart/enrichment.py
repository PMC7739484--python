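"""Pangenome functional-enrichment analysis.

Gene clusters (GCs) group homologous genes across the genomes of a
pangenome, but the same *function* (e.g., a COG accession) can occur in
several distinct GCs.  To ask which functions distinguish groups of
genomes — for example phylogenomic clades — each function's occurrence
across genomes is modeled as a binomial GLM with group membership as
the categorical predictor, and equality of occurrence proportions is
tested with a Rao score test.  For an intercept-only null fit the score
statistic has the closed form

    score = sum_k n_k (p_k - p)^2 / (p (1 - p)),    df = K - 1,

with group sizes ``n_k``, group occurrence proportions ``p_k``, and the
pooled proportion ``p``; this equals the Pearson chi-squared statistic
of the 2 x K presence/absence-by-group table.  Per-function p-values
are converted to q-values (Storey's method by default) to control the
false discovery rate, and functions present in (nearly) all genomes are
flagged as the functional core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig

__all__ = [
    "build_function_occurrence",
    "rao_score_test",
    "rao_score_matrix",
    "estimate_qvalues",
    "classify_core",
    "enrichment_analysis",
]

ANNOTATION_COLUMNS = ("gene_cluster_id", "accession")


def build_function_occurrence(
    gc_matrix: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a GC x genome count matrix to a function x genome
    binary occurrence matrix.

    A function is present in a genome iff at least one gene cluster
    annotated with that function has a nonzero count there (union
    semantics).  Functions whose annotated GCs occur in no genome are
    dropped.  Unannotated GCs are allowed and contribute nothing.

    Parameters
    ----------
    gc_matrix
        Gene-cluster x genome gene counts.
    annotations
        Long table with columns ``gene_cluster_id``, ``accession`` (one
        row per GC/function link; a GC may carry several functions).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    ann = annotations.astype({c: str for c in ANNOTATION_COLUMNS})
    unknown = set(ann["gene_cluster_id"]) - set(gc_matrix.index.astype(str))
    if unknown:
        raise ValueError(
            f"annotations reference unknown gene clusters: {sorted(unknown)[:5]}"
        )
    present = (gc_matrix >= 1)
    present.index = present.index.astype(str)
    rows = {}
    for accession, sub in ann.groupby("accession", sort=True):
        occ = present.loc[sub["gene_cluster_id"].unique()].any(axis=0)
        if occ.any():
            rows[accession] = occ
    if not rows:
        return pd.DataFrame(columns=gc_matrix.columns, dtype=bool)
    out = pd.DataFrame(rows).T
    out.index.name = "accession"
    return out


def rao_score_test(
    presence: np.ndarray, groups: np.ndarray
) -> tuple[float, int, float]:
    """Rao score test of equal occurrence proportions across groups.

    Parameters
    ----------
    presence
        Binary vector over genomes.
    groups
        Group label per genome (K >= 2 distinct labels, each nonempty).

    Returns
    -------
    (score, df, p) with df = K - 1 and p from the upper tail of the
    chi-squared distribution.  A degenerate pooled proportion (all
    present or all absent) yields (0, df, 1).
    """
    y = np.asarray(presence, dtype=float)
    labels = np.asarray(groups)
    if y.shape != labels.shape:
        raise ValueError("presence and groups must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("presence vector must be binary")
    uniq, inverse = np.unique(labels, return_inverse=True)
    K = uniq.size
    if K < 2:
        raise ValueError("need at least two groups")
    n_k = np.bincount(inverse, minlength=K).astype(float)
    if (n_k == 0).any():
        raise ValueError("every group must be nonempty")
    df = K - 1
    p_bar = y.mean()
    if p_bar in (0.0, 1.0):
        return 0.0, df, 1.0
    p_k = np.bincount(inverse, weights=y, minlength=K) / n_k
    score = float(np.sum(n_k * (p_k - p_bar) ** 2) / (p_bar * (1.0 - p_bar)))
    p = float(stats.chi2.sf(score, df))
    if score == 0.0:
        p = 1.0
    return score, df, p


def rao_score_matrix(
    occurrence: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized :func:`rao_score_test` over the rows of a binary matrix.

    Returns (scores, df, p_values), one entry per row.  Rows with a
    degenerate pooled proportion get score 0 and p 1.
    """
    Y = np.asarray(occurrence, dtype=float)
    labels = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[1] != labels.size:
        raise ValueError("occurrence must be (functions x genomes)")
    uniq, inverse = np.unique(labels, return_inverse=True)
    K = uniq.size
    if K < 2:
        raise ValueError("need at least two groups")
    n_k = np.bincount(inverse, minlength=K).astype(float)
    if (n_k == 0).any():
        raise ValueError("every group must be nonempty")
    df = K - 1
    p_bar = Y.mean(axis=1)
    # per-group presence counts: functions x K
    counts = np.zeros((Y.shape[0], K))
    for k in range(K):
        counts[:, k] = Y[:, inverse == k].sum(axis=1)
    p_k = counts / n_k
    denom = p_bar * (1.0 - p_bar)
    ok = denom > 0
    scores = np.zeros(Y.shape[0])
    scores[ok] = (
        (n_k * (p_k[ok] - p_bar[ok, None]) ** 2).sum(axis=1) / denom[ok]
    )
    pvals = np.ones(Y.shape[0])
    nonzero = ok & (scores > 0)
    pvals[nonzero] = stats.chi2.sf(scores[nonzero], df)
    return scores, df, pvals


def estimate_qvalues(
    p_values: np.ndarray,
    cfg: ThresholdConfig | None = None,
    method: str | None = None,
    storey_lambda: float | None = None,
) -> np.ndarray:
    """q-values from p-values for FDR control.

    ``method="storey"`` estimates the null proportion pi0 = min(1,
    #{p > lambda} / ((1 - lambda) m)) and applies the step-up rule
    ``q_(i) = min_{t >= p_(i)} pi0 * m * t / #{p <= t}`` over the
    observed p-values; ``method="bh"`` is the same with pi0 = 1
    (Benjamini-Hochberg).  q-values are monotone in p and capped at 1.
    """
    cfg = cfg or ThresholdConfig()
    method = method or cfg.fdr_method
    lam = cfg.storey_lambda if storey_lambda is None else storey_lambda
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        if not 0 <= lam < 1:
            raise ValueError("storey_lambda must be in [0, 1)")
        pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
        if pi0 == 0.0:
            pi0 = 1.0 / m  # all p below lambda; keep q-values positive
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    # step-up: running minimum from the largest p down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_core(occurrence_row: np.ndarray, cfg: ThresholdConfig) -> bool:
    """Core call: function present in at least ``core_occurrence_fraction``
    of the genomes."""
    row = np.asarray(occurrence_row, dtype=float)
    if row.size == 0:
        raise ValueError("occurrence row is empty")
    return bool(row.mean() >= cfg.core_occurrence_fraction)


def enrichment_analysis(
    occurrence: pd.DataFrame, groups: pd.Series, cfg: ThresholdConfig
) -> pd.DataFrame:
    """Full enrichment analysis over a function x genome occurrence matrix.

    Parameters
    ----------
    occurrence
        Binary function x genome matrix (see
        :func:`build_function_occurrence`).
    groups
        Group (e.g., clade) label per genome id; must cover every column.
    cfg
        Thresholds: ``enrichment_q_threshold`` (strict "below"),
        ``core_occurrence_fraction``, and the FDR method.

    Returns
    -------
    One row per function, ordered by (q, p, accession), with the score
    statistic, df, p, q, enriched and core flags, the groups whose
    occurrence proportion exceeds the pooled proportion, and per-group
    proportions.
    """
    missing = set(occurrence.columns) - set(groups.index)
    if missing:
        raise ValueError(f"groups missing for genomes: {sorted(missing)[:5]}")
    if occurrence.shape[0] == 0:
        return pd.DataFrame(
            columns=[
                "accession", "enrichment_score", "df", "p_value", "q_value",
                "enriched", "core", "associated_groups",
            ]
        )
    labels = groups.reindex(occurrence.columns).to_numpy()
    Y = occurrence.to_numpy(dtype=float)
    scores, df, pvals = rao_score_matrix(Y, labels)
    qvals = estimate_qvalues(pvals, cfg)

    uniq = np.unique(labels)
    p_bar = Y.mean(axis=1)
    prop = {
        g: Y[:, labels == g].mean(axis=1) for g in uniq
    }
    associated = [
        ",".join(g for g in uniq if prop[g][i] > p_bar[i]) for i in range(Y.shape[0])
    ]
    out = pd.DataFrame(
        {
            "accession": occurrence.index.astype(str),
            "enrichment_score": scores,
            "df": df,
            "p_value": pvals,
            "q_value": qvals,
            "enriched": qvals < cfg.enrichment_q_threshold,
            "core": p_bar >= cfg.core_occurrence_fraction,
            "associated_groups": associated,
        }
    )
    for g in uniq:
        out[f"proportion_{g}"] = prop[g]
    out = out.sort_values(
        by=["q_value", "p_value", "accession"], kind="mergesort"
    ).reset_index(drop=True)
    return out
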