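"""Subcellular-compartment enrichment of a hit-gene set.

Each gene carries a 0-5 localization confidence per compartment
(COMPARTMENTS-style). A gene set's compartment score is the mean score of
its genes rescaled to [0, 1] (genes without evidence contribute 0).
Compartments are removed before testing when they are too undescriptive
(set score >= 0.7), have low signal (set score <= 0.02), or carry only
weak evidence (no individual gene in the set scoring >= 3.5/5).

Enrichment compares the query-set score to the mean score of many random
gene sets of the same size drawn without replacement from the screened
library; the empirical p-value uses the +1 pseudocount and BH controls the
FDR across kept compartments. Enrichment is one-sided (>=), matching a
fold-change-over-random-average readout; the log2 fold change per kept
compartment is the quantity mapped onto a cell diagram downstream.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from cargoscreen.io import LocalizationMatrix

logger = logging.getLogger("cargoscreen")

DEFAULT_THRESHOLDS = (0.7, 0.02, 3.5)
MAX_SCORE = 5.0

STATUS_KEPT = "kept"
STATUS_UNDESCRIPTIVE = "undescriptive"
STATUS_LOW_SIGNAL = "low_signal"
STATUS_WEAK_EVIDENCE = "weak_evidence"


def gene_set_score(
    genes: Iterable[str], compartment: str, matrix: LocalizationMatrix
) -> float:
    """Mean localization score of the set in one compartment, rescaled to
    [0, 1]; genes absent from the matrix contribute score 0."""
    genes = [g.upper() for g in genes]
    if not genes:
        raise ValueError("empty gene set")
    if compartment not in matrix.compartments:
        raise KeyError(f"unknown compartment {compartment!r}")
    col = matrix.scores[compartment]
    total = float(col.reindex(genes).fillna(0.0).sum())
    return total / (len(genes) * MAX_SCORE)


def _score_block(matrix: LocalizationMatrix,
                 genes: Sequence[str]) -> np.ndarray:
    """(len(genes), n_compartments) score array, absent genes = 0."""
    return (matrix.scores.reindex([g.upper() for g in genes])
            .fillna(0.0).to_numpy())


def filter_compartments(
    matrix: LocalizationMatrix,
    query_set: Iterable[str],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Filter status per compartment, evaluated on the query set.

    kept iff low_signal < S < undescriptive AND some query gene has an
    individual score >= strong_evidence; thresholds default to
    (0.7, 0.02, 3.5). Order of precedence when several rules fire:
    undescriptive, low_signal, weak_evidence.
    """
    undescriptive, low_signal, strong = thresholds
    query = sorted({g.upper() for g in query_set})
    if not query:
        raise ValueError("empty query set")
    block = _score_block(matrix, query)
    s = block.mean(axis=0) / MAX_SCORE
    max_individual = block.max(axis=0)
    status = []
    for sc, mx in zip(s, max_individual):
        if sc >= undescriptive:
            status.append(STATUS_UNDESCRIPTIVE)
        elif sc <= low_signal:
            status.append(STATUS_LOW_SIGNAL)
        elif mx < strong:
            status.append(STATUS_WEAK_EVIDENCE)
        else:
            status.append(STATUS_KEPT)
    return pd.DataFrame({
        "compartment": matrix.compartments,
        "name": [matrix.compartment_names.get(c, c)
                 for c in matrix.compartments],
        "set_score": s,
        "max_individual_score": max_individual,
        "status": status,
    })


def _random_set_scores(
    matrix: LocalizationMatrix,
    background: Sequence[str],
    set_size: int,
    n_boot: int,
    rng: np.random.Generator,
    chunk_rows: int | None = None,
) -> np.ndarray:
    """(n_boot, n_compartments) scores of random same-size gene sets drawn
    without replacement from the background; computed incrementally via a
    sparse indicator x score-matrix product so genome-scale backgrounds
    stay desk-feasible."""
    scores = _score_block(matrix, background) / MAX_SCORE
    n_genes, n_comp = scores.shape
    if chunk_rows is None:
        # keep the random-key block near ~32 MB regardless of library size
        chunk_rows = max(1, int(4e6 // max(n_genes, 1)))
    out = np.empty((n_boot, n_comp))
    done = 0
    while done < n_boot:
        rows = min(chunk_rows, n_boot - done)
        # k distinct indices per row via random-key partial sort
        keys = rng.random((rows, n_genes))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        indicator = sparse.csr_matrix(
            (np.ones(rows * set_size), idx.ravel(),
             np.arange(0, rows * set_size + 1, set_size)),
            shape=(rows, n_genes))
        out[done:done + rows] = (indicator @ scores) / set_size
        done += rows
    return out


def bootstrap_enrichment(
    query_set: Iterable[str],
    matrix: LocalizationMatrix,
    background_genes: Iterable[str],
    n_boot: int = 100_000,
    seed: int = 0,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    apply_filters: bool = True,
) -> pd.DataFrame:
    """Per-compartment enrichment of the query set over random expectation.

    Draws ``n_boot`` random gene sets of the query's size (without
    replacement from the library background), and per kept compartment
    reports the null mean score, fold change FC = S_q / S_null_mean, log2
    FC, empirical p = (1 + #{S_random >= S_q}) / (n_boot + 1), and BH q
    across kept compartments. Compartments removed by the filters carry
    their status and no p.
    """
    query = sorted({g.upper() for g in query_set})
    background = sorted({g.upper() for g in background_genes})
    if not query:
        raise ValueError("empty query set")
    if len(query) > len(background):
        raise ValueError("query larger than background universe")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)

    filt = filter_compartments(matrix, query, thresholds) if apply_filters \
        else None
    comps = list(matrix.compartments)
    s_query = _score_block(matrix, query).mean(axis=0) / MAX_SCORE

    null = _random_set_scores(matrix, background, len(query), n_boot, rng)
    null_mean = null.mean(axis=0)
    exceed = (null >= s_query[None, :]).sum(axis=0)
    p_emp = (1.0 + exceed) / (n_boot + 1.0)

    rows = []
    for i, comp in enumerate(comps):
        status = filt["status"].iloc[i] if filt is not None else STATUS_KEPT
        fc = s_query[i] / null_mean[i] if null_mean[i] > 0 else np.nan
        rows.append({
            "compartment": comp,
            "name": matrix.compartment_names.get(comp, comp),
            "query_score": s_query[i],
            "null_mean": null_mean[i],
            "fold_change": fc,
            "log2_fc": np.log2(fc) if np.isfinite(fc) and fc > 0 else np.nan,
            "p": p_emp[i] if status == STATUS_KEPT else np.nan,
            "status": status,
        })
    table = pd.DataFrame(rows)
    kept = table["status"] == STATUS_KEPT
    table["q"] = np.nan
    if kept.any():
        table.loc[kept, "q"] = multipletests(
            table.loc[kept, "p"], method="fdr_bh")[1]
    return table


def export_compartment_map(results: pd.DataFrame) -> pd.DataFrame:
    """Kept compartments only, ordered by descending log2 fold change —
    the table a cell-diagram renderer consumes."""
    kept = results[results["status"] == STATUS_KEPT].copy()
    kept = kept.sort_values(["log2_fc", "compartment"],
                            ascending=[False, True], kind="mergesort")
    return kept[["compartment", "name", "log2_fc", "q", "status"]].reset_index(
        drop=True)
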