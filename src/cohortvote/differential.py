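"""Per-cohort differential expression by median fold change.

The per-cohort ranking criterion is the ratio of group medians on the linear
scale: ``FC(g) = median(secondary) / median(primary)``.  Each cohort's top-N
upregulated list is the N genes with the largest FC strictly above 1, ranked
deterministically (FC descending, symbol ascending on ties).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = ["median_fold_change", "select_top_n", "top_n_set"]

DEFAULT_TOP_N = 1000


def median_fold_change(
    cohort: ExpressionCohort, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Median fold change (secondary over primary) per gene.

    ``FC = (median_secondary + eps) / (median_primary + eps)`` with
    ``eps = pseudocount``.  With the default ``pseudocount = 0``, genes whose
    primary or secondary median is exactly zero have no defined ratio and are
    excluded (count logged).  Returns a DataFrame indexed by gene with column
    ``median_fc``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    sec = cohort.samples_in_group("secondary")
    pri = cohort.samples_in_group("primary")
    if len(sec) == 0 or len(pri) == 0:
        raise ValueError(f"{cohort.cohort_id}: a group has zero samples")
    med_sec = cohort.values[sec].median(axis=1).to_numpy()
    med_pri = cohort.values[pri].median(axis=1).to_numpy()

    keep = np.ones(len(med_sec), dtype=bool)
    if pseudocount == 0:
        keep = (med_sec > 0) & (med_pri > 0)
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.warning(
                "%s: excluded %d gene(s) with a zero group median "
                "(no pseudocount configured)",
                cohort.cohort_id, n_excluded,
            )
    fc = (med_sec[keep] + pseudocount) / (med_pri[keep] + pseudocount)
    return pd.DataFrame(
        {"median_fc": fc}, index=cohort.gene_ids[keep].rename("gene")
    )


def select_top_n(fc_table: pd.DataFrame, n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """Flag the top-``n`` upregulated genes of one cohort.

    Genes with ``median_fc > 1`` are ranked by fold change descending, gene
    symbol ascending on ties; the top ``min(n, #upregulated)`` are flagged.
    Returns the table with added ``fc_rank`` (1-based among upregulated genes,
    <NA> otherwise) and boolean ``in_top_n`` columns, in the original gene
    order.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    table = fc_table.copy()
    up = table.index[table["median_fc"] > 1.0]
    ranked = (
        table.loc[up, ["median_fc"]]
        .reset_index()
        .sort_values(["median_fc", "gene"], ascending=[False, True],
                     kind="mergesort")
    )
    rank = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked["gene"], dtype="Int64"
    )
    table["fc_rank"] = rank.reindex(table.index)
    table["in_top_n"] = (table["fc_rank"] <= n).fillna(False).astype(bool)
    if 0 < len(up) < n:
        logger.info(
            "only %d upregulated genes available for a top-%d list; "
            "all flagged", len(up), n,
        )
    return table


def top_n_set(diff_table: pd.DataFrame) -> set[str]:
    """The top-N membership set of a :func:`select_top_n` output."""
    return set(diff_table.index[diff_table["in_top_n"]])
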