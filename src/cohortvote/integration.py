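"""Cross-cohort integration by vote counting over top-N lists.

A gene's ``duplication_times`` is the number of cohorts whose top-N
upregulated list contains it — the vote-count statistic that ranks the
integrated signature.  The signature retains genes appearing in at least
``min_duplication`` cohorts (default 5, i.e. "more than four"), sorted by
duplication count, then summarized fold change, then symbol.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["count_duplication", "build_signature"]

DEFAULT_MIN_DUPLICATION = 5


def count_duplication(
    top_lists: Mapping[str, set[str]],
    universes: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Tally per-gene list membership and measurement across cohorts.

    Returns a DataFrame indexed by gene with ``duplication_times`` (number of
    cohorts whose top-N set contains the gene) and ``cohorts_measured``
    (number of cohort universes containing it), over the union of all
    universes.  Every top-N set must be a subset of its cohort's universe.
    """
    if set(top_lists) - set(universes):
        raise ValueError("top list provided for a cohort with no universe")
    for cohort_id, top in top_lists.items():
        stray = top - universes[cohort_id]
        if stray:
            raise ValueError(
                f"{cohort_id}: top-N gene(s) absent from own universe: "
                f"{sorted(stray)[:5]}"
            )
    all_genes = sorted(set().union(*universes.values())) if universes else []
    dup = pd.Series(0, index=pd.Index(all_genes, name="gene"), dtype=int)
    measured = pd.Series(0, index=dup.index, dtype=int)
    for cohort_id, universe in universes.items():
        measured[measured.index.isin(universe)] += 1
        top = top_lists.get(cohort_id, set())
        if top:
            dup[dup.index.isin(top)] += 1
    return pd.DataFrame(
        {"duplication_times": dup, "cohorts_measured": measured}
    )


def build_signature(
    dup_counts: pd.DataFrame,
    fc_tables: Mapping[str, pd.DataFrame],
    min_duplication: int = DEFAULT_MIN_DUPLICATION,
    fc_scope: str = "top",
) -> pd.DataFrame:
    """Assemble the ranked integrated signature.

    Retains genes with ``duplication_times >= min_duplication``.  The
    summarized ``median_fold_change`` is the median of the gene's per-cohort
    fold changes over the cohorts where it made the top-N list
    (``fc_scope="top"``, the default) or over all cohorts measuring it
    (``fc_scope="all"``).  Rows are sorted by (duplication_times desc,
    median_fold_change desc, gene asc) and ranked 1..K; ``p_binom``/``q_bh``
    are left NaN for the calibration stage.  An empty signature is permitted.
    """
    if min_duplication < 1:
        raise ValueError("min_duplication must be at least 1")
    if fc_scope not in ("top", "all"):
        raise ValueError("fc_scope must be 'top' or 'all'")
    retained = dup_counts[
        dup_counts["duplication_times"] >= min_duplication
    ].copy()

    med_fc = []
    for gene in retained.index:
        fcs = []
        for table in fc_tables.values():
            if gene not in table.index:
                continue
            if fc_scope == "top" and not bool(table.loc[gene, "in_top_n"]):
                continue
            fcs.append(float(table.loc[gene, "median_fc"]))
        med_fc.append(float(np.median(fcs)) if fcs else np.nan)
    retained["median_fold_change"] = med_fc

    retained = (
        retained.reset_index()
        .sort_values(
            ["duplication_times", "median_fold_change", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    retained["p_binom"] = np.nan
    retained["q_bh"] = np.nan
    retained["rank"] = np.arange(1, len(retained) + 1)
    return retained[
        ["gene", "duplication_times", "cohorts_measured",
         "median_fold_change", "p_binom", "q_bh", "rank"]
    ]
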