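#!/usr/bin/env python
"""Rank genes per cohort by median fold change and integrate across cohorts.

Reads the cohorts written by 01_simulate_cohorts.py, selects each cohort's
top-1000 upregulated list, counts cross-cohort duplication, applies the
more-than-four-cohorts filter (min duplication 5), and writes the ranked
signature with binomial-null p/q values to results/signature.tsv.  Reports
how much of the planted truth the signature recovered.
"""

from pathlib import Path

import pandas as pd

from cohortvote import differential, integration, io, nulls

ROOT = Path(__file__).resolve().parents[1] / "results"
TOP_N = 1000
MIN_DUPLICATION = 5


def main() -> None:
    cohort_dir = ROOT.parent / "scratch" / "cohorts"
    paths = sorted(
        p for p in cohort_dir.glob("cohort*.tsv") if "annotation" not in p.name
    )
    if not paths:
        raise SystemExit("no cohorts found; run 01_simulate_cohorts.py first")

    fc_tables, top_lists, universes = {}, {}, {}
    for path in paths:
        matrix = io.read_expression_matrix(path, scale_hint="auto")
        ann = io.read_sample_annotation(
            path.with_name(path.stem + ".annotation.tsv")
        )
        cohort = io.assemble_cohort(path.stem, matrix, ann)
        table = differential.select_top_n(
            differential.median_fold_change(cohort), n=TOP_N
        )
        fc_tables[cohort.cohort_id] = table
        top_lists[cohort.cohort_id] = differential.top_n_set(table)
        universes[cohort.cohort_id] = set(cohort.gene_ids)

    dup = integration.count_duplication(top_lists, universes)
    signature = integration.build_signature(
        dup, fc_tables, min_duplication=MIN_DUPLICATION
    )
    G = max(len(u) for u in universes.values())
    signature = nulls.calibrate_signature(signature, TOP_N, G)
    io.write_signature(ROOT / "signature.tsv", signature)

    truth = pd.read_csv(cohort_dir / "truth.tsv", sep="\t")
    planted = set(truth["gene"])
    found = set(signature["gene"])
    print(f"signature: {len(signature)} genes in > {MIN_DUPLICATION - 1} "
          f"of {len(paths)} cohorts -> {ROOT / 'signature.tsv'}")
    if len(signature):
        top = signature.iloc[0]
        print(f"  top gene {top['gene']}: duplication "
              f"{top['duplication_times']}/{top['cohorts_measured']}, "
              f"median FC {top['median_fold_change']:.2f}, "
              f"q = {top['q_bh']:.2e}")
    print(f"  recovery: {len(found & planted)}/{len(planted)} planted genes; "
          f"precision {len(found & planted) / max(len(found), 1):.1%}")


if __name__ == "__main__":
    main()
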