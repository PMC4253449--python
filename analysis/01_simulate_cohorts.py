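#!/usr/bin/env python
"""Generate the default eight-cohort discovery simulation and write it out.

Eight independent case series with the published sample counts (20, 19, 52,
171, 167, 164, 104, 79), a 10,000-gene universe, and 50 planted upregulated
genes (fold change 2-4, penetrance 0.8).  Writes one expression TSV and one
annotation TSV per cohort plus the ground truth under scratch/cohorts/.
"""

import json
from pathlib import Path

import pandas as pd

from cohortvote import io, simulate

# large generated matrices live under scratch/, not results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"


def main(seed: int = 1) -> None:
    config = simulate.SimulationConfig(seed=seed)
    cohorts, truth = simulate.generate_multi_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    for cohort in cohorts:
        io.write_expression_matrix(OUT / f"{cohort.cohort_id}.tsv",
                                   cohort.values)
        pd.DataFrame(
            {"sample_id": cohort.sample_ids, "group": cohort.group.to_numpy()}
        ).to_csv(OUT / f"{cohort.cohort_id}.annotation.tsv", sep="\t",
                 index=False)
    simulate.write_truth(OUT / "truth.tsv", truth)
    (OUT / "sim_config.json").write_text(json.dumps(
        {k: v for k, v in config.__dict__.items()}, default=list, indent=2,
    ) + "\n")
    n_secondary = [int((c.group == "secondary").sum()) for c in cohorts]
    print(f"wrote {len(cohorts)} cohorts to {OUT}")
    print(f"  sample counts: {[len(c.sample_ids) for c in cohorts]}")
    print(f"  secondary per cohort: {n_secondary}")
    print(f"  planted genes: {len(truth.planted_genes)}, "
          f"marker gene: {truth.marker_gene}")


if __name__ == "__main__":
    main()
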