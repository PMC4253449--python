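import numpy as np
import pandas as pd
import pytest

from cohortvote.io import ExpressionCohort


def make_cohort(
    cohort_id: str,
    values: np.ndarray,
    genes=None,
    n_primary: int | None = None,
    groups=None,
) -> ExpressionCohort:
    """Assemble an ExpressionCohort from a raw matrix for tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"{cohort_id}_s{j}" for j in range(n_samples)]
    if groups is None:
        if n_primary is None:
            n_primary = n_samples // 2
        groups = ["primary"] * n_primary + ["secondary"] * (n_samples - n_primary)
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(values, index=list(genes), columns=samples),
        group=pd.Series(list(groups), index=samples),
    )


def random_cohort(rng, cohort_id="c", n_genes=50, n_samples=12) -> ExpressionCohort:
    values = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, n_samples))
    return make_cohort(cohort_id, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
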