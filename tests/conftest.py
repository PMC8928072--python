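import numpy as np
import pandas as pd
import pytest

from immunopanel import (
    CohortConfig,
    ExpressionMatrix,
    compute_panel_scores,
    generate_icb_cohort,
    generate_tissue_cohort,
)


def make_matrix(values, genes, samples) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    )


@pytest.fixture(scope="session")
def tissue_cohort():
    """Default multi-tissue tumor/normal cohort (3 tissues, 100 per group)."""
    return generate_tissue_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def tissue_scores(tissue_cohort):
    return compute_panel_scores(tissue_cohort.matrix)


@pytest.fixture(scope="session")
def icb_cohort():
    """Default on-treatment ICB cohort, 50 responders + 50 non-responders."""
    return generate_icb_cohort(
        CohortConfig(n_responders=50, n_nonresponders=50, seed=7)
    )


@pytest.fixture
def small_matrix():
    return make_matrix(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], ["CD8A", "IFNG", "GZMB"], ["s1", "s2"]
    )
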