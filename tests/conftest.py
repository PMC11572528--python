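import numpy as np
import pandas as pd
import pytest

from resilgrey import (
    CohortSpec,
    IndicatorNode,
    IndicatorTree,
    ResponseTable,
    load_packaged_scale,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tree():
    return load_packaged_scale()


@pytest.fixture
def chain_tree():
    """Degenerate one-branch scale: one domain, one content, one item."""
    return IndicatorTree(
        [
            IndicatorNode("a1", 1, None, "domain", 1.0),
            IndicatorNode("a11", 2, "a1", "content", 1.0),
            IndicatorNode("a111", 3, "a11", "item", 1.0),
        ]
    )


@pytest.fixture
def toy_tree():
    """Small tree with two leaves per content for aggregation checks."""
    return IndicatorTree(
        [
            IndicatorNode("d1", 1, None, "", 0.6),
            IndicatorNode("d2", 1, None, "", 0.4),
            IndicatorNode("d11", 2, "d1", "", 1.0),
            IndicatorNode("d21", 2, "d2", "", 1.0),
            IndicatorNode("d111", 3, "d11", "", 0.5),
            IndicatorNode("d112", 3, "d11", "", 0.5),
            IndicatorNode("d211", 3, "d21", "", 0.3),
            IndicatorNode("d212", 3, "d21", "", 0.7),
        ]
    )


def make_table(tree, ratings, ids=None, covariates=None):
    ratings = np.asarray(ratings, dtype=float)
    idx = pd.Index(ids if ids is not None else range(1, len(ratings) + 1),
                   name="respondent_id")
    cov = pd.DataFrame(covariates or {}, index=idx)
    return ResponseTable(
        pd.DataFrame(ratings, index=idx, columns=tree.leaf_ids),
        cov,
        rating_min=tree.rating_min,
        rating_max=tree.rating_max,
    )


@pytest.fixture(scope="session")
def cohort_347(tree):
    """Default synthetic cohort at the study's sample size."""
    return simulate_cohort(CohortSpec(n_respondents=347, seed=20240), tree)
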