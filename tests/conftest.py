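import logging

import numpy as np
import pandas as pd
import pytest

from emtime.io import EnrichmentTable, ExpressionMatrix
from emtime.scoring import MarkerPanel, compute_emt_score, stratify_by_emt
from emtime.simulate import SimulationConfig, generate_cohort

# synthetic generators warn about absent genes etc.; keep test output clean
logging.getLogger("emtime").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def panel():
    return MarkerPanel()


@pytest.fixture(scope="session")
def small_bundle():
    """One seeded synthetic cohort shared (read-only) across tests."""
    return generate_cohort(SimulationConfig(cohort_id="TST", n_samples=200, seed=42))


@pytest.fixture(scope="session")
def scored_bundle(small_bundle):
    scores = compute_emt_score(small_bundle.expression)
    groups = stratify_by_emt(scores)
    return small_bundle, scores, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expression(values, genes, samples, cohort="TST"):
    return ExpressionMatrix(
        cohort, pd.DataFrame(np.asarray(values, dtype=float),
                             index=genes, columns=samples))


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples with hand-pickable values."""
    return make_expression(
        [[0.0, 1.0, -1.0, 2.0],
         [0.5, 0.0, 0.5, -0.5],
         [1.0, -1.0, 0.0, 0.0]],
        genes=["VIM", "CDH1", "FN1"],
        samples=["s1", "s2", "s3", "s4"])
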