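import numpy as np
import pytest

from apscore.scoring import ap_score
from apscore.selection import select_progression_genes
from apscore.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (5 NT + 160 LGG + 80 GBM, 2000 genes)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Small but signal-bearing config for fast end-to-end tests."""
    return SyntheticConfig(n_genes=300, n_nt=4, n_lgg=60, n_gbm=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_selection(default_cohort):
    return select_progression_genes(default_cohort.expression, default_cohort.clinical)


@pytest.fixture(scope="session")
def truth_scores(default_cohort):
    """AP scores computed from the planted truth signature."""
    return ap_score(default_cohort.expression, default_cohort.truth)


def es_bruteforce(ranks, in_set, alpha):
    """Independent naive running-sum oracle for the single-sample ES."""
    ranks = list(map(float, ranks))
    in_set = list(map(bool, in_set))
    n = len(ranks)
    order = sorted(range(n), key=lambda i: -ranks[i])
    denom_in = sum(ranks[i] ** alpha for i in range(n) if in_set[i])
    denom_out = n - sum(in_set)
    es = 0.0
    for pos in range(1, n + 1):
        p_in = sum(
            ranks[order[k]] ** alpha for k in range(pos) if in_set[order[k]]
        ) / denom_in
        p_out = sum(1 for k in range(pos) if not in_set[order[k]]) / denom_out
        es += p_in - p_out
    return es
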