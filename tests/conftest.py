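import numpy as np
import pandas as pd
import pytest

import hypometab as hm


@pytest.fixture(scope="session")
def worked_example():
    """The hand-verified 8-gene x 10-sample scoring fixture."""
    return hm.generate_worked_example()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=600, seed 1)."""
    return hm.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_dereg(default_cohort):
    """Deregulation matrix of the default cohort (90 pathways)."""
    return hm.score_collection(default_cohort.expr, default_cohort.gene_sets)


@pytest.fixture
def small_expr():
    """A tiny deterministic expression matrix for I/O and scoring units."""
    rng = np.random.default_rng(7)
    genes = list(hm.HYPOXIA_8.genes)
    df = pd.DataFrame(
        rng.normal(size=(8, 10)),
        index=genes,
        columns=[f"s{i}" for i in range(10)],
    )
    return hm.ExpressionMatrix(df)


def brute_force_hs(values: pd.DataFrame, tie_rule: str = "le_minus") -> list[int]:
    """Independent elementwise oracle for median-dichotomization scoring."""
    hs = []
    for s in values.columns:
        total = 0
        for g in values.index:
            med = float(np.median(values.loc[g].to_numpy()))
            v = float(values.loc[g, s])
            if tie_rule == "le_minus":
                total += 1 if v > med else -1
            else:
                total += 1 if v >= med else -1
        hs.append(total)
    return hs
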