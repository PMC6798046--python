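import math

import numpy as np
import pandas as pd
import pytest

from sigmeta.effects import GeneStudyEffect, Z95
from sigmeta.studies import CASE, CONTROL, ExpressionStudy


def make_effect(lfc, variance, gene="G", study_id="S0", n_case=10, n_control=10):
    se = math.sqrt(variance)
    return GeneStudyEffect(
        gene=gene,
        study_id=study_id,
        lfc=lfc,
        variance=variance,
        se=se,
        ci95=(lfc - Z95 * se, lfc + Z95 * se),
        n_case=n_case,
        n_control=n_control,
    )


def make_study(values_by_gene, n_case, n_control, study_id="S0", **kwargs):
    """Build a study from per-gene value lists (controls first, then cases)."""
    genes = list(values_by_gene)
    columns = [f"{study_id}_c{i}" for i in range(n_control)] + [
        f"{study_id}_t{i}" for i in range(n_case)
    ]
    matrix = pd.DataFrame(
        np.array([values_by_gene[g] for g in genes], dtype=float),
        index=genes,
        columns=columns,
    )
    group = pd.Series([CONTROL] * n_control + [CASE] * n_case, index=columns)
    return ExpressionStudy(
        study_id=study_id, matrix=matrix, group=group, is_log2=True, **kwargs
    )


@pytest.fixture(scope="session")
def demo_workspace(tmp_path_factory):
    """One demo pipeline run shared by the end-to-end tests."""
    from sigmeta.pipeline import demo_fixture

    directory = tmp_path_factory.mktemp("demo")
    report = demo_fixture(directory, seed=11)
    return directory, report
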