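"""Per-study, per-gene log2 fold-change effect sizes.

The effect size is the difference of group means on the log2 scale (case
minus control), with an unpooled Welch-style sampling variance
``s²_case/n_case + s²_ctrl/n_ctrl`` so unequal group variances do not bias
the weights used later in pooling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .studies import ExpressionStudy

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for every confidence interval.
Z95 = 1.959964


@dataclass(frozen=True)
class GeneStudyEffect:
    """One gene's log2 fold change in one study, with sampling variance."""

    gene: str
    study_id: str
    lfc: float
    variance: float
    se: float
    ci95: tuple[float, float]
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("sampling variance cannot be negative")


def study_effect(study: ExpressionStudy, gene: str) -> GeneStudyEffect:
    """Compute the log2 fold change of one gene in one study.

    Missing values are dropped per group; each group must retain at least
    two finite values for the sample variance to exist.
    """
    if gene not in study.matrix.index:
        raise KeyError(f"gene {gene!r} is not measured in study {study.study_id!r}")
    row = study.matrix.loc[gene]
    case = np.asarray(row[study.case_columns], dtype=float)
    ctrl = np.asarray(row[study.control_columns], dtype=float)
    case = case[np.isfinite(case)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError(
            f"gene {gene!r} in study {study.study_id!r}: need >= 2 finite values "
            f"per group (got {case.size} cases, {ctrl.size} controls)"
        )
    lfc = float(case.mean() - ctrl.mean())
    variance = float(case.var(ddof=1) / case.size + ctrl.var(ddof=1) / ctrl.size)
    if variance == 0.0 and lfc != 0.0:
        logger.warning(
            "gene %s in study %s: zero within-group variance with nonzero "
            "fold change %g",
            gene,
            study.study_id,
            lfc,
        )
    se = math.sqrt(variance)
    return GeneStudyEffect(
        gene=gene,
        study_id=study.study_id,
        lfc=lfc,
        variance=variance,
        se=se,
        ci95=(lfc - Z95 * se, lfc + Z95 * se),
        n_case=int(case.size),
        n_control=int(ctrl.size),
    )


def _study_effects_block(study: ExpressionStudy) -> dict[str, GeneStudyEffect]:
    """All genes' effects for one study, computed with array group moments.

    Matches :func:`study_effect` exactly (same pairwise NaN dropping and
    (n−1) variances) but avoids per-gene row indexing.
    """
    case = study.matrix[study.case_columns].to_numpy(dtype=float)
    ctrl = study.matrix[study.control_columns].to_numpy(dtype=float)
    out: dict[str, GeneStudyEffect] = {}

    def _moments(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        finite = np.isfinite(block)
        n = finite.sum(axis=1)
        filled = np.where(finite, block, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=1) / n
            ss = (np.where(finite, block - mean[:, None], 0.0) ** 2).sum(axis=1)
            var = ss / (n - 1)
        return mean, var, n

    cm, cv, cn = _moments(case)
    km, kv, kn = _moments(ctrl)
    for i, gene in enumerate(study.matrix.index):
        if cn[i] < 2 or kn[i] < 2:
            raise ValueError(
                f"gene {gene!r} in study {study.study_id!r}: need >= 2 finite "
                f"values per group (got {cn[i]} cases, {kn[i]} controls)"
            )
        lfc = float(cm[i] - km[i])
        variance = float(cv[i] / cn[i] + kv[i] / kn[i])
        se = math.sqrt(variance)
        out[str(gene)] = GeneStudyEffect(
            gene=str(gene),
            study_id=study.study_id,
            lfc=lfc,
            variance=variance,
            se=se,
            ci95=(lfc - Z95 * se, lfc + Z95 * se),
            n_case=int(cn[i]),
            n_control=int(kn[i]),
        )
    return out


def effects_table(
    studies: Sequence[ExpressionStudy], signature: Sequence[str]
) -> dict[str, list[GeneStudyEffect]]:
    """Per-gene lists of per-study effects, in study order.

    A gene contributes one effect per study that measures it; genes measured
    in no study are omitted with a warning.
    """
    if not studies:
        raise ValueError("no studies supplied")
    blocks = [_study_effects_block(s) for s in studies]
    table: dict[str, list[GeneStudyEffect]] = {}
    for gene in signature:
        effs = [b[gene] for b in blocks if gene in b]
        if effs:
            table[gene] = effs
        else:
            logger.warning("gene %s is measured in no study; skipped", gene)
    return table


def effects_to_frame(table: Mapping[str, Sequence[GeneStudyEffect]]):
    """Flatten an effects table to a tidy DataFrame for TSV serialisation."""
    import pandas as pd

    rows = [
        {
            "gene": e.gene,
            "study_id": e.study_id,
            "lfc": e.lfc,
            "se": e.se,
            "ci_low": e.ci95[0],
            "ci_high": e.ci95[1],
            "n_case": e.n_case,
            "n_control": e.n_control,
        }
        for effs in table.values()
        for e in effs
    ]
    return pd.DataFrame(rows)
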