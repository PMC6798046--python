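"""Inverse-variance meta-analysis with heterogeneity-based model selection.

For each gene the per-study log2 fold changes are pooled with inverse-
variance weights.  Cochran's Q measures the total variation of the study
effects around the fixed-effects pooled estimate; under homogeneity Q is
chi-square with k−1 degrees of freedom, so

    ISq = 100% × (Q − df) / Q,   truncated at 0 when Q ≤ df.

If ISq = 0 the fixed-effects model is kept; otherwise the DerSimonian–Laird
moment estimate of the between-study variance τ² widens the weights to
1/(vᵢ + τ²) and the random-effects model is used.  The pooled estimate is
tested with a two-sided normal z-test, the standard large-sample test for
inverse-variance pooling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .effects import GeneStudyEffect, Z95

logger = logging.getLogger(__name__)


class Heterogeneity(NamedTuple):
    Q: float
    df: int
    ISq: float
    pQ: float
    tau2: float


class PooledEstimate(NamedTuple):
    lfc: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    weights: tuple[float, ...]


@dataclass(frozen=True)
class MetaGeneResult:
    """Pooled result for one gene: estimate, test, heterogeneity, weights."""

    gene: str
    k: int
    model: str  # "fixed" | "random"
    lfc: float
    se: float
    ci95: tuple[float, float]
    z: float
    p: float
    Q: float
    df: int
    ISq: float
    pQ: float
    tau2: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.ISq <= 100.0:
            raise ValueError("ISq must lie in [0, 100]")
        if self.tau2 < 0:
            raise ValueError("tau2 cannot be negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("normalized weights must sum to 1")
        if self.df != self.k - 1:
            raise ValueError("df must equal k - 1")


def _variances(effects: Sequence[GeneStudyEffect]) -> np.ndarray:
    """Sampling variances with the zero-variance replacement rule applied."""
    v = np.array([e.variance for e in effects], dtype=float)
    if np.all(v == 0):
        raise ValueError(
            "all studies report zero sampling variance; weights are undefined"
        )
    if np.any(v == 0):
        smallest = v[v > 0].min()
        logger.warning(
            "replacing %d zero sampling variance(s) with the smallest positive "
            "variance %g",
            int((v == 0).sum()),
            smallest,
        )
        v = np.where(v == 0, smallest, v)
    return v


def heterogeneity(effects: Sequence[GeneStudyEffect]) -> Heterogeneity:
    """Cochran's Q, ISq, the Q p-value and the DerSimonian–Laird τ²."""
    if not effects:
        raise ValueError("empty effects list")
    y = np.array([e.lfc for e in effects], dtype=float)
    v = _variances(effects)
    k = len(effects)
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    if df == 0:
        return Heterogeneity(Q=0.0, df=0, ISq=0.0, pQ=1.0, tau2=0.0)
    if Q <= df:
        ISq = 0.0
        tau2 = 0.0
    else:
        ISq = 100.0 * (Q - df) / Q
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = (Q - df) / denom
    pQ = float(stats.chi2.sf(Q, df))
    return Heterogeneity(Q=Q, df=df, ISq=ISq, pQ=pQ, tau2=tau2)


def _pool(y: np.ndarray, w: np.ndarray) -> PooledEstimate:
    sw = float(np.sum(w))
    lfc = float(np.sum(w * y) / sw)
    se = math.sqrt(1.0 / sw)
    z = lfc / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    weights = tuple(float(x) for x in w / sw)
    return PooledEstimate(
        lfc=lfc,
        se=se,
        z=z,
        p=p,
        ci95=(lfc - Z95 * se, lfc + Z95 * se),
        weights=weights,
    )


def pool_fixed(effects: Sequence[GeneStudyEffect]) -> PooledEstimate:
    """Fixed-effects pooling with weights 1/vᵢ."""
    if not effects:
        raise ValueError("empty effects list")
    y = np.array([e.lfc for e in effects], dtype=float)
    v = _variances(effects)
    return _pool(y, 1.0 / v)


def pool_random(effects: Sequence[GeneStudyEffect], tau2: float) -> PooledEstimate:
    """Random-effects pooling with weights 1/(vᵢ + τ²)."""
    if not effects:
        raise ValueError("empty effects list")
    if tau2 < 0:
        raise ValueError("tau2 cannot be negative")
    y = np.array([e.lfc for e in effects], dtype=float)
    v = _variances(effects)
    return _pool(y, 1.0 / (v + tau2))


def meta_gene(effects: Sequence[GeneStudyEffect]) -> MetaGeneResult:
    """Full per-gene meta-analysis with the ISq model-selection rule.

    The fixed-effects model is used iff ISq = 0 (i.e. Q ≤ df); otherwise the
    random-effects model with the DerSimonian–Laird τ².  A single-study gene
    pools trivially to that study's effect and is flagged in the log.
    """
    if not effects:
        raise ValueError("empty effects list")
    genes = {e.gene for e in effects}
    if len(genes) > 1:
        raise ValueError(f"effects mix several genes: {sorted(genes)}")
    het = heterogeneity(effects)
    if het.ISq == 0.0:
        model = "fixed"
        pooled = pool_fixed(effects)
    else:
        model = "random"
        pooled = pool_random(effects, het.tau2)
    k = len(effects)
    if k == 1:
        logger.info(
            "gene %s is measured in a single study; pooled result equals that "
            "study's effect",
            effects[0].gene,
        )
    return MetaGeneResult(
        gene=effects[0].gene,
        k=k,
        model=model,
        lfc=pooled.lfc,
        se=pooled.se,
        ci95=pooled.ci95,
        z=pooled.z,
        p=pooled.p,
        Q=het.Q,
        df=het.df,
        ISq=het.ISq,
        pQ=het.pQ,
        tau2=het.tau2,
        weights=pooled.weights,
    )


def meta_all(
    effects_by_gene: dict[str, list[GeneStudyEffect]]
) -> list[MetaGeneResult]:
    """Run :func:`meta_gene` over an effects table, keeping gene order."""
    return [meta_gene(effs) for effs in effects_by_gene.values()]


def results_to_frame(results: Sequence[MetaGeneResult]):
    """Serialise results to the consensus-table layout (one row per gene).

    The ``random_effects_model`` column prints YES/NO, mirroring the usual
    presentation of heterogeneity-selected meta-analyses.
    """
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "random_effects_model": "YES" if r.model == "random" else "NO",
                "n_studies": r.k,
                "lfc": r.lfc,
                "se": r.se,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p,
                "ISq_pct": r.ISq,
                "p_Q": r.pQ,
                "tau2": r.tau2,
            }
            for r in results
        ]
    )
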