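"""Consensus screening of pooled results and forest-plot data.

A gene is a consensus signature gene when its pooled p-value falls strictly
below the p threshold and its pooled |log2 fold change| strictly exceeds the
fold-change threshold (an |LFC| > 1 means more than twofold up or below
0.5-fold down on the linear scale).  No multiple-testing correction is
applied by default; a Benjamini–Hochberg column can be added for reference
but never alters the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .effects import GeneStudyEffect
from .meta import MetaGeneResult, pool_fixed, pool_random


@dataclass(frozen=True)
class SignatureTable:
    """Genes passing the consensus screen, sorted by p ascending."""

    rows: tuple[MetaGeneResult, ...]
    criteria: tuple[float, float]  # (p threshold, |LFC| threshold)

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.rows]


def screen(
    results: Sequence[MetaGeneResult],
    p_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> SignatureTable:
    """Keep genes with p < p_threshold and |pooled LFC| > lfc_threshold.

    Both inequalities are strict, so boundary values are excluded.
    """
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("screening thresholds must be positive")
    kept = [
        r
        for r in results
        if r.p < p_threshold and (r.lfc > lfc_threshold or r.lfc < -lfc_threshold)
    ]
    kept.sort(key=lambda r: r.p)
    return SignatureTable(rows=tuple(kept), criteria=(p_threshold, lfc_threshold))


def forest_data(
    result: MetaGeneResult, effects: Sequence[GeneStudyEffect]
) -> list[dict]:
    """Forest-plot records: one per study plus the pooled summary row.

    Each study record carries its effect, 95% CI and normalized weight under
    the model the gene was pooled with; the summary record repeats the
    pooled estimate exactly.
    """
    genes = {e.gene for e in effects}
    if genes != {result.gene}:
        raise ValueError(
            f"effects belong to {sorted(genes)} but the result is for "
            f"{result.gene!r}"
        )
    if result.model == "random":
        pooled = pool_random(effects, result.tau2)
    else:
        pooled = pool_fixed(effects)
    records = [
        {
            "kind": "study",
            "study_id": e.study_id,
            "lfc": e.lfc,
            "ci_low": e.ci95[0],
            "ci_high": e.ci95[1],
            "weight": w,
        }
        for e, w in zip(effects, pooled.weights)
    ]
    records.append(
        {
            "kind": "summary",
            "study_id": "pooled",
            "lfc": result.lfc,
            "ci_low": result.ci95[0],
            "ci_high": result.ci95[1],
            "weight": 1.0,
        }
    )
    return records


def add_bh_column(results: Sequence[MetaGeneResult]):
    """Benjamini–Hochberg adjusted p-values, for reference only."""
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    p = [r.p for r in results]
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"gene": [r.gene for r in results], "p": p, "p_bh": q})
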