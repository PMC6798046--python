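"""Synthetic multi-study expression data, survival cohorts and covariates.

Every downstream stage of the pipeline can be exercised against data with
known ground truth.  The generative model mirrors the statistical
assumptions of the random-effects meta-analysis: each gene has a true mean
log2 fold change mu_g, a between-study variance tau2_g, and a per-study
realised effect mu_g (+ country shift) + N(0, tau2_g); samples add
independent N(0, sigma²) noise on the log2 scale around a per-gene baseline
drawn once per compendium from N(8, 2²) log2 units, the typical processed
microarray range.  Per-study platform masks remove genes from some studies
so a gene can be measured in only k of K studies, as happens when platforms
carry different gene panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .studies import CASE, CONTROL, ExpressionStudy
from .downstream import SurvivalCohort, coexpression_groups, HIGH

#: Baseline control expression is drawn from N(BASELINE_MEAN, BASELINE_SD²).
BASELINE_MEAN = 8.0
BASELINE_SD = 2.0

#: Baseline event hazard for the "low" coexpression group (1/time units).
BASELINE_HAZARD = 0.1


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters for a synthetic multi-study compendium."""

    gene_ids: tuple[str, ...]
    mu: np.ndarray  # true log2 fold change per gene
    tau2: np.ndarray  # between-study variance per gene (log2² units)
    platform_masks: np.ndarray  # studies × genes boolean
    sigma: float = 1.0  # within-group per-sample SD (log2 units)
    seed: int = 0
    country_effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "tau2", np.asarray(self.tau2, dtype=float))
        object.__setattr__(
            self, "platform_masks", np.asarray(self.platform_masks, dtype=bool)
        )
        g = len(self.gene_ids)
        if self.mu.shape != (g,) or self.tau2.shape != (g,):
            raise ValueError("mu and tau2 must have one entry per gene")
        if np.any(self.tau2 < 0):
            raise ValueError("tau2 must be non-negative elementwise")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.platform_masks.ndim != 2 or self.platform_masks.shape[1] != g:
            raise ValueError("platform_masks must be a studies × genes array")
        if not self.platform_masks.any(axis=1).all():
            raise ValueError("every platform mask must cover at least one gene")

    @property
    def n_studies(self) -> int:
        return self.platform_masks.shape[0]

    def baselines(self) -> np.ndarray:
        """Per-gene baseline control expression, fixed per compendium."""
        rng = np.random.default_rng([self.seed, 0])
        return BASELINE_MEAN + BASELINE_SD * rng.standard_normal(len(self.gene_ids))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_ids": list(self.gene_ids),
                    "mu": self.mu.tolist(),
                    "tau2": self.tau2.tolist(),
                    "platform_masks": self.platform_masks.astype(int).tolist(),
                    "sigma": self.sigma,
                    "seed": self.seed,
                    "country_effect": dict(self.country_effect),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            mu=np.asarray(d["mu"]),
            tau2=np.asarray(d["tau2"]),
            platform_masks=np.asarray(d["platform_masks"], dtype=bool),
            sigma=d["sigma"],
            seed=d["seed"],
            country_effect=d.get("country_effect", {}),
        )


def generate_study(
    truth: SyntheticTruth,
    study_index: int,
    n_case: int,
    n_control: int,
    country: str = "",
    date: int | None = None,
    study_id: str | None = None,
) -> ExpressionStudy:
    """Generate one case/control study from the ground truth.

    Controls are centred at the per-gene baseline; cases at baseline plus
    the study-level realised effect mu_g + country shift + N(0, tau2_g).
    Per-sample noise is N(0, sigma²) on the log2 scale.  Genes outside the
    study's platform mask are absent from the matrix.  The sub-seed is
    derived deterministically from (truth.seed, study_index), so studies are
    independent yet reproducible.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("n_case and n_control must be at least 1")
    if not 0 <= study_index < truth.n_studies:
        raise ValueError(
            f"study_index {study_index} outside the {truth.n_studies} masks"
        )
    rng = np.random.default_rng([truth.seed, 1 + study_index])
    mask = truth.platform_masks[study_index]
    genes = [g for g, m in zip(truth.gene_ids, mask) if m]
    baseline = truth.baselines()[mask]
    shift = float(truth.country_effect.get(country, 0.0))
    realised = (
        truth.mu[mask]
        + shift
        + np.sqrt(truth.tau2[mask]) * rng.standard_normal(mask.sum())
    )
    n = n_control + n_case
    noise = truth.sigma * rng.standard_normal((int(mask.sum()), n))
    values = baseline[:, None] + noise
    values[:, n_control:] += realised[:, None]
    sid = study_id or f"SYN{study_index:02d}"
    columns = [f"{sid}_ctrl_{i}" for i in range(n_control)] + [
        f"{sid}_case_{i}" for i in range(n_case)
    ]
    matrix = pd.DataFrame(values, index=genes, columns=columns)
    group = pd.Series(
        [CONTROL] * n_control + [CASE] * n_case, index=columns, name="group"
    )
    return ExpressionStudy(
        study_id=sid,
        matrix=matrix,
        group=group,
        platform_id=f"panel{study_index:02d}",
        country=country,
        date=date,
        is_log2=True,
    )


def generate_compendium(
    truth: SyntheticTruth,
    study_specs: Sequence[tuple[int, int, str, int]],
    study_ids: Sequence[str] | None = None,
) -> list[ExpressionStudy]:
    """Generate one study per ``(n_case, n_control, country, date)`` spec."""
    if not study_specs:
        raise ValueError("need at least one study spec")
    if len(study_specs) > truth.n_studies:
        raise ValueError(
            f"{len(study_specs)} specs but only {truth.n_studies} platform masks"
        )
    if study_ids is not None and len(study_ids) != len(study_specs):
        raise ValueError("study_ids must match study_specs in length")
    return [
        generate_study(
            truth,
            i,
            n_case,
            n_control,
            country,
            date,
            study_id=None if study_ids is None else study_ids[i],
        )
        for i, (n_case, n_control, country, date) in enumerate(study_specs)
    ]


def generate_survival_cohort(
    n: int,
    hr: float,
    median_gap: float = 2.0,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalCohort:
    """Generate a two-gene cohort whose median split carries a hazard ratio.

    Half the patients receive a coexpression shift of ``median_gap`` log2
    units in both genes, so the median split recovers two groups.  Event
    times are exponential with rate ``BASELINE_HAZARD`` in the low group and
    ``BASELINE_HAZARD * hr`` in the (realised) high group.  Censoring is
    independent of group: with probability ``censor_rate`` a record is
    administratively censored at a uniform fraction of its event time.
    """
    if n < 4:
        raise ValueError("need at least 4 patients")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng([seed, 2])
    base = np.full(n, BASELINE_MEAN)
    base[n // 2 :] += median_gap
    expr_a = base + 0.5 * rng.standard_normal(n)
    expr_b = base + 0.5 * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "expr_a": expr_a,
            "expr_b": expr_b,
            "time": 0.0,
            "event": 1,
        }
    )
    cohort = SurvivalCohort(df.assign(time=1.0))  # placeholder times for split
    labels = coexpression_groups(cohort)
    rate = np.where(labels == HIGH, BASELINE_HAZARD * hr, BASELINE_HAZARD)
    times = rng.exponential(1.0 / rate)
    censored = rng.random(n) < censor_rate
    obs_times = np.where(censored, times * rng.random(n), times)
    df["time"] = obs_times
    df["event"] = (~censored).astype(int)
    return SurvivalCohort(df)


def generate_covariate_table(
    truth: SyntheticTruth,
    studies: Sequence[ExpressionStudy],
    gene: str,
) -> pd.DataFrame:
    """Study-covariate rows (lfc, sample_size, country, date) for one gene."""
    from .effects import study_effect

    rows = []
    for s in studies:
        if gene not in s.matrix.index:
            continue
        e = study_effect(s, gene)
        rows.append(
            {
                "gene": gene,
                "study_id": s.study_id,
                "lfc": e.lfc,
                "sample_size": s.n_case + s.n_control,
                "country": s.country,
                "date": s.date,
            }
        )
    return pd.DataFrame(rows)
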