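"""End-to-end orchestration: filter → ingest → effects → meta → screen →
downstream, driven by a single YAML/JSON configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .downstream import (
    SurvivalCohort,
    mlr_covariates,
    pearson,
    survival_analysis,
)
from .effects import effects_table, effects_to_frame
from .meta import meta_all, results_to_frame
from .screen import forest_data, screen
from .studies import (
    CASE_CONTROL_ARRAY,
    ExpressionStudy,
    collapse_probes,
    detect_and_log2,
    filter_datasets,
    read_expression_table,
    read_signature,
    subset_signature,
    write_study,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyManifestEntry:
    study_id: str
    expression: str
    labels: str
    country: str = ""
    date: int | None = None
    organism: str = "Homo sapiens"
    design: str = CASE_CONTROL_ARRAY
    platform_id: str = ""
    probe_map: str | None = None
    n_case: int | None = None
    n_control: int | None = None


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    signature: str
    output_dir: str
    studies: list[StudyManifestEntry] = field(default_factory=list)
    p_threshold: float = 0.01
    lfc_threshold: float = 1.0
    seed: int = 0
    survival_cohort: str | None = None
    run_survival: bool = True
    run_correlation: bool = True
    run_mlr: bool = True

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        studies = [StudyManifestEntry(**s) for s in raw.pop("studies", [])]
        return cls(studies=studies, **raw)


def _ingest_study(entry: StudyManifestEntry) -> ExpressionStudy:
    if not Path(entry.expression).exists():
        raise FileNotFoundError(f"expression table not found: {entry.expression}")
    if not Path(entry.labels).exists():
        raise FileNotFoundError(f"labels file not found: {entry.labels}")
    study = read_expression_table(
        entry.expression,
        entry.labels,
        study_id=entry.study_id,
        platform_id=entry.platform_id,
        country=entry.country,
        date=entry.date,
    )
    study = detect_and_log2(study)
    if entry.probe_map:
        pm = pd.read_csv(
            entry.probe_map, sep="\t", header=None, names=["probe", "gene"]
        )
        study = collapse_probes(study, dict(zip(pm["probe"], pm["gene"])))
    return study


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; returns a run report dictionary.

    Writes inclusion decisions, the per-study effects TSV, the per-gene
    pooled results TSV, the screened signature table, forest-plot JSON and
    the downstream results to ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": {}, "outputs": {}}

    if not Path(config.signature).exists():
        raise FileNotFoundError(f"signature file not found: {config.signature}")
    signature = read_signature(config.signature)

    # -- stage: inclusion filter -----------------------------------------
    metadata = []
    entries = {}
    for e in config.studies:
        entries[e.study_id] = e
        metadata.append(
            (
                e.study_id,
                e.n_case if e.n_case is not None else 0,
                e.n_control if e.n_control is not None else 0,
                e.organism,
                e.design,
            )
        )
    decisions = filter_datasets(metadata)
    pd.DataFrame(
        [
            {
                "study_id": d.study_id,
                "included": d.included,
                "reasons": "; ".join(d.reasons),
            }
            for d in decisions
        ]
    ).to_csv(out / "inclusion.tsv", sep="\t", index=False)
    report["stages"]["filter"] = {
        "included": sum(d.included for d in decisions),
        "excluded": sum(not d.included for d in decisions),
    }

    # -- stage: ingest ----------------------------------------------------
    studies = []
    for d in decisions:
        if not d.included:
            continue
        try:
            studies.append(subset_signature(_ingest_study(entries[d.study_id]), signature))
        except Exception as exc:
            raise RuntimeError(
                f"ingest stage failed for study {d.study_id!r}: {exc}"
            ) from exc
    if not studies:
        raise RuntimeError("no studies survived the inclusion filter")
    report["stages"]["ingest"] = {"studies": len(studies)}

    # -- stage: effects ----------------------------------------------------
    table = effects_table(studies, signature)
    effects_to_frame(table).to_csv(out / "effects.tsv", sep="\t", index=False)
    report["stages"]["effects"] = {"genes": len(table)}

    # -- stage: meta -------------------------------------------------------
    results = meta_all(table)
    results_to_frame(results).to_csv(out / "meta.tsv", sep="\t", index=False)
    forest = {
        r.gene: forest_data(r, table[r.gene]) for r in results
    }
    (out / "forest.json").write_text(json.dumps(forest, indent=1))
    report["stages"]["meta"] = {"genes": len(results)}

    # -- stage: screen -----------------------------------------------------
    sig_table = screen(results, config.p_threshold, config.lfc_threshold)
    results_to_frame(list(sig_table.rows)).to_csv(
        out / "signature_table.tsv", sep="\t", index=False
    )
    report["stages"]["screen"] = {
        "retained": len(sig_table.rows),
        "genes": sig_table.genes,
        "criteria": {"p": config.p_threshold, "lfc": config.lfc_threshold},
    }

    # -- stage: downstream -------------------------------------------------
    if config.survival_cohort and (config.run_survival or config.run_correlation):
        if not Path(config.survival_cohort).exists():
            raise FileNotFoundError(
                f"survival cohort not found: {config.survival_cohort}"
            )
        cohort = SurvivalCohort.from_csv(config.survival_cohort)
        if config.run_survival:
            sr = survival_analysis(cohort)
            report["stages"]["survival"] = {
                "logrank_chi2": sr.chi2,
                "logrank_p": sr.p,
                "hr": sr.hr,
                "hr_ci95": list(sr.hr_ci95),
                "cox_p": sr.cox_p,
                "n_high": sr.n_high,
                "n_low": sr.n_low,
            }
        if config.run_correlation:
            cr = pearson(cohort.data["expr_a"], cohort.data["expr_b"])
            report["stages"]["correlation"] = {"r": cr.r, "p": cr.p, "n": cr.n}

    if config.run_mlr and sig_table.rows:
        mlr_out = {}
        for r in sig_table.rows:
            rows = []
            for s in studies:
                if r.gene not in s.matrix.index:
                    continue
                eff = next(e for e in table[r.gene] if e.study_id == s.study_id)
                rows.append(
                    {
                        "gene": r.gene,
                        "study_id": s.study_id,
                        "lfc": eff.lfc,
                        "sample_size": s.n_case + s.n_control,
                        "country": s.country,
                        "date": s.date,
                    }
                )
            cov = pd.DataFrame(rows)
            try:
                m = mlr_covariates(cov)
                mlr_out[r.gene] = {
                    name: {"coef": list(f.coef), "p": f.p, "ci95": [list(c) for c in f.ci95]}
                    for name, f in m.factors.items()
                }
            except ValueError as exc:
                mlr_out[r.gene] = {"error": str(exc)}
        (out / "mlr.json").write_text(json.dumps(mlr_out, indent=1))
        report["stages"]["mlr"] = {"genes": list(mlr_out)}

    # -- run log -----------------------------------------------------------
    report["config"] = {
        **{
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "studies"
        },
        "n_studies_configured": len(config.studies),
        "defaults": {
            "log2_detection_threshold": 50.0,
            "probe_collapse": "max mean expression, lexicographic tie-break",
            "effect_variance": "Welch s1^2/n1 + s2^2/n2",
            "tau2_estimator": "DerSimonian-Laird",
            "model_selection": "fixed iff ISq == 0",
            "coexpression_split": "mean of the two genes, strictly above median = high",
            "cox_ties": "Breslow",
            "country_test": "partial F vs country-free model",
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# demo workspace
# ---------------------------------------------------------------------------

#: Study manifest modelled on a published 13-dataset gastric-cancer
#: case/control compendium: (study_id, n_control, n_case, country, year).
DEMO_MANIFEST: list[tuple[str, int, int, str, int]] = [
    ("GSE19826", 15, 12, "China", 2010),
    ("GSE3438", 49, 50, "South Korea", 2006),
    ("GSE13861", 19, 65, "USA", 2011),
    ("GSE13911", 31, 38, "Italy", 2008),
    ("GSE29272", 134, 134, "USA", 2013),
    ("GSE29998", 49, 50, "Singapore", 2012),
    ("GSE31811", 17, 21, "Japan", 2014),
    ("GSE37023-GPL97", 36, 29, "Singapore", 2012),
    ("GSE37023-GPL96", 36, 112, "Singapore", 2012),
    ("GSE44740", 12, 12, "United Kingdom", 2013),
    ("GSE64951", 31, 63, "USA", 2015),
    ("GSE79973", 10, 10, "China", 2016),
    ("GSE81948", 5, 15, "Italy", 2017),
]

#: The two consensus genes planted in the demo compendium, with their true
#: log2 fold changes and the number of studies whose panel carries them.
DEMO_PLANTED = {"CXCL8": (1.64, 10), "MMP9": (1.40, 6)}


def demo_truth(seed: int = 0, n_null: int = 102) -> simulate.SyntheticTruth:
    """Ground truth for the demo: 2 planted genes among ``n_null`` nulls."""
    planted = list(DEMO_PLANTED)
    gene_ids = tuple(planted + [f"NULL{i:03d}" for i in range(n_null)])
    mu = np.zeros(len(gene_ids))
    for i, g in enumerate(planted):
        mu[i] = DEMO_PLANTED[g][0]
    k_studies = len(DEMO_MANIFEST)
    rng = np.random.default_rng([seed, 3])
    masks = np.ones((k_studies, len(gene_ids)), dtype=bool)
    for i, g in enumerate(planted):
        k_measured = DEMO_PLANTED[g][1]
        off = rng.choice(k_studies, size=k_studies - k_measured, replace=False)
        masks[off, i] = False
    return simulate.SyntheticTruth(
        gene_ids=gene_ids,
        mu=mu,
        tau2=np.zeros(len(gene_ids)),
        platform_masks=masks,
        sigma=1.0,
        seed=seed,
        country_effect={"China": 0.5},
    )


def demo_fixture(directory: str | Path, seed: int = 0) -> dict[str, Any]:
    """Materialise a synthetic demo workspace and run the pipeline on it.

    Writes a 13-study compendium whose group sizes and countries mirror the
    gastric-cancer compendium above, a 104-gene signature list containing
    the two planted genes, and an n=200 survival cohort, then executes every
    stage.  Returns the run report.
    """
    directory = Path(directory)
    data_dir = directory / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    truth = demo_truth(seed)
    truth.to_json(data_dir / "truth.json")
    specs = [(nca, nco, country, date) for _, nco, nca, country, date in DEMO_MANIFEST]
    ids = [sid for sid, *_ in DEMO_MANIFEST]
    studies = simulate.generate_compendium(truth, specs, study_ids=ids)
    manifest_entries = []
    for study, (sid, nco, nca, country, date) in zip(studies, DEMO_MANIFEST):
        expr, labels = write_study(study, data_dir)
        manifest_entries.append(
            StudyManifestEntry(
                study_id=sid,
                expression=str(expr),
                labels=str(labels),
                country=country,
                date=date,
                n_case=nca,
                n_control=nco,
            )
        )

    sig_path = data_dir / "signature.txt"
    sig_path.write_text("\n".join(truth.gene_ids) + "\n")

    cohort = simulate.generate_survival_cohort(
        n=200, hr=2.0, median_gap=2.0, censor_rate=0.2, seed=seed
    )
    cohort_path = data_dir / "survival_cohort.csv"
    cohort.data.to_csv(cohort_path, index=False)

    config = PipelineConfig(
        signature=str(sig_path),
        output_dir=str(directory / "results"),
        studies=manifest_entries,
        seed=seed,
        survival_cohort=str(cohort_path),
    )
    (directory / "config.yaml").write_text(
        yaml.safe_dump(
            {
                **{
                    k: v
                    for k, v in dataclasses.asdict(config).items()
                    if k != "studies"
                },
                "studies": [dataclasses.asdict(e) for e in config.studies],
            },
            sort_keys=False,
        )
    )
    return run_pipeline(config)
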