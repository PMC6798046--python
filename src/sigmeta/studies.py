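"""Reading, normalising and reducing case/control expression studies.

A study is a genes × samples numeric matrix on the log2 scale, a per-sample
case/control label, and the study-level metadata (country, year, platform)
that the covariate-regression stage consumes.  This module also applies the
dataset-inclusion criteria used to assemble a multi-study compendium.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Matrix values above this are taken to be on the linear intensity scale.
#: Log2 microarray values rarely exceed ~20; linear intensities sit in the
#: hundreds to tens of thousands, so 50 separates the two regimes cleanly.
LOG2_DETECTION_THRESHOLD = 50.0

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class ExpressionStudy:
    """One expression study: log2 (or raw) matrix plus labels and metadata.

    Parameters
    ----------
    study_id:
        Accession-like label, e.g. ``"GSE19826"``.
    matrix:
        Genes × samples numeric table; the row index holds probe or gene
        identifiers and the columns hold sample identifiers.
    group:
        Per-sample label, ``"case"`` or ``"control"``, indexed by sample
        identifier in the same order as the matrix columns.
    platform_id:
        Platform label; studies run on several platforms are handled as
        separate :class:`ExpressionStudy` objects.
    country:
        Study country (the "population region" covariate).
    date:
        Study year.
    is_log2:
        Whether the matrix values are on the log2 scale (either natively or
        because :func:`detect_and_log2` transformed them).
    """

    study_id: str
    matrix: pd.DataFrame
    group: pd.Series
    platform_id: str = ""
    country: str = ""
    date: int | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.group):
            raise ValueError(
                f"study {self.study_id!r}: matrix has {self.matrix.shape[1]} "
                f"sample columns but {len(self.group)} group labels"
            )
        if list(self.matrix.columns) != list(self.group.index):
            raise ValueError(
                f"study {self.study_id!r}: sample order in matrix and group "
                "labels disagree"
            )
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: unknown group labels {sorted(bad)}"
            )
        if self.n_case == 0 or self.n_control == 0:
            raise ValueError(
                f"study {self.study_id!r}: both case and control samples are "
                f"required (got {self.n_case} cases, {self.n_control} controls)"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_case(self) -> int:
        return int((self.group == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.group == CONTROL).sum())

    @property
    def case_columns(self) -> list[str]:
        return list(self.group.index[self.group == CASE])

    @property
    def control_columns(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    def with_matrix(self, matrix: pd.DataFrame, **changes) -> "ExpressionStudy":
        return replace(self, matrix=matrix, **changes)


@dataclass(frozen=True)
class InclusionDecision:
    """Outcome of the dataset-inclusion screen for one study."""

    study_id: str
    included: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must be equivalent to an empty reason list")


def read_expression_table(
    path: str | Path,
    labels_path: str | Path,
    *,
    study_id: str | None = None,
    platform_id: str = "",
    country: str = "",
    date: int | None = None,
) -> ExpressionStudy:
    """Read a tab-separated expression table plus a sample-label file.

    The table's first column holds probe/gene identifiers and the header row
    holds sample identifiers; the labels file maps every sample to ``case``
    or ``control`` (two tab-separated columns, no header).  Values are
    returned untransformed — apply :func:`detect_and_log2` afterwards.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.empty or table.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    table.index = table.index.astype(str)
    table.index.name = None
    table.columns = table.columns.astype(str)
    try:
        table = table.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc

    labels_raw = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample_id", "label"]
    )
    labels = pd.Series(
        labels_raw["label"].astype(str).values,
        index=labels_raw["sample_id"].astype(str).values,
    )
    missing = [s for s in table.columns if s not in labels.index]
    if missing:
        raise ValueError(
            f"{labels_path}: no case/control label for sample(s) {missing}"
        )
    group = labels.reindex(table.columns)
    return ExpressionStudy(
        study_id=study_id or path.stem,
        matrix=table,
        group=group,
        platform_id=platform_id,
        country=country,
        date=date,
        is_log2=False,
    )


def detect_and_log2(study: ExpressionStudy) -> ExpressionStudy:
    """Log2-transform a study that is still on the linear intensity scale.

    If the matrix maximum exceeds ``LOG2_DETECTION_THRESHOLD`` every value v
    becomes log2(v + 1) (the pseudo-count guards zeros); otherwise the matrix
    is returned unchanged.  Idempotent, because a transformed matrix falls
    back below the threshold.
    """
    if study.matrix.size == 0:
        raise ValueError(f"study {study.study_id!r}: empty matrix")
    vmax = float(np.nanmax(study.matrix.values))
    if vmax <= LOG2_DETECTION_THRESHOLD:
        return replace(study, is_log2=True) if not study.is_log2 else study
    if float(np.nanmin(study.matrix.values)) < 0:
        raise ValueError(
            f"study {study.study_id!r}: negative values alongside a maximum of "
            f"{vmax:.3g} — scale is ambiguous, cannot log2-transform"
        )
    transformed = np.log2(study.matrix + 1.0)
    return study.with_matrix(transformed, is_log2=True)


def collapse_probes(
    study: ExpressionStudy, probe_to_gene: Mapping[str, str]
) -> ExpressionStudy:
    """Collapse probe-level rows to gene level.

    For each gene the single probe with the highest mean expression across
    all samples is kept (ties broken by the lexicographically smaller probe
    id).  Probes absent from the mapping are dropped with a logged count.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapped = [p for p in study.matrix.index if p in probe_to_gene]
    n_unmapped = study.matrix.shape[0] - len(mapped)
    if not mapped:
        raise ValueError(
            f"study {study.study_id!r}: no matrix row appears in the probe map"
        )
    if n_unmapped:
        logger.info(
            "study %s: dropped %d unmapped probe row(s)", study.study_id, n_unmapped
        )
    sub = study.matrix.loc[mapped]
    means = sub.mean(axis=1)
    choice = pd.DataFrame(
        {
            "gene": [probe_to_gene[p] for p in sub.index],
            "mean": means.values,
            "probe": sub.index,
        }
    )
    # max-mean rule; ties -> lexicographically smaller probe id
    choice = choice.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    keep = choice.drop_duplicates("gene", keep="first")
    collapsed = sub.loc[keep["probe"]]
    collapsed.index = keep["gene"].values
    return study.with_matrix(collapsed)


#: Canonical design label accepted by :func:`filter_datasets`.
CASE_CONTROL_ARRAY = "case-control expression profiling by array"


def _design_is_case_control_array(design: str) -> bool:
    d = design.lower()
    return "array" in d and "case" in d and "control" in d


def filter_datasets(
    metadata: Iterable[tuple[str, int, int, str, str]],
) -> list[InclusionDecision]:
    """Apply the dataset-inclusion criteria to study metadata rows.

    Each row is ``(study_id, n_case, n_control, organism, design)``.  A
    study is included iff the design is case-vs-control expression profiling
    by array, the total sample size is ≥ 20, each group has ≥ 5 samples, and
    the organism is Homo sapiens.  Violated criteria are enumerated in
    ``reasons``.
    """
    decisions: list[InclusionDecision] = []
    for study_id, n_case, n_control, organism, design in metadata:
        if n_case < 0 or n_control < 0:
            raise ValueError(f"study {study_id!r}: negative sample count")
        reasons: list[str] = []
        if not _design_is_case_control_array(design):
            reasons.append(
                "design is not case-vs-control expression profiling by array"
            )
        if n_case + n_control < 20:
            reasons.append(f"total sample size {n_case + n_control} < 20")
        if n_case < 5:
            reasons.append(f"cases {n_case} < 5")
        if n_control < 5:
            reasons.append(f"controls {n_control} < 5")
        if organism.strip().lower() != "homo sapiens":
            reasons.append(f"organism {organism!r} is not Homo sapiens")
        decisions.append(
            InclusionDecision(
                study_id=study_id,
                included=not reasons,
                reasons=tuple(reasons),
            )
        )
    return decisions


def subset_signature(
    study: ExpressionStudy, signature: Sequence[str]
) -> ExpressionStudy:
    """Restrict a study to the signature genes measured on its platform.

    Gene symbols are matched case-insensitively.  Signature genes absent from
    the platform are simply not in the result, so downstream pooling counts
    only the studies that measure each gene.
    """
    if not signature:
        raise ValueError("signature gene list is empty")
    by_upper: dict[str, str] = {}
    for g in study.matrix.index:
        by_upper.setdefault(str(g).upper(), g)
    present = [by_upper[s.upper()] for s in signature if s.upper() in by_upper]
    if not present:
        raise ValueError(
            f"study {study.study_id!r}: no overlap between the signature and "
            "the platform gene panel"
        )
    sub = study.matrix.loc[present].copy()
    # report under the signature's capitalisation
    rename = {by_upper[s.upper()]: s for s in signature if s.upper() in by_upper}
    sub.index = [rename[g] for g in sub.index]
    return study.with_matrix(sub)


def read_signature(path: str | Path) -> list[str]:
    """Read a one-gene-per-line signature file (blank lines ignored)."""
    genes = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not genes:
        raise ValueError(f"{path}: signature file contains no genes")
    return genes


def write_study(study: ExpressionStudy, directory: str | Path) -> tuple[Path, Path]:
    """Write a study as the expression + labels TSV pair the reader consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr_path = directory / f"{study.study_id}.expression.tsv"
    labels_path = directory / f"{study.study_id}.labels.tsv"
    study.matrix.to_csv(expr_path, sep="\t", index_label="gene_id")
    study.group.to_frame().to_csv(labels_path, sep="\t", header=False)
    return expr_path, labels_path
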