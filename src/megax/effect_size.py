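"""Per-study, per-gene log2 fold-change effect sizes.

The effect size is the difference of group means on the log2 scale
(case − control), with a Welch-form standard error

    SE = sqrt(s²_case / n_case + s²_control / n_control)

where s² is the unbiased sample variance within each group.  Linear-scale
intensity matrices are transformed with ``log2(x + 1)`` first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateEffectError, ValidationError
from .io import ExpressionStudy

logger = logging.getLogger(__name__)

#: heuristic bounds: a matrix whose values all lie in [-10, 30] is taken as log2
_LOG2_MAX = 30.0
_LOG2_MIN = -10.0


@dataclass(frozen=True)
class StudyEffect:
    """One gene's effect in one study: LFC (case − control), its SE and the
    group sizes.  ``degenerate`` marks the zero-variance-in-both-groups case
    where the SE is exactly 0."""

    study_id: str
    gene: str
    lfc: float
    se: float
    n_control: int
    n_case: int
    degenerate: bool = False

    def __post_init__(self):
        if not math.isfinite(self.lfc):
            raise ValidationError(f"{self.study_id}/{self.gene}: non-finite LFC")
        if self.se <= 0 and not self.degenerate:
            raise ValidationError(
                f"{self.study_id}/{self.gene}: se must be > 0 unless flagged degenerate"
            )


def detect_scale(study: ExpressionStudy) -> str:
    """Classify the intensity scale of *study* as ``log2`` or ``linear``.

    Heuristic: log2 iff every finite value lies in [-10, 30] (log2 microarray
    intensities rarely exceed ~16; raw intensities run to tens of thousands).
    """
    finite = study.values[np.isfinite(study.values)]
    if finite.size == 0:
        raise ValidationError(f"{study.metadata.study_id}: all-NA expression matrix")
    if finite.max() <= _LOG2_MAX and finite.min() >= _LOG2_MIN:
        return "log2"
    return "linear"


def to_log2(study: ExpressionStudy) -> ExpressionStudy:
    """Return a copy of *study* with values replaced by ``log2(x + 1)``.

    Requires ``study.scale == 'linear'`` and all values > −1.
    """
    if study.scale != "linear":
        raise ValidationError(
            f"{study.metadata.study_id}: to_log2 requires a linear-scale study (scale={study.scale!r})"
        )
    finite = study.values[np.isfinite(study.values)]
    if finite.size and finite.min() <= -1:
        raise ValidationError(f"{study.metadata.study_id}: values must be > -1 for log2(x+1)")
    return ExpressionStudy(
        metadata=study.metadata,
        genes=list(study.genes),
        values=np.log2(study.values + 1.0),
        group=list(study.group),
        sample_ids=list(study.sample_ids),
        scale="log2",
    )


def ensure_log2(study: ExpressionStudy) -> ExpressionStudy:
    """Detect the scale if unset and log-transform linear studies."""
    if study.scale is None:
        study.scale = detect_scale(study)
    return to_log2(study) if study.scale == "linear" else study


def collapse_duplicates(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse duplicate gene symbols to the row with highest mean expression.

    Ties keep the first occurrence; the output preserves first-occurrence
    gene order.  Mirrors the common probe→gene reduction for array data.
    """
    if len(set(study.genes)) == len(study.genes):
        return study
    best: dict[str, int] = {}
    means = np.nanmean(study.values, axis=1)
    order: list[str] = []
    for i, g in enumerate(study.genes):
        if g not in best:
            best[g] = i
            order.append(g)
        elif means[i] > means[best[g]]:
            best[g] = i
    keep = [best[g] for g in order]
    return ExpressionStudy(
        metadata=study.metadata,
        genes=order,
        values=study.values[keep],
        group=list(study.group),
        sample_ids=list(study.sample_ids),
        scale=study.scale,
    )


def compute_study_effect(study: ExpressionStudy, gene: str) -> StudyEffect:
    """Welch-form LFC effect for one gene in one study.

    Samples with missing values are dropped; each group must retain at least
    two usable samples.  The study must already be on the log2 scale.
    """
    if study.scale != "log2":
        raise ValidationError(
            f"{study.metadata.study_id}: effects require log2 scale (call ensure_log2 first)"
        )
    row = study.gene_row(gene)
    ctrl = row[study.control_mask]
    case = row[study.case_mask]
    ctrl = ctrl[np.isfinite(ctrl)]
    case = case[np.isfinite(case)]
    if len(ctrl) < 2 or len(case) < 2:
        raise DegenerateEffectError(
            f"{study.metadata.study_id}/{gene}: needs >=2 usable samples per group "
            f"(got {len(ctrl)} control, {len(case)} case)"
        )
    lfc = float(case.mean() - ctrl.mean())
    var = case.var(ddof=1) / len(case) + ctrl.var(ddof=1) / len(ctrl)
    se = float(np.sqrt(var))
    return StudyEffect(
        study_id=study.metadata.study_id,
        gene=gene,
        lfc=lfc,
        se=se,
        n_control=len(ctrl),
        n_case=len(case),
        degenerate=(se == 0.0),
    )


def compute_effect_table(
    studies: Iterable[ExpressionStudy],
    genes: Sequence[str] | None = None,
    collapse: bool = True,
) -> list[StudyEffect]:
    """Compute effects for *genes* across *studies* (all genes if ``None``).

    Genes with any missing value in a study are excluded from that study's
    effects (logged); studies lacking a gene simply contribute no row for it.
    """
    effects: list[StudyEffect] = []
    for study in studies:
        study = ensure_log2(study)
        if collapse:
            study = collapse_duplicates(study)
        targets = genes if genes is not None else study.genes
        for gene in targets:
            if gene not in study.genes:
                continue
            row = study.gene_row(gene)
            if not np.all(np.isfinite(row)):
                logger.info(
                    "%s/%s: missing values; gene excluded from this study",
                    study.metadata.study_id, gene,
                )
                continue
            effects.append(compute_study_effect(study, gene))
    return effects


def standardized_effect(effect: StudyEffect) -> StudyEffect:
    """Optional standardized variant: LFC and SE divided by the pooled-sample
    scale implied by the Welch SE, giving a unit-variance z-style effect.

    Exposed for exploration; the pipeline pools raw LFC.
    """
    if effect.se <= 0:
        raise DegenerateEffectError(f"{effect.study_id}/{effect.gene}: zero SE")
    denom = effect.se * math.sqrt(effect.n_control + effect.n_case)
    return replace(effect, lfc=effect.lfc / denom, se=effect.se / denom)
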