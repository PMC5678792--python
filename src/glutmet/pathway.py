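"""Per-sample pathway activity scores and group-level comparisons.

A process with several genes is summarized by the first principal
component of its gene-by-sample expression block (genes centered and,
by default, scaled to unit variance), fitted jointly on cancer and
control samples so both groups live on one scale.  A single-gene
process passes through as the centered (scaled) expression row.  The
PC sign is arbitrary, so the score is anchored to correlate
non-negatively with the mean expression of the genes used: higher
expression of the process's genes means a higher activity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .registry import ProcessGeneSet, Registry

logger = logging.getLogger(__name__)


@dataclass
class ActivityScore:
    """One per-sample scalar summarizing a process's expression."""

    process_id: str
    scores: pd.Series  # indexed by sample id, zero mean
    orientation: int  # +1 / -1 sign applied to the raw PC direction
    variance_explained: float
    genes_used: tuple[str, ...]


@dataclass
class PathwayComparison:
    """Welch t comparison of an activity score between cancer and control."""

    process_id: str
    mean_cancer: float
    mean_control: float
    change: float  # mean_cancer - mean_control
    t_stat: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def score_process(
    matrix: ExpressionMatrix,
    geneset: ProcessGeneSet,
    scale: bool = True,
) -> ActivityScore:
    """Score one process on all samples of ``matrix``.

    Multi-gene sets use PC1 of the centered (optionally scaled) gene
    block; single-gene sets use the centered row.  Deterministic.
    """
    present = [g for g in sorted(geneset.genes) if g in matrix.genes]
    missing = sorted(geneset.genes - set(present))
    if not present:
        raise ValidationError(
            f"process {geneset.id!r}: none of its genes are in the matrix "
            f"(missing: {missing})"
        )
    if missing:
        logger.warning("process %s: dropping absent genes %s", geneset.id, missing)
    if matrix.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples to score a process")

    block = matrix.values.loc[present].to_numpy(dtype=float)
    centered = block - block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1)
    if np.any(sd == 0):
        flat = [g for g, s in zip(present, sd) if s == 0]
        raise ValidationError(
            f"process {geneset.id!r}: zero-variance gene rows {flat}"
        )
    if scale:
        centered = centered / sd[:, None]

    if len(present) == 1:
        raw = centered[0]
        var_explained = 1.0
    else:
        # PC1 via SVD of the centered block; per-sample score is the
        # projection onto the leading gene-space direction.
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        raw = s[0] * vt[0]
        var_explained = float(s[0] ** 2 / np.sum(s**2))

    mean_profile = centered.mean(axis=0)
    corr = float(np.dot(raw, mean_profile))
    orientation = -1 if corr < 0 else 1
    scores = pd.Series(orientation * raw, index=matrix.samples, name=geneset.id)
    return ActivityScore(
        process_id=geneset.id,
        scores=scores,
        orientation=orientation,
        variance_explained=var_explained,
        genes_used=tuple(present),
    )


def compare_levels(score: ActivityScore, annotation: pd.DataFrame) -> PathwayComparison:
    """Welch two-sample t of the activity score, cancer vs control."""
    groups = annotation.loc[score.scores.index, "group"]
    cancer = score.scores[groups == "cancer"].to_numpy()
    control = score.scores[groups == "control"].to_numpy()
    if len(cancer) == 0 or len(control) == 0:
        raise ValidationError(
            f"process {score.process_id!r}: both groups must be present to compare"
        )
    if np.array_equal(np.sort(cancer), np.sort(control)):
        t, p = 0.0, 1.0  # identical distributions; Welch t is 0/0 when var is 0
    else:
        t, p = stats.ttest_ind(cancer, control, equal_var=False)
    return PathwayComparison(
        process_id=score.process_id,
        mean_cancer=float(cancer.mean()),
        mean_control=float(control.mean()),
        change=float(cancer.mean() - control.mean()),
        t_stat=float(t),
        p_value=float(p),
    )


def metabolism_change(
    matrix: ExpressionMatrix,
    registry: Registry,
    process_ids: list[str] | tuple[str, ...],
    scale: bool = True,
) -> pd.DataFrame:
    """Per-cohort change in a combined process score (cancer minus control).

    The genes of all requested processes are pooled into one set, scored
    per cohort (PCA fitted on that cohort's cancer+control samples), and
    compared between groups.  Returns a DataFrame indexed by cohort with
    columns change, t_stat, p_value, significant.
    """
    genes = registry.union_genes(process_ids)
    combined = ProcessGeneSet(
        id="+".join(process_ids), name="combined", genes=genes, role="synthesis"
    )
    rows = {}
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        comp = compare_levels(score_process(sub, combined, scale=scale), sub.annotation)
        rows[cohort] = {
            "change": comp.change,
            "t_stat": comp.t_stat,
            "p_value": comp.p_value,
            "significant": comp.significant,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cohort"
    return out


def comparison_table(
    matrix: ExpressionMatrix,
    registry: Registry,
    process_ids: list[str] | None = None,
    scale: bool = True,
) -> pd.DataFrame:
    """Long-format per-(process, cohort) comparison table."""
    ids = process_ids if process_ids is not None else registry.ids()
    records = []
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        for pid in ids:
            gs = registry.lookup(pid)
            try:
                comp = compare_levels(score_process(sub, gs, scale=scale), sub.annotation)
            except ValidationError as exc:
                logger.warning("cohort %s process %s skipped: %s", cohort, pid, exc)
                continue
            records.append(
                {
                    "cohort": cohort,
                    "process": pid,
                    "change": comp.change,
                    "t_stat": comp.t_stat,
                    "p_value": comp.p_value,
                    "significant": comp.significant,
                }
            )
    return pd.DataFrame.from_records(records)
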