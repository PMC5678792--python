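"""Cross-cohort correlations and conditional co-expression.

Three analyses live here:

* plain Pearson correlation between two cohort-level vectors (e.g. the
  per-cohort change in glutamine-metabolism activity vs an externally
  supplied 5-year survival rate);
* a proteasome-based proxy for the change in intracellular reactive
  oxygen species (ROS) burden, computed as the cancer-minus-control
  change of the proteasome gene-set activity score per cohort;
* conditional co-expression: anchor genes (by default the nucleotide-
  synthesis rate-limiters PPAT and CAD) define a composite via PC1,
  samples inside a central quantile band of that composite are treated
  as having constant nucleotide-synthesis level, and anchor-vs-target
  correlations are recomputed on that subset, blanking cells whose P
  exceeds the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .pathway import metabolism_change, score_process
from .registry import ProcessGeneSet, Registry

#: Default proteasome gene set used as the ROS-burden proxy.
PROTEASOME_GENES = frozenset(
    {"PSMD1", "PSMD2", "PSMD11", "PSMD14", "PSME3", "PSME4", "PSMB5"}
)

PROTEASOME_SET = ProcessGeneSet(
    id="proteasome",
    name="Proteasome subunits (ROS proxy)",
    genes=PROTEASOME_GENES,
    role="antioxidant",
)


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided t-based P value."""

    r: float
    p_value: float
    n: int
    label_x: str = "x"
    label_y: str = "y"


@dataclass
class CondCoexprConfig:
    """Settings for the conditional co-expression analysis."""

    anchor_genes: tuple[str, ...] = ("PPAT", "CAD")
    band: tuple[float, float] = (0.4, 0.6)  # central quantile interval
    target_genes: tuple[str, ...] = tuple(sorted(PROTEASOME_GENES))
    p_threshold: float = 0.05
    min_samples: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi <= 1):
            raise ValidationError("band must satisfy 0 <= lower < upper <= 1")
        if not self.anchor_genes:
            raise ValidationError("at least one anchor gene is required")


def pearson(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    label_x: str = "x",
    label_y: str = "y",
) -> CorrelationResult:
    """Pearson r with two-sided P from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), p_value=float(p), n=len(x), label_x=label_x, label_y=label_y
    )


def merge_cohorts(values: pd.Series, merge: dict[str, list[str]]) -> pd.Series:
    """Average named cohort subsets into one value each (e.g. kidney subtypes).

    ``merge`` maps a new label to the cohorts it replaces; all other
    cohorts pass through unchanged.
    """
    out = values.copy()
    for label, members in merge.items():
        missing = [c for c in members if c not in out.index]
        if missing:
            raise ValidationError(f"merge group {label!r}: cohorts {missing} absent")
        out = out.drop(members)
        out[label] = float(values[members].mean())
    return out.sort_index()


def correlate_change(
    change: pd.Series,
    external: pd.Series,
    merge: dict[str, list[str]] | None = None,
    label_x: str = "change",
    label_y: str = "external",
) -> CorrelationResult:
    """Correlate a per-cohort change score with an external cohort vector."""
    if merge:
        change = merge_cohorts(change, merge)
    common = change.index.intersection(external.index)
    if len(common) < 3:
        raise ValidationError(
            f"need at least 3 shared cohorts, got {len(common)}"
        )
    return pearson(change[common], external[common], label_x=label_x, label_y=label_y)


def ros_change(
    matrix: ExpressionMatrix,
    proteasome_set: ProcessGeneSet = PROTEASOME_SET,
) -> pd.DataFrame:
    """Per-cohort change in proteasome activity (the ROS-burden proxy)."""
    registry = Registry([proteasome_set])
    return metabolism_change(matrix, registry, [proteasome_set.id])


def conditional_coexpression(
    matrix: ExpressionMatrix,
    config: CondCoexprConfig | None = None,
) -> pd.DataFrame:
    """Anchor-vs-target correlations within a constant-anchor sample band.

    Returns a wide table (anchor genes as rows, target genes as columns)
    of Pearson r values; cells with P above ``config.p_threshold`` are
    NaN, mirroring a blank in the exported matrix.  Pass a full-width
    band ``(0, 1)`` for plain all-sample correlations.
    """
    config = config or CondCoexprConfig()
    missing = [g for g in config.anchor_genes if g not in matrix.genes]
    if missing:
        raise ValidationError(f"anchor genes absent from matrix: {missing}")

    anchor_set = ProcessGeneSet(
        id="anchor", name="anchor composite", genes=frozenset(config.anchor_genes)
    )
    composite = score_process(matrix, anchor_set).scores
    lo, hi = config.band
    q_lo, q_hi = composite.quantile([lo, hi])
    keep = composite.index[(composite >= q_lo) & (composite <= q_hi)]
    if len(keep) < config.min_samples:
        raise ValidationError(
            f"band {config.band} retains only {len(keep)} samples "
            f"(< {config.min_samples}); widen the band"
        )

    sub = matrix.values.loc[:, keep]
    rows = {}
    for anchor in config.anchor_genes:
        row = {}
        for target in config.target_genes:
            if target not in matrix.genes:
                row[target] = np.nan
                continue
            res = pearson(
                sub.loc[anchor], sub.loc[target], label_x=anchor, label_y=target
            )
            row[target] = res.r if res.p_value <= config.p_threshold else np.nan
        rows[anchor] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "anchor"
    return out


def conditional_coexpression_by_cohort(
    matrix: ExpressionMatrix, config: CondCoexprConfig | None = None
) -> pd.DataFrame:
    """Run :func:`conditional_coexpression` per cohort; long-format output."""
    config = config or CondCoexprConfig()
    frames = []
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        wide = conditional_coexpression(sub, config)
        long = wide.reset_index().melt(
            id_vars="anchor", var_name="target", value_name="r"
        )
        long.insert(0, "cohort", cohort)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
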