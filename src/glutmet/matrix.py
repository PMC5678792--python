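"""Log-scale expression matrix with per-sample group/cohort annotations.

The matrix holds log2-scale expression values, genes in rows and samples
in columns, together with a sample annotation table carrying a ``group``
column (``cancer`` / ``control``) and a ``cohort`` label.  It is the
universal input to every downstream analysis.  Cohorts with fewer than
ten samples in either group can be dropped up front, mirroring the usual
inclusion filter for two-group tumor/normal comparisons.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("cancer", "control")
#: Minimum samples per group for a cohort to enter grouped analyses.
MIN_GROUP_SIZE = 10


class ExpressionMatrix:
    """Genes x samples log2 expression values plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    annotation
        DataFrame indexed by sample id with columns ``group`` and
        ``cohort``; its index must match ``values.columns`` exactly.
    """

    def __init__(self, values: pd.DataFrame, annotation: pd.DataFrame):
        self.values = values
        self.annotation = annotation
        self.validate()

    def validate(self) -> None:
        v, a = self.values, self.annotation
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        for col in ("group", "cohort"):
            if col not in a.columns:
                raise ValidationError(f"annotation lacks required column {col!r}")
        if list(a.index) != list(v.columns):
            raise ValidationError("annotation index does not match matrix sample columns")
        bad = set(a["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.annotation["cohort"].unique())

    def group_mask(self, group: str) -> pd.Series:
        return self.annotation["group"] == group

    def subset_cohort(self, cohort: str) -> "ExpressionMatrix":
        mask = self.annotation["cohort"] == cohort
        if not mask.any():
            from .errors import NotFoundError

            raise NotFoundError(f"cohort {cohort!r} not present in annotation")
        return ExpressionMatrix(self.values.loc[:, mask.to_numpy()], self.annotation.loc[mask])

    def group_sizes(self, cohort: str | None = None) -> dict[str, int]:
        a = self.annotation
        if cohort is not None:
            a = a[a["cohort"] == cohort]
        return {g: int((a["group"] == g).sum()) for g in GROUPS}

    def filter_cohorts(self, min_per_group: int = MIN_GROUP_SIZE) -> "ExpressionMatrix":
        """Drop cohorts with fewer than ``min_per_group`` samples in either group."""
        keep: list[str] = []
        for cohort in self.cohorts:
            sizes = self.group_sizes(cohort)
            if all(sizes[g] >= min_per_group for g in GROUPS):
                keep.append(cohort)
            else:
                logger.warning(
                    "cohort %s excluded: below minimum group size (%s)", cohort, sizes
                )
        if not keep:
            raise ValidationError(
                f"no cohort has at least {min_per_group} samples in both groups"
            )
        mask = self.annotation["cohort"].isin(keep)
        return ExpressionMatrix(self.values.loc[:, mask.to_numpy()], self.annotation.loc[mask])


# -- TSV I/O ------------------------------------------------------------------


def read_expression(matrix_path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) and an annotation TSV.

    Lines starting with ``#`` (metadata headers written by this package)
    are ignored.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values, annotation)


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    annotation_path: str | Path,
    header: str | None = None,
) -> None:
    """Write matrix + annotation as TSV; values at full float precision."""
    for path, frame, label in (
        (matrix_path, matrix.values, "gene"),
        (annotation_path, matrix.annotation, "sample"),
    ):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            frame.to_csv(fh, sep="\t", index_label=label)
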