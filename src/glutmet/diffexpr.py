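"""Two-group differential expression with an empirical-Bayes moderated t.

A gene is called up- or down-regulated when its signed linear fold
change between the cancer and control group means exceeds +/-1.5 and the
two-sided P value of its t statistic is at most 0.05.  The t statistic
uses per-gene variances shrunk toward a common prior: the prior scale
s0^2 and degrees of freedom d0 are estimated by matching the first two
moments of the log residual variances (digamma/trigamma identities for
the log of a scaled chi-square), and each gene's posterior variance is
the d0/d weighted average of prior and observed variance.  The moderated
t then carries d0 + d degrees of freedom.  With moderation off the
statistic reduces exactly to the ordinary pooled-variance two-sample t.

Fold changes are computed on the linear scale (values are stored as
log2, so group means are averaged after inverse transform) and reported
as a signed ratio: r when cancer/control >= 1, otherwise -control/cancer,
so the +/-1.5 cutoff is symmetric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EstimationError, ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    """Thresholds and options for differential-expression calls."""

    fc_threshold: float = 1.5  # signed linear fold change
    p_threshold: float = 0.05
    variance_moderation: bool = True
    bh_correction: bool = False  # off by default: raw per-gene P values

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValidationError("fc_threshold must be > 1")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")


def signed_fold_change(mean_cancer: float, mean_control: float) -> float:
    """Signed linear fold change of two positive group means.

    Returns ``mean_cancer/mean_control`` when the ratio is >= 1 and
    ``-mean_control/mean_cancer`` otherwise, so |result| >= 1 always.
    """
    if mean_cancer <= 0 or mean_control <= 0:
        raise ValidationError("group means must be positive on the linear scale")
    if mean_cancer >= mean_control:
        return mean_cancer / mean_control
    return -mean_control / mean_cancer


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward an estimated common prior.

    Fits a scaled F prior to the observed variances by moment matching
    on log(s2): the mean of the adjusted logs gives the prior scale
    s0^2, and inverting the trigamma function on the excess variance of
    the logs gives the prior degrees of freedom d0 (infinite when the
    observed spread is no larger than chi-square sampling noise).

    Returns (posterior variances, d0, s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise EstimationError("all gene variances are zero; cannot moderate")
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        raise EstimationError("need at least 2 genes with positive variance")
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    if np.isfinite(d0):
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s0_2)
    return post, float(d0), s0_2


def moderated_t(matrix: ExpressionMatrix, config: DEConfig | None = None) -> pd.DataFrame:
    """Per-gene two-group test of cancer vs control for one cohort's matrix.

    Returns a DataFrame indexed by gene with columns ``signed_fc``,
    ``log2_fc``, ``t_stat``, ``p_value``, ``df``, ``call``.
    """
    config = config or DEConfig()
    groups = matrix.annotation["group"]
    # enforce one memory layout so reduction order (hence the last ulp)
    # is identical regardless of how the caller assembled the frame
    cancer = np.ascontiguousarray(
        matrix.values.loc[:, (groups == "cancer").to_numpy()].to_numpy(dtype=float)
    )
    control = np.ascontiguousarray(
        matrix.values.loc[:, (groups == "control").to_numpy()].to_numpy(dtype=float)
    )
    n1, n2 = cancer.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 samples per group")

    mean1 = cancer.mean(axis=1)
    mean2 = control.mean(axis=1)
    diff = mean1 - mean2
    df_resid = float(n1 + n2 - 2)
    ss = cancer.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    moderate = config.variance_moderation
    if moderate and matrix.values.shape[0] < 2:
        warnings.warn(
            "single-gene matrix: falling back to the ordinary two-sample t",
            stacklevel=2,
        )
        moderate = False

    if moderate:
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
        df_total = d0 + df_resid
    else:
        s2_post = s2
        df_total = df_resid

    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    ok = denom > 0
    t[ok] = diff[ok] / denom[ok]
    t[~ok & (diff != 0)] = np.sign(diff[~ok & (diff != 0)]) * np.inf
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))

    lin1 = np.exp2(cancer).mean(axis=1)
    lin2 = np.exp2(control).mean(axis=1)
    sfc = np.array([signed_fold_change(a, b) for a, b in zip(lin1, lin2)])
    log2_fc = np.log2(lin1 / lin2)

    p_call = p
    if config.bh_correction:
        from statsmodels.stats.multitest import multipletests

        p_call = multipletests(p, method="fdr_bh")[1]
    call = np.full(len(sfc), "none", dtype=object)
    call[(sfc > config.fc_threshold) & (p_call <= config.p_threshold)] = "up"
    call[(sfc < -config.fc_threshold) & (p_call <= config.p_threshold)] = "down"

    return pd.DataFrame(
        {
            "signed_fc": sfc,
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_value": p,
            "df": df_total,
            "call": call,
        },
        index=matrix.genes,
    )


def de_table(matrix: ExpressionMatrix, config: DEConfig | None = None) -> pd.DataFrame:
    """Per-cohort DE calls: long table (cohort, gene, signed_fc, t, P, call).

    Cohorts lacking one of the two groups are skipped with a warning.
    """
    config = config or DEConfig()
    frames = []
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        sizes = sub.group_sizes()
        if min(sizes.values()) < 2:
            logger.warning("cohort %s skipped: group sizes %s", cohort, sizes)
            continue
        res = moderated_t(sub, config)
        res = res.reset_index(names="gene")
        res.insert(0, "cohort", cohort)
        frames.append(res)
    if not frames:
        raise ValidationError("no cohort had both groups with >= 2 samples")
    return pd.concat(frames, ignore_index=True)
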