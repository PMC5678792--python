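"""Multiple-group interaction regression for differential substrate contribution.

The product pathway's per-sample activity y_p is regressed on the
reactant activities x_1..x_M together with a binary group indicator ID
(1 = cancer, 0 = control) and the reactant-by-group interactions:

    y_p = b0 + a0*ID + b1*x_1 + ... + bM*x_M + a1*(x_1:ID) + ... + aM*(x_M:ID)

The main effects b_m are the reactant slopes in control tissue; each
interaction coefficient a_m is the difference of that slope in cancer.
A reactant whose interaction term is significantly positive is
classified as having an *increased* contribution to the product in
cancer, significantly negative as *decreased*, otherwise *none*.

Fitting is ordinary least squares with classical standard errors
(heteroskedasticity-robust errors are available behind a flag); each
coefficient gets a two-sided t test on n - (2M+2) residual degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import RankDeficiencyError, ValidationError
from .matrix import ExpressionMatrix
from .pathway import score_process
from .registry import ProcessGeneSet, ReactionSpec, Registry

P_SIGNIFICANT = 0.05


@dataclass
class ContributionModelSpec:
    """Assembled per-sample inputs of one interaction regression."""

    product: np.ndarray  # y_p, length n
    reactants: dict[str, np.ndarray]  # name -> x_m, each length n
    group_indicator: np.ndarray  # ID in {0, 1}, length n

    def __post_init__(self) -> None:
        n = len(self.product)
        if any(len(x) != n for x in self.reactants.values()) or len(
            self.group_indicator
        ) != n:
            raise ValidationError("all model vectors must have the same length")
        if not self.reactants:
            raise ValidationError("at least one reactant is required")
        uniq = set(np.unique(self.group_indicator))
        if not uniq <= {0, 1} or len(uniq) != 2:
            raise ValidationError("group indicator must contain both 0 and 1")

    @property
    def n_samples(self) -> int:
        return len(self.product)

    @property
    def n_reactants(self) -> int:
        return len(self.reactants)


@dataclass
class ContributionFit:
    """OLS estimates for one product pathway in one cohort.

    ``table`` has one row per coefficient (intercept, ID, each reactant
    main effect, each reactant:ID interaction) with estimate, SE, t, P.
    """

    table: pd.DataFrame
    df_resid: int
    classification: dict[str, str] = field(default_factory=dict)

    @property
    def id_significant(self) -> bool:
        return bool(self.table.loc["ID", "p_value"] <= P_SIGNIFICANT)

    def coefficient(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])


def _classify(estimate: float, p_value: float) -> str:
    if p_value <= P_SIGNIFICANT:
        return "increased" if estimate > 0 else "decreased"
    return "none"


def fit_contribution(
    spec: ContributionModelSpec,
    robust: bool = False,
    standardize: bool = False,
) -> ContributionFit:
    """Fit the interaction regression and classify each reactant.

    With ``standardize`` the reactant and product vectors are divided by
    their sample standard deviation first, making coefficients
    comparable across reactants measured on different scales.
    """
    names = list(spec.reactants)
    m = spec.n_reactants
    n = spec.n_samples
    n_params = 2 * m + 2
    if n <= n_params:
        raise ValidationError(
            f"need more than {n_params} samples to fit {m} reactants, got {n}"
        )

    y = np.asarray(spec.product, dtype=float)
    xs = {k: np.asarray(v, dtype=float) for k, v in spec.reactants.items()}
    if standardize:
        y = y / y.std(ddof=1)
        xs = {k: v / v.std(ddof=1) for k, v in xs.items()}
    gid = np.asarray(spec.group_indicator, dtype=float)

    cols = {"intercept": np.ones(n), "ID": gid}
    for k in names:
        cols[k] = xs[k]
    for k in names:
        cols[f"{k}:ID"] = xs[k] * gid
    design = pd.DataFrame(cols)

    x_mat = design.to_numpy()
    rank = np.linalg.matrix_rank(x_mat)
    if rank < n_params:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(x_mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag[0] * max(x_mat.shape) * np.finfo(float).eps
        bad = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {n_params}); "
            f"collinear columns: {bad}"
        )

    model = sm.OLS(y, design)
    fitted = model.fit(cov_type="HC3") if robust else model.fit()
    table = pd.DataFrame(
        {
            "estimate": fitted.params,
            "se": fitted.bse,
            "t_stat": fitted.tvalues,
            "p_value": fitted.pvalues,
        }
    )
    table.index.name = "term"
    classification = {
        k: _classify(table.loc[f"{k}:ID", "estimate"], table.loc[f"{k}:ID", "p_value"])
        for k in names
    }
    return ContributionFit(
        table=table, df_resid=int(fitted.df_resid), classification=classification
    )


def run_product(
    matrix: ExpressionMatrix,
    registry: Registry,
    reaction: ReactionSpec,
    robust: bool = False,
    scale_genes: bool = True,
) -> dict[str, ContributionFit]:
    """Score product and reactants per cohort and fit the regression.

    The product score pools the genes of all product processes; each
    reactant route pools its synthesis/uptake processes.  Scores are
    standardized before fitting so coefficients are comparable across
    reactants.  Returns one :class:`ContributionFit` per cohort.
    """
    fits: dict[str, ContributionFit] = {}
    for cohort in matrix.cohorts:
        sub = matrix.subset_cohort(cohort)
        try:
            product_set = ProcessGeneSet(
                id=f"{reaction.product_id}",
                name="product",
                genes=registry.union_genes(reaction.product_processes),
            )
            y = score_process(sub, product_set, scale=scale_genes).scores.to_numpy()
            xs = {}
            for name, pids in reaction.reactant_routes:
                rset = ProcessGeneSet(
                    id=name, name=name, genes=registry.union_genes(pids)
                )
                xs[name] = score_process(sub, rset, scale=scale_genes).scores.to_numpy()
            gid = (sub.annotation["group"] == "cancer").to_numpy().astype(float)
            spec = ContributionModelSpec(
                product=y, reactants=xs, group_indicator=gid
            )
            fits[cohort] = fit_contribution(spec, robust=robust, standardize=True)
        except (ValidationError, RankDeficiencyError) as exc:
            raise type(exc)(
                f"cohort {cohort!r}, product {reaction.product_id!r}: {exc}"
            ) from exc
    return fits


def classification_table(
    fits_by_product: dict[str, dict[str, ContributionFit]],
) -> pd.DataFrame:
    """Long-format summary across products and cohorts.

    One row per (cohort, product, term) with estimate, SE, t, P, and the
    increased/decreased/none classification for interaction terms.
    """
    records = []
    for product_id, by_cohort in fits_by_product.items():
        for cohort, fit in by_cohort.items():
            for term, row in fit.table.iterrows():
                cls = ""
                if term.endswith(":ID"):
                    cls = fit.classification[term[: -len(":ID")]]
                records.append(
                    {
                        "cohort": cohort,
                        "product": product_id,
                        "term": term,
                        "estimate": row["estimate"],
                        "se": row["se"],
                        "t_stat": row["t_stat"],
                        "p_value": row["p_value"],
                        "classification": cls,
                    }
                )
    return pd.DataFrame.from_records(records)
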