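"""Synthetic expression cohorts with planted latent pathway structure.

The generator emits exactly the statistical structure the downstream
analyses assume.  For a chosen reaction (product pathway plus reactant
routes) and a :class:`SimTruth`:

* each reactant m gets a latent per-sample activity
  z_m = delta_m * ID + Normal(0, 1), where ID is 1 for cancer samples
  and 0 for controls, so delta_m is the group mean shift in units of
  the latent's standard deviation;
* the product's latent activity is the group-specific linear
  combination y = b0 + a0*ID + sum_m (b_m + a_m*ID) * z_m + Normal(0, sigma^2),
  the generative mirror of the interaction regression fitted by
  :mod:`glutmet.contribution`;
* every gene of a process loads positively on its process's latent
  (genes shared by several processes load on their mean), with a
  per-gene baseline and Normal(0, tau^2) noise, all on the log2 scale;
* a configurable number of background genes carry baseline plus noise
  only.

One integer seed drives everything through deterministically spawned
substreams, so an identical :class:`SimTruth` reproduces a cohort
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .matrix import ExpressionMatrix, write_expression
from .registry import ProcessGeneSet, ReactionSpec, Registry, write_gmt

#: Row label of the product activity in the returned latents frame.
PRODUCT_ROW = "product"


@dataclass(frozen=True)
class SimTruth:
    """Planted parameters of one simulated cohort.

    Coefficients are on the standardized activity scale (latents have
    unit within-group variance); shifts, baselines and noise are in
    log2 expression units.
    """

    n_cancer: int = 30
    n_control: int = 30
    beta0: float = 0.0
    alpha0: float = 0.0
    beta: tuple[float, ...] = (0.5, 0.5)
    alpha: tuple[float, ...] = (0.0, 0.0)
    delta: tuple[float, ...] = (0.0, 0.0)  # per-reactant group shift
    sigma: float = 1.0  # product activity noise sd
    tau: float = 0.3  # per-gene noise sd
    loading_low: float = 0.8  # gene loadings drawn U(low, high), all > 0
    loading_high: float = 1.2
    baseline_low: float = 4.0  # per-gene baseline drawn U(low, high), log2
    baseline_high: float = 10.0
    n_background: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 10 or self.n_control < 10:
            raise ValidationError(
                "cohorts need at least 10 cancer and 10 control samples"
            )
        if len(self.beta) != len(self.alpha) or len(self.beta) != len(self.delta):
            raise ValidationError("beta, alpha and delta must have equal length")
        if self.sigma < 0 or self.tau < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        if not (0 < self.loading_low <= self.loading_high):
            raise ValidationError("gene loadings must be positive")
        if self.n_background < 0:
            raise ValidationError("n_background must be non-negative")


def synthetic_reaction(
    n_reactants: int = 2,
    genes_per_reactant: int = 5,
    genes_per_product: int = 6,
) -> tuple[Registry, ReactionSpec]:
    """A synthetic registry + reaction with disjoint single-process routes."""
    processes = []
    routes = []
    for m in range(1, n_reactants + 1):
        genes = frozenset(f"R{m}G{j}" for j in range(1, genes_per_reactant + 1))
        processes.append(
            ProcessGeneSet(id=f"R{m}", name=f"synthetic reactant {m}", genes=genes,
                           role="uptake")
        )
        routes.append((f"r{m}", (f"R{m}",)))
    product_genes = frozenset(f"PRODG{j}" for j in range(1, genes_per_product + 1))
    processes.append(
        ProcessGeneSet(id="PROD", name="synthetic product", genes=product_genes)
    )
    registry = Registry(processes)
    reaction = ReactionSpec("synthetic_product", ("PROD",), tuple(routes))
    return registry, reaction


def simulate_cohort(
    truth: SimTruth,
    registry: Registry,
    reaction: ReactionSpec,
    cohort: str = "SIM",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one cohort's expression matrix plus its latent activities.

    Returns ``(matrix, latents)`` where ``latents`` has one row per
    reactant route (named as in the reaction) plus a ``product`` row.
    """
    reaction.validate_against(registry)
    m = len(reaction.reactant_routes)
    if len(truth.beta) != m:
        raise ValidationError(
            f"truth has {len(truth.beta)} coefficient slots but reaction "
            f"{reaction.product_id!r} has {m} reactant routes"
        )

    n1, n2 = truth.n_cancer, truth.n_control
    n = n1 + n2
    gid = np.concatenate([np.ones(n1), np.zeros(n2)])
    samples = [f"{cohort}_C{i:03d}" for i in range(1, n1 + 1)] + [
        f"{cohort}_N{i:03d}" for i in range(1, n2 + 1)
    ]

    ss = np.random.SeedSequence(truth.seed)
    rng_latent, rng_gene, rng_noise, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # latent reactant activities and the product combination
    z = np.empty((m, n))
    for i, delta in enumerate(truth.delta):
        z[i] = delta * gid + rng_latent.standard_normal(n)
    y = truth.beta0 + truth.alpha0 * gid
    for i in range(m):
        y = y + (truth.beta[i] + truth.alpha[i] * gid) * z[i]
    y = y + truth.sigma * rng_latent.standard_normal(n)

    route_names = [name for name, _ in reaction.reactant_routes]
    latents = pd.DataFrame(
        np.vstack([z, y]), index=route_names + [PRODUCT_ROW], columns=samples
    )

    # map each emitted gene to the latent(s) it loads on
    gene_latents: dict[str, list[str]] = {}
    for gene in sorted(registry.union_genes(reaction.product_processes)):
        gene_latents.setdefault(gene, []).append(PRODUCT_ROW)
    for name, pids in reaction.reactant_routes:
        for gene in sorted(registry.union_genes(pids)):
            gene_latents.setdefault(gene, []).append(name)

    genes = sorted(gene_latents)
    loadings = rng_gene.uniform(truth.loading_low, truth.loading_high, len(genes))
    baselines = rng_gene.uniform(truth.baseline_low, truth.baseline_high, len(genes))
    rows = np.empty((len(genes), n))
    for i, gene in enumerate(genes):
        signal = latents.loc[gene_latents[gene]].mean(axis=0).to_numpy()
        rows[i] = loadings[i] * signal + baselines[i] + truth.tau * rng_noise.standard_normal(n)

    bg_names = [f"BG{i:04d}" for i in range(1, truth.n_background + 1)]
    bg_base = rng_bg.uniform(truth.baseline_low, truth.baseline_high, len(bg_names))
    bg_rows = bg_base[:, None] + truth.tau * rng_bg.standard_normal((len(bg_names), n))

    values = pd.DataFrame(
        np.vstack([rows, bg_rows]) if bg_names else rows,
        index=genes + bg_names,
        columns=samples,
    )
    annotation = pd.DataFrame(
        {
            "group": ["cancer"] * n1 + ["control"] * n2,
            "cohort": cohort,
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values, annotation), latents


def simulate_study(
    truth: SimTruth,
    registry: Registry,
    reaction: ReactionSpec,
    cohorts: list[str],
) -> tuple[ExpressionMatrix, dict[str, pd.DataFrame]]:
    """Several cohorts with independent draws, seeded from one master seed."""
    child_seeds = np.random.SeedSequence(truth.seed).generate_state(len(cohorts))
    matrices, latents = [], {}
    for cohort, child in zip(cohorts, child_seeds):
        t = dataclasses.replace(truth, seed=int(child % 2**31))
        mat, lat = simulate_cohort(t, registry, reaction, cohort=cohort)
        matrices.append(mat)
        latents[cohort] = lat
    values = pd.concat([m.values for m in matrices], axis=1)
    annotation = pd.concat([m.annotation for m in matrices], axis=0)
    return ExpressionMatrix(values, annotation), latents


def simulate_de_cohort(
    n_genes: int = 1000,
    n_up: int = 10,
    log2_shift: float = 2.0,
    n_cancer: int = 30,
    n_control: int = 30,
    tau: float = 0.3,
    baseline: tuple[float, float] = (4.0, 10.0),
    seed: int = 0,
    cohort: str = "DE",
) -> tuple[ExpressionMatrix, list[str]]:
    """A flat cohort with ``n_up`` planted up-regulated genes.

    Planted genes get a ``log2_shift`` mean increase in cancer samples
    (2.0 = a four-fold linear change); all other genes are baseline plus
    Normal(0, tau^2) noise.  Returns the matrix and the planted gene ids.
    """
    if n_up > n_genes:
        raise ValidationError("n_up cannot exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_cancer + n_control
    gid = np.concatenate([np.ones(n_cancer), np.zeros(n_control)])
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    planted = genes[:n_up]
    base = rng.uniform(baseline[0], baseline[1], n_genes)
    values = base[:, None] + tau * rng.standard_normal((n_genes, n))
    values[:n_up] += log2_shift * gid
    samples = [f"{cohort}_C{i:03d}" for i in range(1, n_cancer + 1)] + [
        f"{cohort}_N{i:03d}" for i in range(1, n_control + 1)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame(
            {"group": ["cancer"] * n_cancer + ["control"] * n_control, "cohort": cohort},
            index=pd.Index(samples, name="sample"),
        ),
    )
    return matrix, planted


# -- fixture I/O --------------------------------------------------------------


def write_fixture(
    matrix: ExpressionMatrix,
    out_dir: str | Path,
    truth: SimTruth | None = None,
    latents: pd.DataFrame | dict[str, pd.DataFrame] | None = None,
    registry: Registry | None = None,
    reaction: ReactionSpec | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort as a reusable on-disk fixture.

    Always writes ``expression.tsv`` and ``annotation.tsv``; optionally
    the truth YAML, latent activities, the registry GMT and the reaction
    routes YAML.  Values round-trip through the readers exactly for ids
    and to full float precision for values.
    """
    matrix.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
    }
    write_expression(matrix, files["expression"], files["annotation"])
    if truth is not None:
        files["truth"] = out / "truth.yaml"
        files["truth"].write_text(
            yaml.safe_dump(dataclasses.asdict(truth), sort_keys=True)
        )
    if latents is not None:
        files["latents"] = out / "latents.tsv"
        if isinstance(latents, dict):
            latents = pd.concat(latents, names=["cohort", "latent"])
        latents.to_csv(files["latents"], sep="\t")
    if registry is not None:
        files["genesets"] = out / "genesets.gmt"
        write_gmt(registry, files["genesets"])
    if reaction is not None:
        files["routes"] = out / "routes.yaml"
        payload = {
            reaction.product_id: {
                "product": list(reaction.product_processes),
                "reactants": {k: list(v) for k, v in reaction.reactant_routes},
            }
        }
        files["routes"].write_text(yaml.safe_dump(payload, sort_keys=True))
    return files


def read_truth(path: str | Path) -> SimTruth:
    """Load a truth YAML written by :func:`write_fixture`."""
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("beta", "alpha", "delta", "band"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimTruth(**raw)
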