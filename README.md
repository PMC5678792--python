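# glutmet

Cross-cancer analysis of glutamine and glutamate metabolism from bulk
gene expression: pathway activity scoring, differential expression, and
a multiple-group interaction regression that asks *which reactant
metabolites contribute differently to a product pathway in cancer
versus control tissue*.

## Who this is for

Computational biologists comparing tumor/normal RNA-seq cohorts (TCGA-style:
a log2 expression matrix plus cancer/control and cohort labels per
sample) who want to move beyond per-gene calls to pathway-level
questions: is purine synthesis fed more by glutamine or by nucleoside
salvage in this cancer type? Does glutamate's contribution to serine
synthesis change in tumors?

## The model

Each metabolic process *m* (an uptake transporter family, a synthesis
route's rate-limiting enzymes) is summarized by one per-sample activity
score: the first principal component of its gene-by-sample expression
block, sign-anchored so higher expression means a higher score (a
single-gene process passes through as its centered expression row).

For a product pathway *p* with reactants r₁…r_M, the product score
**y**ₚ is regressed on the reactant scores **x**₁…**x**_M, a binary
group indicator *ID* (1 = cancer, 0 = control), and their interactions:

```
yₚ = β₀ + α₀·ID + β₁x₁ + ⋯ + β_M x_M + α₁(x₁:ID) + ⋯ + α_M(x_M:ID)
```

β_m is reactant m's slope in control tissue; the interaction
coefficient α_m is how much that slope differs in cancer. A
significantly positive α_m (two-sided t at 0.05) classifies the
reactant's contribution as *increased* in cancer, significantly
negative as *decreased*, otherwise *none*.

Around this core the package provides:

* a curated registry of 36 lettered process gene sets (glutamine and
  glutamate influx, nucleotide de novo and salvage synthesis,
  glycolysis/oxidative phosphorylation, lipid, UDP-GlcNAc, asparagine,
  proline, serine, and glutathione metabolism) with GMT I/O, plus ten
  packaged product→reactant route definitions;
* differential expression with a signed linear fold-change threshold
  (±1.5) and an empirical-Bayes moderated t (variances shrunk toward a
  moment-matched prior; reduces exactly to the pooled-variance t with
  moderation off);
* cohort-level Pearson correlations (e.g. metabolism change vs a
  user-supplied 5-year survival rate, or vs a proteasome-based ROS
  proxy) and conditional co-expression within a constant-anchor sample
  band (default anchors PPAT and CAD, the nucleotide-synthesis
  rate-limiters);
* a synthetic-data generator that plants latent per-process activities,
  group shifts, and group-specific contribution coefficients, so every
  statistical claim above is testable against known truth.

## Worked example

Score a planted synthetic cohort and fit the contribution model:

```python
import glutmet as gm

registry, reaction = gm.synthetic_reaction()          # 2 reactants, 1 product
truth = gm.SimTruth(n_cancer=30, n_control=30,
                    beta=(0.5, 0.5),    # control-tissue slopes
                    alpha=(0.8, 0.0),   # planted cancer-specific change, r1 only
                    delta=(0.5, 0.0),   # latent group shift of r1
                    seed=1, n_background=30)
mat, latents = gm.simulate_cohort(truth, registry, reaction)
fit = gm.run_product(mat, registry, reaction)["SIM"]
print(fit.table.round(3))
print(fit.classification)
```

```
           estimate     se  t_stat  p_value
term
intercept    -0.022  0.137  -0.164    0.870
ID           -0.069  0.192  -0.362    0.719
r1            0.398  0.146   2.730    0.009
r2            0.394  0.156   2.532    0.014
r1:ID         0.463  0.196   2.369    0.021
r2:ID        -0.322  0.194  -1.658    0.103
{'r1': 'increased', 'r2': 'none'}
```

Both reactants carry significant main effects (they feed the product in
both groups), but only r1 — the reactant with the planted α = 0.8 —
gets a significant positive interaction and is classified *increased*;
coefficients are on the standardized activity scale, so the estimate
0.463 is attenuated relative to the latent-scale 0.8 by the product
score's standardization. The curated registry works the same way on
real matrices:

```python
registry = gm.load_registry()
registry.lookup("A1").genes     # {'SLC1A5', 'SLC38A1', 'SLC38A2', 'SLC38A3', 'SLC38A5'}
gm.route_table("purine", registry).reactants
# {'glutamine': ('A1','A2'), 'adenosine': ('B5',), 'guanosine': ('B6',), 'inosine': ('B7',)}
```

A `glutmet` console command wraps the same operations (`simulate`, `de`,
`score`, `contrib`, `correlate`, `condcoexpr`, `report`); all outputs
are TSV/JSON with a metadata header, and cohorts with fewer than 10
samples in either group are excluded up front.

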