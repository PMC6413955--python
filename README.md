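# scfba

Single-cell constraint-based flux analysis: build a multi-scale
stoichiometric model of `N` single cells sharing a microenvironment (TME)
compartment, constrain each cell's fluxes with transcript-derived Reaction
Activity Scores (RAS), and analyze the resulting single-cell fluxomes —
growth heterogeneity, gene essentiality, metabolic cooperation, and flux
clustering.

## Method overview

1. **Template network** (`scfba.network`) — read an SBML model (metabolites,
   reactions, reversibility, GPR rules, a biomass pseudo-reaction); exchange
   reactions are detected as single-metabolite reactions. GPR strings are
   parsed into evaluable AND/OR trees (`scfba.gpr`).
2. **Expression preprocessing** (`scfba.expression`) — load a genes × cells
   TPM matrix (TSV/CSV/MTX), filter cells detecting < 5000 genes, and
   reconcile single-cell zeros against a bulk profile: genes off in bulk and
   every cell are deleted from the template (`G_off`); genes off in every
   cell but expressed in bulk are replaced by the bulk value; heterogeneous
   zeros are kept and handled by the ε flux floor.
3. **Activity scores** (`scfba.ras`) — per cell, AND nodes score the minimum
   of their children (subunits), OR nodes the sum (isoforms); scores are
   normalized per reaction across cells.
4. **Population model** (`scfba.population`) — each cell's exchange reactions
   become reversible *cooperation* reactions into shared TME pools; each TME
   species gets a *blood* exchange. The matrix is
   `(N·M + N_blood) × (N·(N+N_ext) + N_blood)`. The medium opens nutrient
   uptakes (scaled by population size) and secretion routes; secretable
   species also get per-cell direct secretion reactions so that blocking
   cooperation never blocks waste disposal.
5. **Bounds** (`scfba.bounds`) — reaction capacities from flux variability
   (no optimality) under medium-only constraints; per-cell upper bounds
   `U = ε + (F − ε)·share`; lower bound `0` (irreversible) or `−U`.
6. **Solve** (`scfba.solve`) — LP via scipy/HiGHS: population biomass or ATP
   objective, per-cell biomass spans at the optimum, single-gene deletion
   growth ratios, cooperation-knockout ratios.
7. **Analytics** (`scfba.analytics`) — per-feature min–max normalization,
   hierarchical + bootstrap k-means clustering, elbow/silhouette
   diagnostics, two-group z contrasts.
8. **Synthetic fixtures** (`scfba.synthetic`) — a toy
   glycolysis/oxphos/palmitate network with cooperation potential plus a
   simulated two-subpopulation expression matrix (lognormal noise,
   expression-dependent dropout), so the whole pipeline is testable offline.

## CLI

```sh
scfba simulate --cells 40 --subpops 2 --dropout 0.3 --seed 7 --out fixture/
scfba run --model fixture/model.xml --expr fixture/expression.tsv \
      --bulk fixture/bulk.tsv --medium fixture/medium.yaml \
      --mode scFBA --out results/
scfba deletions  --model ... --expr ... --medium ... --mode scFBA --out del.tsv
scfba coop-ratio --model ... --expr ... --medium ... --objective biomass
scfba cluster    --features results/fluxes.tsv --on flux --kmax 20 --seed 7 --out clus/
scfba eps-scan   --model ... --expr ... --medium ... --out scan.tsv
scfba inspect-model fixture/model.xml
```

Modes: `popFBA` (identical cells, medium constraints only), `bulkFBA`
(single template after bulk-off gene deletion), `scFBA` (per-cell
score-derived bounds).

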