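# hypometab

Integrative analysis of the crosstalk between hypoxia and global
metabolism in bulk tumor expression cohorts — for computational biologists
studying how the hypoxic state of breast (or other solid) tumors relates
to pathway-level metabolic deregulation, subtype structure, and outcome.

The pipeline chains five stages, each usable on its own from Python:

1. **Hypoxia scoring** — for each signature gene g and sample s, a call
   c_g(s) = +1 if x_gs exceeds the cohort median of g, else −1; the
   hypoxia score is HS(s) = Σ_g c_g(s), and HS > 0 defines the HS-high
   group. Built-in signatures: the 8-gene hypoxia-responsive panel
   (DDIT4, LDHA, MXI1, NDRG1, P4HA1, PGK1, SLC2A1, VEGFA) and the
   15-gene Buffa metagene.
2. **Pathway deregulation** — per gene set, a principal curve is fitted
   in the PCA-reduced, z-scored pathway subspace; a sample's score is
   its arc-length distance from the reference origin, min-max normalized
   to [0, 1] (the Pathifier concept).
3. **Metabolic typing** — clustering of the pathways × samples
   deregulation matrix into three types relabeled M1/M2/M3 in ascending
   order of mean deregulation, plus nearest-centroid label transfer to
   new panels.
4. **Correlation fingerprints** — Pearson screen of HS against pathway
   or metabolite features, overall and within each type, with
   discovery/validation consistency counting and per-type breadth
   ordering; Shapiro-gated t/Mann–Whitney and Kruskal–Wallis + Dunn
   group comparisons.
5. **Survival** — Kaplan–Meier, log-rank (HS-high vs HS-low), and Cox
   proportional hazards (Breslow ties, uni- and multivariate).

A synthetic cohort generator plants the full structure the analysis
assumes — a latent hypoxia level driving the signature genes, three
types with increasing deregulation and elevated hypoxia in M3, broader
hypoxia-metabolism coupling in M1 than M3, and hazard increasing with
hypoxia — so the entire pipeline is testable with ground truth and no
external data. See `docs/methods.md` for models and parameters.

## Worked example

The package ships a hand-checkable 8-gene × 10-sample fixture in which
every gene's values are a permutation of 1..10 (cohort median 5.5):

```python
>>> import hypometab as hm
>>> expr, expected = hm.generate_worked_example()
>>> hm.score_signature(expr, hm.HYPOXIA_8).table
           hs group  n_genes_found
sample_id
s01         8  high              8
s02        -8   low              8
s03         0   low              8
...
s10         0   low              8
```

Sample s01 holds every gene's maximum, so all eight calls are +1 and
HS = +8 (HS-high); s02 holds every minimum (HS = −8); each remaining
sample sits above exactly four medians, so its calls cancel to HS = 0
and it lands in the low group (the high group requires HS > 0).

On a full simulated cohort (n = 600, seed 1), running scoring →
deregulation → typing → fingerprints (`examples/03` and `04`) prints:

```
cluster-mean deregulation (ordering convention M1 <= M2 <= M3):
M1    0.264
M2    0.396
M3    0.540
adjusted Rand index vs planted types: 0.960

hypoxia score by metabolic type:
      n   mean_hs  sem_hs
M1  295    -1.024   0.330
M2  154    -0.961   0.446
M3  151     2.980   0.429
kruskal-wallis: p = 3.36e-12
```

The planted M1 < M2 < M3 deregulation ordering is recovered almost
perfectly, and the M3 type carries a markedly higher hypoxia score than
M1 and M2 — the coupling between metabolic deregulation and hypoxia the
generator plants and the analysis is built to detect. The
`examples/` directory contains one short narrative script per
capability (scoring, deregulation, typing, fingerprints, survival,
full pipeline).

## Command line

Each stage is also a subcommand of a thin CLI:

```bash
hypometab simulate --n 600 --seed 1 --out sim/
hypometab score --expr sim/expr.tsv --signature builtin:8gene --out scores.tsv
hypometab deregulate --expr sim/expr.tsv --gmt sim/pathways.gmt --out dereg.tsv
hypometab type --dereg dereg.tsv --seed 17 --out types.tsv
hypometab correlate --scores scores.tsv --features dereg.tsv --types types.tsv --out fp.tsv
hypometab survive --scores scores.tsv --clinical sim/clinical.tsv --endpoint os --out surv.tsv
hypometab run --config run.yaml        # the whole pipeline, one config
```

`hypometab run` writes every stage table, the resolved config, and a
`summary.json`; identical configs reproduce byte-identical outputs.

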