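# metabodyn

Analysis toolkit for replicated time-course metabolomics of plant batch
suspension cultures — the kind of GC-MS profiling study in which a
heterotrophic cell line (e.g. tobacco BY-2) is followed through lag,
proliferation, elongation, stationary and death phases, with a few
hundred metabolites measured in several biological replicates at each
sampling day.

The package covers the full analysis chain for such a design:

- **Preprocessing** — per-sample median normalization, natural-log
  transform (half-minimum floor for zeros), per-metabolite autoscaling,
  and KNN imputation of sporadically missing cells in metabolite
  (feature) space.
- **Ordination and contrasts** — PCA with 90% chi-square confidence
  ellipses; Ward clustering of profiles with Pearson distance 1 − *r*;
  two-group **OPLS-DA** (NIPALS PLS1 with orthogonal signal correction)
  reporting the predictive variance fraction
  R²X_pred = ‖t_p p_pᵀ‖²_F / ‖X‖²_F and per-metabolite
  **VIP** scores, VIP_j = √(J·w_j²/Σw²) so that mean VIP² = 1;
  Mann–Whitney/Welch tests with Benjamini–Hochberg adjustment.
- **Metabolite-set enrichment (MSEA)** — preranked weighted
  Kolmogorov–Smirnov running-sum statistic on OPLS-DA predictive
  loadings, permutation null from random member sets, NES and adjusted
  p-values per pathway (KEGG-style GMT input with a manual-correction
  override table).
- **Covariation mapping** — signed correlation network of mean temporal
  profiles (|r| > 0.85 edges), attraction/repulsion layout, k-means
  clustering of nodes, per-cluster median dynamics and class
  composition, plus the inside-pathway vs outside-pathway correlation
  contrast.
- **Variability fingerprints** — per-day Canberra distances
  (Σ|uᵢ−vᵢ|/(|uᵢ|+|vᵢ|)) between metabolite pairs across biological
  replicates, then hierarchical clustering of the days in that
  pair-distance space.
- **Synthetic data** — a generator producing batch-culture metabolome
  tables with known ground truth (four temporal archetypes,
  pathway-coupled covariation, log-normal replicate noise, sporadic
  missingness) and a calibrated three-flux medium-kinetics model
  (sucrose uptake, extracellular hydrolysis to hexoses, hexose-fed
  logistic biomass growth, phenomenological pH dip-and-rise).

## Worked example

Run the whole pipeline on a simulated dataset from a single seed:

```bash
metabodyn run --seed 1 --outdir out
```

or, in Python:

```python
from metabodyn import run_pipeline

report = run_pipeline({"outdir": "out", "seed": 1,
                       "simulation": {"n_metabolites": 360}})
for entry in report["contrasts"][:3]:
    a, b = entry["contrast"]
    print(a, "vs", b, f"R2X_pred={entry['r2x_pred']:.2f}",
          f"VIP>1: {entry['n_vip_strong']}")
print("archetype ARI:", report["covariation"]["archetype_ari"])
```

prints (seed 1):

```
[21, 23] vs [1, 2] R2X_pred=0.89 VIP>1: 188
[1, 2] vs [4, 7] R2X_pred=0.61 VIP>1: 148
[7] vs [14] R2X_pred=0.89 VIP>1: 138
archetype ARI: 1.0
```

The first line reads: comparing cultures at subculturing age (days
21–23) against newly transferred ones (days 1–2), 89% of the total
metabolite variance lies on the class-predictive OPLS-DA component, and
188 of 360 metabolites exceed the conventional VIP > 1 importance
threshold.  The archetype ARI of 1.0 says the correlation-network
k-means clusters recovered the four planted temporal archetypes
exactly.  `out/report.json` holds the full machine-readable report and
`out/` the per-stage TSV/GraphML/Newick artifacts.

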