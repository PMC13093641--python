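# demogscape

Two-population demographic inference and landscape genetics for
ddRAD-style SNP data, built around the phylogeographic question of a
medium-dispersal forest ungulate (Reeves's muntjac) sampled along a
north–south gradient: did the northern and southern populations diverge
under Pleistocene climate cycling, how much gene flow followed, and do
geography, landscape resistance or climate structure today's genetic
differentiation?

The package provides, as a single tested toolkit:

- **SNP filtering** — call-rate (≥ 80%), minor-allele-count (MAC ≥ 5) and
  windowed LD pruning (r² > 0.2 within 25 kb) over a VCF-backed genotype
  matrix.
- **Summary statistics** — nucleotide diversity π, Weir–Cockerham F_ST,
  joint site-frequency spectra with exact hypergeometric projection, and
  Euclidean genetic distances.
- **A structured-coalescent simulator** (numba-accelerated) for two demes
  plus an ancestral merger, with piecewise-constant sizes, epoch-switched
  asymmetric migration and infinite-sites mutation.
- **SFS composite-likelihood inference** over a 12-scenario model family
  (constant/changed sizes x six gene-flow regimes), with ECM-style
  maximization, AIC model selection, and 1-D profile parameter recovery
  accelerated by exact path reweighting of a shared genealogy ensemble.
- **Landscape analyses** — slope/land-use resistance surfaces, Dijkstra
  least-cost-path distances, haversine geographic distances,
  environmental dissimilarity, and the |r| > 0.7 climate-variable filter.
- **Mantel and partial Mantel** permutation tests.
- **A pcadapt-style selection scan** (PCA, per-SNP z-scores, robust
  Mahalanobis distances, genomic-inflation correction, BH FDR).
- **A synthetic-data generator** producing complete study bundles (VCF,
  coordinates, sampling years, rasters, climate tables) with known
  generative truth, including planted high-differentiation outlier loci.

The core model: demes north/south of diploid sizes `N_N(t)`, `N_S(t)`
split from an ancestor of size `N_anc` at `T_div`; backward in time a deme
holding `k` lineages coalesces at rate `C(k,2)/(2N)` per generation and
lineages migrate at per-generation rates `m_NS`, `m_SN`. The fitted
statistic is the folded joint SFS; the objective is the multinomial
composite likelihood `log10 L = Σ_ij O_ij log10 p̂_ij` over polymorphic
cells, ranked across scenarios by `AIC = 2k − 2 ln(10) log10 L`. The
shipped best-fit history (changed sizes, interrupted gene flow) has
`N_anc = 534,000`, divergence 66,033 y ago, southern/northern
post-divergence sizes 28,407 / 57,679 expanding to 190,000 / 81,000, and
asymmetric flow (8.19e-3 north→south vs 4.25e-3 south→north) interrupted
45,820–30,660 y ago.

## Worked example

```python
import numpy as np
from demogscape import (generate_study, apply_default_filters, wc_fst,
                        mantel, euclidean_genetic_distance, pca_scan)
from demogscape.landscape import great_circle_distance

bundle = generate_study(seed=7, n_loci=600, outliers=12)
g, report = apply_default_filters(bundle.genotypes)
print(report.to_dict())
print("F_ST(north, south) =",
      round(wc_fst(g, "north", "south").theta_hat, 4))

gen = euclidean_genetic_distance(bundle.genotypes)
geo = great_circle_distance(bundle.sites[["lon", "lat"]].to_numpy(),
                            labels=bundle.sites["site_id"].tolist())
res = mantel(gen, geo, n_perm=999, seed=1)
print(f"Mantel r = {res.r:.3f}, p = {res.p:.4f}")

scan = pca_scan(bundle.genotypes, K=1, fdr=0.01)
hits = scan.outliers(0.01)
print("scan outliers:", len(hits), "lambda =", round(scan.lambda_gif, 2))
```

prints (seed 7):

```
{'n_input_sites': 3481, 'n_removed_call_rate': 0, 'n_removed_mac': 739,
 'n_removed_ld': 1420, 'n_retained': 1322}
F_ST(north, south) = 0.0163
Mantel r = 0.151, p = 0.0010
scan outliers: 18 lambda = 1.0
```

LD pruning removes the most sites because SNPs within one 300 bp locus
share a genealogy and are near-perfectly linked; the MAC filter takes the
abundant coalescent singletons. The modest north–south F_ST reflects the
high fitted migration rates; genetic and geographic distances correlate
because the admixed individuals are intermediate both genetically and
spatially. On this bundle all 18 scan discoveries fall on planted outlier
loci.

The same stages are exposed as a CLI:

```bash
demogscape synth --seed 7 --out bundle/
demogscape filter --vcf bundle/genotypes.vcf --out pruned.vcf --report report.json
demogscape scan --vcf bundle/genotypes.vcf --k 1 --fdr 0.01 --out scan.tsv
demogscape run --config study.yaml          # synth -> filter -> stats
```

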