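# facemodkit

Gene-based multivariate association testing of **low-frequency coding
variants** (MAF < 1%) against **hierarchical 3D facial-shape modules**.

Normal-range facial morphology is highly polygenic, and variants too rare to
test individually can still be detected when aggregated within genes.
`facemodkit` implements the full analysis chain for that design:

1. **Phenotyping** (`shapemod`) — dense homologous quasi-landmarks are
   co-aligned by generalized Procrustes analysis (GPA); landmarks are
   clustered into co-varying groups by spectral bipartition of an
   RV-coefficient similarity matrix, recursively, producing a five-level
   binary hierarchy of 31 overlapping facial segments ("modules") from the
   full face down to local regions. Each module is summarized by PCA scores
   (retention by parallel analysis), adjusted for sex, age, height, weight,
   facial size and ancestry PCs by partial least-squares regression, and
   screened for outliers with robust Mahalanobis distances.
2. **Genotype preparation** (`genoprep`) — VCF ingestion, minor-allele
   orientation, the low-frequency filters (MAF < 1%, minor allele count
   ≥ 4), gene grouping (≥ 2 qualifying variants), Beta(1, 25) variant
   weights.
3. **Kernel association engine** (`kerneltest`) — for each gene × module
   pair, multivariate score statistics under the 2 × 2 grid of phenotype
   kernels (homogeneous Σ_P = **11**′ / heterogeneous Σ_P = I) and genotype
   kernels (SKAT / burden):

   S = G_w′ R Σ̂⁻¹,  Q_het×SKAT = tr(SS′),  Q_hom×SKAT = Σ_j (1′s_j)²,

   with burden kernels collapsing S across variants first. Null tails are
   mixtures Σ λ χ²₁ whose eigenvalues factor as eig(Σ_P Σ̂⁻¹) ⊗
   eig(G_w′P₀G_w), evaluated by Ruben's exact series (saddlepoint/Liu
   fallbacks). The four kernel p-values are combined by a **minP omnibus**
   calibrated under a Gaussian copula whose 4 × 4 correlation is estimated
   from null residual resamples.
4. **Single-variant follow-up** (`singlevar`) — reverse proportional-odds
   regression of genotype on all module PCs jointly (LRT, df = K), with a
   Firth-penalized fallback for separated low-frequency variants.
5. **Reporting** (`report`) — Li–Ji effective number of independent modules
   M_eff from the inter-module RV correlation, Bonferroni threshold
   α/(n_genes · M_eff), carrier-vs-non-carrier centroid-distance effect
   sizes, and exaggerated shape "morph" exports (ASCII PLY + TSV).
6. **Synthetic cohorts** (`synthgen`) — a generative model of the assumed
   data structure (nested co-varying landmark groups, covariate effects,
   rigid nuisance transforms, exome-style low-frequency genotypes with
   planted gene effects) so the entire pipeline is testable end to end
   without any controlled-access data.

## Worked example

```python
import numpy as np
from facemodkit import synthgen, shapemod, genoprep, kerneltest, report

# synthetic cohort: 500 individuals, 64 landmarks, a causal gene planted
# in leaf segment 8 of a 4-level hierarchy
cfg = synthgen.SynthConfig(
    n_individuals=500, n_landmarks=64, n_levels=4,
    n_genes=10, variants_per_gene=(5, 5), maf_range=(0.004, 0.008),
    planted_effects=[synthgen.PlantedEffect("gene0003", 8, 3.0)], seed=1,
)
data = synthgen.generate_dataset(cfg)

# phenotype the planted module, test every gene against it
leaf = data.ground_truth.template_hierarchy.get(8)
phen = shapemod.segment_phenotype(data.faces, leaf.indices, segment_id=8, rng=1)
geno, _ = genoprep.filter_variants(data.genotypes)
genes = genoprep.group_by_gene(geno, data.gene_map)
res = kerneltest.scan([phen], genes, b_resamples=300, seed=1)
print(res.sort_values("p_omnibus")[["gene", "p_omnibus"]].head(3).to_string(index=False))
```

```
    gene  p_omnibus
gene0003   0.008839
gene0002   0.064141
gene0009   0.341342
```

The planted gene `gene0003` is the top omnibus hit in its module; the
remaining genes sit at null-level p-values (a single desk-scale replicate
has moderate power — the planted displacement is calibrated so the causal
gene tops the scan in roughly 80–90% of replicates, which
`scripts/acceptance.py` measures over 50 seeds). At cohort scale
(8091 genes, 19 effective modules) the Bonferroni threshold is

```python
thr = report.significance_threshold(8091, 19, 0.05)   # 3.3e-07
```

A command-line interface mirrors the stages
(`facemodkit synth | phenotype | scan | followup | report | run`); see
`facemodkit --help`.

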