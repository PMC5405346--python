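# peagbs

Genotyping-by-sequencing (GBS) analysis for germplasm collections: genotype
calling from allele read depths, marker filtering, dual-catalog union,
missing-data-standardized private-allele accounting, probabilistic PCA,
mixed-linear-model association mapping, and allele-coverage core-collection
selection — exercisable end to end on synthetic collections with known truth.

## The problem

Genebank collections of mostly inbred crop accessions (a few hundred lines in
a handful of genetic groups) are routinely characterized with reduced-
representation sequencing. Reference-free pipelines call SNPs on short
consensus "tags", so depth is shallow (mean ≈ 4 reads per cell), nearly half
the genotypes are missing, and every downstream question — which groups hold
novel alleles, where a Mendelian trait maps, which small subset of accessions
preserves the collection's diversity — must be answered on that noisy matrix.
`peagbs` implements that analysis chain as a tested library with a thin CLI,
for breeders and curators working with biallelic SNP panels.

## Methods at the core

* **Genotype calls** from the alternate-read fraction *f* at each cell:
  *f* < 0.05 → homozygous, 0.05 ≤ *f* < 0.10 → missing, *f* ≥ 0.10 →
  heterozygous.
* **Marker filters**: MAF ≥ 0.01, call rate ≥ 0.2, heterozygosity ≤ 0.25
  (the het ceiling flags collapsed paralogs in an inbred panel); one SNP per
  tag; union of two SNP catalogs with 64 bp tags aligned inside 80 bp tags,
  the first catalog's genotypes winning at shared loci.
* **Private alleles** per group after downsampling every group to a common
  score *T* ± 0.5, where an accession scores 1 − (proportion missing),
  averaged over 100 random iterations.
* **Probabilistic PCA**: EM fit of x = Wz + ε tolerating missing genotypes.
* **Association**: y = μ + PCs·β_c + x·β + u + e with u ~ N(0, σ²_g K),
  K the VanRaden genomic relationship matrix; variance components estimated
  once by REML on the null model (P3D/EMMAX), per-SNP GLS Wald tests,
  Bonferroni control at α/m.
* **Core selection**: greedy allele set cover with backward pruning under a
  sampling-intensity sweep, targeting ≥ 95% allele coverage.

## Worked example

```python
from peagbs import (synthetic_gbs as sg, genotype_calling as gc,
                    marker_filtering as mf, core_selection as cs,
                    association_scan as asc)

cfg = sg.SimConfig(n_groups=3, accessions_per_group=40, n_loci=1000, seed=42)
truth = sg.simulate_population(cfg)
gm = gc.call_matrix(sg.simulate_read_depths(truth, cfg))
kept, report = mf.filter_markers(gm)
core = cs.intensity_sweep(kept, target_coverage=0.95)
y = sg.simulate_binary_trait(truth, penetrance=(1, 1, 0), seed=42)
scan = asc.mlm_scan(y, kept, asc.vanraden_kinship(kept))
```

prints, via the obvious reporting lines:

```
called 1000 SNPs x 120 accessions; 48% missing
retained 988/1000 SNPs (excluded: {'call_rate': 0, 'maf': 12, 'het_rate': 0})
core of 15 accessions: coverage 0.951, MAF retention 0.902
top GWAS hit TP000026 (causal locus TP000026): p = 1.13e-13, Bonferroni 5.06e-05
```

Read: shallow depth plus tag dropout leaves 48% of genotypes missing (the
intended regime); 12 simulated loci drift below the 1% MAF floor; 15 of 120
accessions suffice to retain 95.1% of observed alleles while 90% of SNPs keep
MAF ≥ 0.01 inside the core; and the fully penetrant recessive flower-color-
style locus is recovered as the top association, far beyond the Bonferroni
threshold 0.05/988.

The same stages are available as CLI subcommands
(`peagbs simulate / call / filter / union / diversity / pca / gwas / core`);
see `peagbs --help`.

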