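# famseq-assoc

Gene-based association testing for **case-control sequence data in
pedigrees**. When a sample contains relatives, population-based tests
understate the variance of case-control allele-frequency contrasts and their
p-values are invalid. This package implements four gene-region statistics,
each rescaled by a kinship-derived correction factor so that its null
distribution remains chi-square for family data:

* **T²_F = T² / P_corr** — generalized (Hotelling-type) T²: the contrast of
  case and control mean minor-allele dosage vectors, d' S⁺ d, scaled by
  n_A n_Ā / n, with S the pooled within-group covariance;
* **T_CMCF = T_CMC / P_corr** — the combined multivariate and collapsing
  (CMC) test: variants with MAF below a threshold are collapsed into a
  single carrier indicator before the T² machinery;
* **T_FPCAF = T_FPCA / P_corr** — functional PCA: each individual's dosages
  across the gene are smoothed into a function of genomic position with a
  B-spline basis, and group means of the leading functional principal
  component scores are contrasted;
* **Chi_min** — the minimum p-value over per-variant 1-df allelic chi-square
  tests (each statistic divided by P_corr), reported deliberately without
  within-gene multiplicity adjustment; it serves as an anti-conservative
  comparator.

The correction factor is the variance ratio

    P_corr = [ ΣΣ_A 2φᵢⱼ/n_A² + ΣΣ_Ā 2φᵢⱼ/n_Ā² − 2 ΣΣ_{A×Ā} 2φᵢⱼ/(n_A n_Ā) ]
             / (1/n_A + 1/n_Ā)

where φᵢⱼ is the pedigree kinship coefficient (computed exactly by
recursion, inbreeding included) over the case set A and control set Ā.
P_corr = 1 exactly when all sampled individuals are unrelated and non-inbred.

Around the statistics the package provides a genome-scan driver (VCF + BED +
PED/FAM + phenotype table → per-gene TSV), a replicate-based type-I-error /
power evaluator, and a gene-dropping simulator (template pedigrees, founder
haplotypes from a mixed common/rare frequency spectrum, Mendelian
transmission, logistic liability phenotype) so the whole pipeline runs
without access-restricted data.

## Worked example

```python
from famseq_assoc import GeneAssociation
from famseq_assoc.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(n_pedigrees=300, n_genes=3, n_causal_genes=1, seed=42)
ds = simulate_dataset(config)          # ds.causal_genes == ['GENE0002']

cases = ds.phenotype.loc[ds.phenotype.pheno == 2, "iid"].tolist()
controls = ds.phenotype.loc[ds.phenotype.pheno == 1, "iid"].tolist()

model = GeneAssociation.from_pedigree(
    ds.matrices["GENE0002"], ds.individuals, cases, controls
)
print(model.fit().summary())
```

```
Gene-based family association tests
=======================================================
individuals: 1200  (cases 323, controls 877)
variants: 17   P_corr: 1.0334
-------------------------------------------------------
method     statistic   df     p-value
T2F          34.8715   17   6.467e-03
CMCF         23.4008   13   3.711e-02
FPCAF         1.7193    2   4.233e-01
CHIMIN       16.4668    1   4.951e-05
=======================================================
```

The causal gene (three rare variants with strong carrier effects) is picked
up by T²_F at p ≈ 0.006 across its 17 polymorphic variants; CMC loses some
signal by collapsing the causal rare variants together with null rare
background (p ≈ 0.037 at 13 df); FPCA, which assumes a smooth dosage signal
along the gene, misses the concentrated rare signal; Chi_min's p-value looks
smallest but is not multiplicity-adjusted — under the null it is grossly
inflated (its empirical type I error at nominal 0.05 is ≈ 0.43 in the
calibration study below). The same fit on a non-causal gene in this dataset
gives T²_F p ≈ 0.31. P_corr ≈ 1.03 here because hypertension-like case
status clusters only mildly within these nuclear families.

The same analysis runs from the shell on standard file formats:

```bash
famseq-assoc simulate --config sim.yaml --out simdir/
famseq-assoc scan --vcf simdir/rep001.vcf --ped simdir/pedigree.fam \
    --pheno simdir/rep001_pheno.tsv --genes simdir/genes.bed --out scan.tsv
famseq-assoc evaluate --scans 'scans/rep*.tsv' --causal simdir/causal_genes.txt \
    --out eval.tsv
```

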