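# sswas — single-step weighted GWAS

`sswas` implements a complete weighted single-step genome-wide association
pipeline for partially genotyped pedigreed populations, the setting typical
of national beef-cattle evaluations (tens of thousands of animals with
carcass records, a third of them genotyped on a 50K SNP array, the rest
contributing through the pedigree). It is aimed at animal breeders and
quantitative geneticists who want an open, testable implementation of the
method usually run through the BLUPF90 family of programs.

## The model

Phenotypes follow a single-trait animal model

```
y = Xb + Za + e,      a ~ N(0, H σ²a),   e ~ N(0, I σ²e)
```

with contemporary group (herd × birth year × birth season) and sex as fixed
factors and slaughter age as a covariate. Single-step GBLUP replaces the
pedigree relationship inverse A⁻¹ by

```
H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]
```

where A22 is the pedigree relationship block of the genotyped animals and
G = ZDZ′ / Σᵢ 2pᵢ(1−pᵢ) is the (weighted) genomic relationship matrix built
from allele-frequency-centred gene content Z. Variance components come from
average-information REML; heritability is h² = σ²a/(σ²a+σ²e).

The weighted iteration back-solves SNP effects from the genotyped animals'
GEBVs, û = λ D Z′G⁻¹ â_g, re-weights each SNP by dᵢ = ûᵢ²·2pᵢ(1−pᵢ),
rescales the weights so tr(D) stays constant (keeping the implied total
genetic variance fixed), rebuilds G and repeats — three iterations by
convention. Finally the additive variance is decomposed into non-overlapping
windows of consecutive SNPs spanning ≤ 1 Mb: a window's share is
Var(Σⱼ Zⱼûⱼ)/σ²a × 100, and windows above 1% of the genetic variance
(≈ 19.6× the average share when a 50K map yields 1956 windows) are declared
significant and annotated against user-supplied BED intervals.

Because real carcass data sets of this kind are not publicly deposited, the
package ships a first-class synthetic-data generator (pedigree simulation,
gene dropping, planted QTL plus a genome-wide marker polygene, herd-year-
season effects, female-biased genotyping) so every stage is testable
end-to-end.

## Worked example

`python examples/wssgwas_windows.py` simulates 1,200 animals (≈ 860
genotyped at 800 SNPs) with one planted QTL carrying 10% of the additive
variance, runs the full pipeline and prints:

```
planted QTL: chr2:107061565 effect +0.256 (10% of additive variance)
AIREML h2 = 0.277; 3 re-weighting iterations, tr(D) = 800.0 (conserved)
325 windows; expected average share 0.3077%; 1% rule is 3.2x that average

windows above 1% of the additive genetic variance:
 chrom  start_bp    end_bp  n_snp  gvar_pct annotations
     2 106946378 107946378      3  9.885344 PLANTED_QTL
     1  92126971  93126971      4  6.570082
     ...
QTL window recovered: True
```

The `gvar_pct` column is the percentage of total additive genetic variance
explained by each 1-Mb window; the planted QTL's window tops the table and
is recovered by the BED annotation. `examples/simulate_and_fit.py` shows
variance-component estimation (AIREML ĥ² = 0.297 against a simulated truth
of 0.30) and the GEBV-accuracy gain of H over A; `examples/qc_cascade.py`
shows the sequential genotype QC report.

The same stages are scriptable from the shell:

```
sswas simulate --config sim.yaml --out simdir/
sswas qc --genotypes simdir/genotypes.tsv --map simdir/map.tsv --autosomes 1-29 --out qcdir/
sswas run --config run.yaml        # qc -> fit -> gwas -> windows -> plot
```

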