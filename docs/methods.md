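# Methods

## Model and procedure

`sswas` fits the single-trait animal model y = Xb + Za + e with
a ~ N(0, H σ²a) and e ~ N(0, I σ²e). X carries an explicit intercept,
drop-first dummy columns for each fixed factor (contemporary group, sex)
and centred covariates (slaughter age); the identifiability constraint is
arbitrary and leaves breeding values invariant. Z is the 0/1 incidence of
records onto pedigree positions, so animals without records (and ancestors)
contribute through the relationship structure only.

The combined relationship inverse is
H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹], kept as the sparse A⁻¹ plus a dense
correction block on the genotyped animals.

* **A⁻¹** comes from Henderson's rules with inbreeding coefficients by the
  Meuwissen–Luo recursion; each animal contributes at most 9 nonzeros.
  Unknown parents get Mendelian-sampling variance 1 (no unknown-parent
  groups).
* **A22** is the genotyped block of the tabular relationship matrix
  (dense recursion; adequate at the pedigree sizes this package targets,
  up to a few tens of thousands of animals).
* **G** = ZDZ′ · λ with λ = 1/Σ 2pᵢ(1−pᵢ). Z is gene content centred by
  2pᵢ, where pᵢ is the observed post-QC frequency of the *counted* allele —
  not the folded minor-allele frequency, which would corrupt the centring
  whenever p > 0.5. A configuration switch (`p=` argument of `build_G`)
  allows external frequencies. With frequencies estimated from the
  genotyped set itself, raw G is exactly singular (its rows sum to zero),
  so G is blended with A22 before inversion: G* = (1−β)G + βA22 with
  β = 0.05 by default, positive-definiteness verified by Cholesky.
  Frequencies and λ are fixed once at their initial values and never
  re-estimated across iterations, so every iteration shares one scale.

### Variance components

AIREML estimates (σ²a, σ²e). The implementation eigendecomposes the
genetic covariance kernel K = Z H Z′ once per data set; after rotating y
and X into the eigenbasis, V = σ²a Λ + σ²e I is diagonal and each AI round
(gradients, average-information matrix, traces of PVᵢ) is O(n p²). This is
algebraically identical to MME-based AIREML for the two-component model
and avoids a fresh Cholesky of V per round. Convergence is declared at a
relative parameter change below 1e-8 (200-round cap, error with the
trajectory tail on failure). If an AI step proposes a non-positive
component, the update falls back to the positive fixed point
θ ← θ · (y′PVᵢPy)/tr(PVᵢ), whose fixed points coincide with the REML score
zeros; components are floored at 1e-10 · var(y), and a boundary estimate
(σ²a ≈ 0) is flagged rather than hidden. Standard errors come from the
inverse AI matrix, se(h²) by the delta method. Variance components are
estimated once under the unweighted (D = I) matrix and held fixed over
the re-weighting iterations, matching common practice; nothing in the
weighting loop re-opens them.

### Solving the mixed model equations

Henderson's equations with coefficient matrix
[X′X, X′Z; Z′X, Z′Z + (σ²e/σ²a) H⁻¹] are solved matrix-free by conjugate
gradients with a Jacobi preconditioner, converged at relative residual
< 1e-10 (cap 5000 iterations; non-convergence is flagged and partial
solutions returned). σ²a = 0 is handled analytically (GLS for b, â = 0).

### Weighted iteration

Per iteration t: build G(t) from D(t) (D(1) = I), blend, assemble H⁻¹,
solve for GEBVs, back-solve û = λ D(t) Z′ G*⁻¹ â_g using the genotyped
animals' GEBVs only, set dᵢ = ûᵢ²·2pᵢ(1−pᵢ), floor at 1e-8 × mean(d) (an
exactly-zero effect would otherwise remove a SNP permanently), and rescale
so tr(D) equals its iteration-1 value (= M), conserving the implied total
genetic variance to 1e-10. Three iterations by default. The back-solve uses
the blended G* actually inverted in H⁻¹; with β = 0 and matching
frequencies the identity λZDZ′G⁻¹â_g = â_g holds exactly.

### Windows

The SNP map is partitioned into non-overlapping windows of consecutive
SNPs: greedily anchored at each chromosome's first unassigned SNP with
membership pos ∈ [anchor, anchor + 1 Mb) (half-open; fixed genomic bins are
available as `mode="bins"`). A window's share is the unbiased empirical
variance across genotyped individuals of its summed SNP term, divided by
the AIREML σ²a from the unweighted fit, × 100. Raw gene content is used
since per-SNP centring constants do not change the variance. Windows above
the threshold (default 1%) are reported ranked by share, with the expected
average share 100/n_windows and the threshold's fold over it stated
alongside. Annotation attaches any user-supplied BED interval overlapping
the half-open window extent; no online database access. Final-iteration
effects feed the decomposition (a switch selects earlier iterations).

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:

* **Pedigree** — founder cohort (half of each sex), then discrete
  generations; each generation mates n_founders/2 dams (without
  replacement, from the previous generation's females) to sires drawn with
  replacement, leaving `offspring_per_mating` offspring of alternating sex.
* **Genotypes** — gene dropping: founder haplotypes Bernoulli(p) with
  p ~ U(0.05, 0.5), offspring inheriting one allele per parent with 1/2
  probabilities per SNP. Positions are uniform over the chromosomes. The
  29-autosome default uses cattle-proportioned lengths scaled to ~2,100 Mb
  total — the SNP-covered extent of a 50K array rather than the physical
  genome, chosen so a 45k-SNP map partitions into a realistic number
  (≈ 2,000) of 1-Mb windows.
* **Phenotypes** — true breeding value = planted QTL effects (each sized to
  a stated fraction of σ²a, placed at common variants, MAF ≥ 0.2 by
  default) + a genome-wide marker polygene (small normal effects on all
  non-QTL SNPs carrying 80% of the remaining additive variance) + an
  infinitesimal pedigree-recursion remainder (20%). The split reflects
  that a dense array tags most, but not all, of the additive variation;
  the infinitesimal part keeps non-genotyped relatives informative through
  the pedigree, which is the point of the single-step machinery. A purely
  pedigree-wise polygene would be untrackable by markers and depresses
  genomic ĥ² well below truth — that regime is a model-misspecification
  study, not the intended emulation. Phenotypes add contemporary-group
  effects (N(0,1) per level), a sex effect, a log-normal slaughter-age
  covariate (mean 63.9, SD 32 months — the long right tail of a cow-heavy
  reference population) and Gaussian residuals; the phenotypic variance is
  1, so σ²a = h² directly. All non-founders are phenotyped; a female-biased
  subset (70% female by default, 30% of phenotyped animals) is "genotyped".
  Everything is a pure function of the seed.

What the generator does **not** emulate: linkage disequilibrium (founder
SNPs are independent; descendants share haplotypes only through
co-inheritance), selection, genotyping error, multi-trait covariance and
unknown-parent structure. Consequently passing tests demonstrate the
estimator and bookkeeping are correct under the assumed model, not that
window shares transfer quantitatively to LD-rich real data — with LD,
neighbouring windows share signal and the per-window sum rule holds only
approximately.

## Numerical choices and problem sizes

* PCG tolerance 1e-10, AIREML tolerance 1e-8; the trace of D is conserved
  to 1e-10 relative; ties in window ranking break by (chromosome, start).
* QC filters run sequentially in the order call rate → MAF → HWE →
  autosome, so per-filter counts are order-dependent; the report records
  the order, and reruns are bit-identical. HWE uses the 1-df chi-square on
  expected genotype counts (the classical array-QC test), not the exact
  test. Monomorphic SNPs fall to the MAF filter. Missing dosages are
  imputed with 2pᵢ after filtering, preserving column means exactly.
* Replicated checks use desk-scale designs chosen to keep the whole suite
  in minutes: variance-component recovery at 3,000 phenotyped / 1,000
  genotyped / 1,000 SNPs over 20 seeds; QTL detection at 3,000 phenotyped /
  2,000 genotyped / 2,000 SNPs over 10 seeds; the acceptance script uses
  8 and 6 replicates of the same designs. The dense-oracle equivalences
  run on pedigrees of ≤ 500 animals where full matrices are exact and
  cheap.

## Known limitations

* Squared-effect re-weighting inflates the largest window shares even in
  null simulations (measured: the null maximum grows several-fold from
  iteration 1 to 3 at desk scales). The trace constraint bounds, but does
  not remove, this concentration — the reason the iteration count stays at
  2–3 in practice and why the unweighted iteration's calibration is the
  safer null reference. Significant-window lists from iteration 3 should
  be read as candidate regions, not calibrated hypothesis tests.
* Detection of a planted QTL by the 1% rule assumes a common causal
  variant; without LD, a rare large-effect variant is shrunk toward zero
  (its prior per-SNP variance is frequency-independent while its data
  information scales with 2pq) and has no tagging neighbours to rescue it.
* A22 and H materialization are dense; beyond ~3×10⁴ pedigree animals a
  sparse/indirect treatment (not implemented) would be needed.
* No unknown-parent groups, metafounders or APY approximation; single
  trait only.
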