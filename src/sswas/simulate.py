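"""Synthetic pedigrees, genotypes and phenotypes for a partially genotyped
beef-cattle population.

The generator emulates the study design the pipeline targets: a founder
cohort followed by discrete generations of random mating, gene dropping of
array-scale SNPs from founder allele frequencies, and phenotypes built from
a handful of planted QTL plus an infinitesimal (pedigree-correlated)
polygenic background, contemporary-group and sex fixed effects, and a
right-skewed slaughter-age covariate.  Only a female-biased subset of the
phenotyped animals is genotyped, so the single-step machinery genuinely has
to merge genotyped and non-genotyped relatives.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import UNKNOWN, GenotypePanel, Pedigree

# Autosome lengths (Mb) proportioned like the cattle (ARS-UCD) karyotype but
# scaled to ~2,100 Mb total: the SNP-covered extent of a 50K array rather
# than the full physical genome (arrays leave chromosome ends and
# centromeric stretches empty).
_CATTLE_AUTOSOME_MB = np.array(
    [158.5, 136.2, 121.0, 120.8, 120.1, 117.8, 110.7, 113.4, 105.7, 103.3,
     106.9, 87.2, 83.5, 82.4, 85.0, 81.0, 75.2, 66.0, 64.1, 72.0, 71.6,
     61.4, 52.5, 62.7, 42.4, 51.7, 45.6, 45.9, 51.1]
)


def cattle_autosome_lengths_bp(n_chromosomes: int = 29) -> np.ndarray:
    """Effective chip-covered autosome lengths in bp (first n chromosomes)."""
    mb = _CATTLE_AUTOSOME_MB[:n_chromosomes]
    scale = 2100.0 / _CATTLE_AUTOSOME_MB.sum()
    return np.round(mb * scale * 1e6).astype(np.int64)


@dataclass
class SimConfig:
    """Study-condition knobs; defaults are the scaled-down test regime
    (600 animals, 1000 SNPs over 5 chromosomes)."""

    n_founders: int = 150
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snps: int = 1000
    n_chromosomes: int = 5
    chromosome_length_bp: int | None = None  # None: chip-covered cattle lengths
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2_true: float = 0.30
    n_qtl: int = 2
    qtl_var_fracs: tuple[float, ...] = (0.10, 0.05)
    marker_polygenic_frac: float = 0.80
    qtl_min_maf: float = 0.20  # plant QTL at common variants only
    prop_genotyped: float = 0.30
    female_genotyping_bias: float = 0.70
    cg_levels: int = 20
    cg_sd: float = 1.0
    sex_effect: float = 0.5
    age_effect: float = 0.02  # per month
    age_mean_months: float = 63.9
    age_sd_months: float = 32.0
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.qtl_var_fracs) != self.n_qtl:
            raise ValueError("qtl_var_fracs length must equal n_qtl")
        if sum(self.qtl_var_fracs) > 1.0:
            raise ValueError("QTL variance fractions sum above 1")


@dataclass
class TruthTable:
    true_breeding_values: np.ndarray  # per pedigree animal
    qtl_positions: list[tuple[int, int, float]]  # (chrom, bp, effect)
    true_h2: float
    true_vc: tuple[float, float]
    sex: np.ndarray = field(default_factory=lambda: np.array([]))  # "M"/"F"


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, np.ndarray]:
    """Discrete-generation random-mating pedigree; returns (ped, sex).

    Each generation mates n_founders//2 dams (sampled without replacement
    from the previous generation's females) with sires drawn with
    replacement from its males; each mating leaves offspring_per_mating
    offspring of alternating sex.  Founders are unrelated, half of each sex.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    n_matings = cfg.n_founders // 2
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    for i in range(cfg.n_founders):
        ids.append(f"F{i:05d}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        sex.append("M" if i % 2 == 0 else "F")
    prev = np.arange(cfg.n_founders)
    for g in range(1, cfg.n_generations + 1):
        males = prev[np.array([sex[i] == "M" for i in prev])]
        females = prev[np.array([sex[i] == "F" for i in prev])]
        if males.size == 0 or females.size < n_matings:
            raise ValueError(
                f"generation {g}: not enough parents "
                f"({males.size} males, {females.size} females for {n_matings} matings)"
            )
        dams = rng.choice(females, size=n_matings, replace=False)
        sires = rng.choice(males, size=n_matings, replace=True)
        new: list[int] = []
        for m in range(n_matings):
            for o in range(cfg.offspring_per_mating):
                idx = len(ids)
                ids.append(f"G{g}{idx:06d}")
                sire.append(int(sires[m]))
                dam.append(int(dams[m]))
                sex.append("M" if (m * cfg.offspring_per_mating + o) % 2 == 0 else "F")
                new.append(idx)
        prev = np.array(new)
    ped = Pedigree(ids, np.array(sire), np.array(dam))
    return ped, np.array(sex)


def drop_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypePanel:
    """Gene-drop SNP genotypes for every pedigree animal.

    Founder allele frequencies are uniform on [maf_low, maf_high]; founder
    haplotypes are Bernoulli(p); offspring receive one allele from each
    parent with independent 1/2 probabilities per SNP.  Positions are
    uniform over the chromosomes and sorted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    M, n = cfg.n_snps, ped.n
    if cfg.chromosome_length_bp is not None:
        lengths = np.full(cfg.n_chromosomes, cfg.chromosome_length_bp, dtype=np.int64)
    else:
        lengths = cattle_autosome_lengths_bp(cfg.n_chromosomes)
    chrom = rng.integers(0, cfg.n_chromosomes, size=M)
    pos = rng.integers(1, lengths[chrom] + 1)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order] + 1, pos[order]

    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=M)
    h1 = np.zeros((n, M), dtype=np.int8)
    h2 = np.zeros((n, M), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            h1[i] = rng.random(M) < p
            h2[i] = rng.random(M) < p
        else:
            pick_s = rng.integers(0, 2, size=M, dtype=np.int8)
            pick_d = rng.integers(0, 2, size=M, dtype=np.int8)
            h1[i] = np.where(pick_s == 0, h1[s], h2[s])
            h2[i] = np.where(pick_d == 0, h1[d], h2[d])
    dosage = (h1 + h2).astype(np.float64)
    snp_ids = [f"snp{j:06d}" for j in range(M)]
    return GenotypePanel(list(ped.ids), snp_ids, dosage, chrom, pos)


def simulate_phenotypes(
    ped: Pedigree,
    panel: GenotypePanel,
    cfg: SimConfig,
    sex: np.ndarray,
) -> tuple[pd.DataFrame, TruthTable]:
    """Phenotypes for all non-founder animals, with the genetic truth.

    True breeding value = planted QTL effects on centered dosages, plus a
    genome-wide marker polygene (small normal effects on every non-QTL SNP,
    carrying marker_polygenic_frac of the non-QTL additive variance -- a
    dense array tags most but not all of the additive variation), plus an
    infinitesimal remainder following the pedigree recursion
    a_i = (a_s + a_d)/2 + Mendelian sampling.  The phenotypic variance is 1
    by construction: sigma2_a = h2_true, sigma2_e = 1 - h2_true.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))
    n = ped.n
    sigma2_a = cfg.h2_true
    sigma2_e = 1.0 - cfg.h2_true

    # planted QTL among common simulated SNPs (a locus carrying >=5% of the
    # genetic variance is, at realistic effect sizes, a common variant)
    p = panel.freqs
    common = np.flatnonzero(np.minimum(p, 1 - p) >= cfg.qtl_min_maf)
    if cfg.n_qtl and common.size < cfg.n_qtl:
        raise ValueError("not enough common SNPs to place QTL")
    qtl_idx = (
        rng.choice(common, size=cfg.n_qtl, replace=False)
        if cfg.n_qtl
        else np.array([], dtype=int)
    )
    g_qtl = np.zeros(n)
    qtl_records = []
    for k, j in enumerate(qtl_idx):
        het = 2.0 * p[j] * (1.0 - p[j])
        if het <= 0:
            continue
        beta = np.sqrt(cfg.qtl_var_fracs[k] * sigma2_a / het)
        beta *= rng.choice([-1.0, 1.0])
        g_qtl += (panel.gene_content[:, j] - 2.0 * p[j]) * beta
        qtl_records.append((int(panel.chrom[j]), int(panel.pos[j]), float(beta)))

    # genome-wide marker polygene on the non-QTL SNPs
    s2_poly = sigma2_a * (1.0 - sum(cfg.qtl_var_fracs))
    s2_marker = s2_poly * cfg.marker_polygenic_frac
    g_marker = np.zeros(n)
    bg_idx = np.setdiff1d(np.arange(panel.n_snps), qtl_idx)
    if s2_marker > 0 and bg_idx.size:
        het_sum = float(np.sum(2.0 * p[bg_idx] * (1.0 - p[bg_idx])))
        betas = rng.standard_normal(bg_idx.size) * np.sqrt(s2_marker / het_sum)
        g_marker = (
            panel.gene_content[:, bg_idx] - 2.0 * p[bg_idx][None, :]
        ) @ betas

    # infinitesimal remainder down the pedigree
    s2_poly = s2_poly - s2_marker
    poly = np.zeros(n)
    ms = rng.standard_normal(n)
    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        if si == UNKNOWN and di == UNKNOWN:
            poly[i] = ms[i] * np.sqrt(s2_poly)
        elif si == UNKNOWN or di == UNKNOWN:
            k = si if si != UNKNOWN else di
            poly[i] = 0.5 * poly[k] + ms[i] * np.sqrt(0.75 * s2_poly)
        else:
            poly[i] = 0.5 * (poly[si] + poly[di]) + ms[i] * np.sqrt(0.5 * s2_poly)
    a = g_qtl + g_marker + poly

    pheno_mask = (ped.sire != UNKNOWN) | (ped.dam != UNKNOWN)
    idx = np.flatnonzero(pheno_mask)
    cg = rng.integers(0, cfg.cg_levels, size=idx.size)
    cg_eff = rng.standard_normal(cfg.cg_levels) * cfg.cg_sd
    # lognormal slaughter age matched to the target mean/SD
    s2 = np.log1p((cfg.age_sd_months / cfg.age_mean_months) ** 2)
    age = rng.lognormal(np.log(cfg.age_mean_months) - s2 / 2, np.sqrt(s2), idx.size)
    sex_i = sex[idx]
    e = rng.standard_normal(idx.size) * np.sqrt(sigma2_e)
    y = (
        cfg.mu
        + cg_eff[cg]
        + np.where(sex_i == "F", cfg.sex_effect, 0.0)
        + cfg.age_effect * (age - age.mean())
        + a[idx]
        + e
    )
    phenos = pd.DataFrame(
        {
            "animal_id": [ped.ids[i] for i in idx],
            "trait": y,
            "contemporary_group": [f"cg{c:03d}" for c in cg],
            "sex": sex_i,
            "slaughter_age": age,
        }
    )
    truth = TruthTable(a, qtl_records, cfg.h2_true, (sigma2_a, sigma2_e), sex)
    return phenos, truth


def select_genotyped(
    phenos: pd.DataFrame, cfg: SimConfig
) -> list[str]:
    """Female-biased sample of phenotyped animals to be genotyped."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
    n_g = int(round(cfg.prop_genotyped * len(phenos)))
    females = phenos.loc[phenos["sex"] == "F", "animal_id"].to_numpy()
    males = phenos.loc[phenos["sex"] == "M", "animal_id"].to_numpy()
    n_f = min(int(round(cfg.female_genotyping_bias * n_g)), females.size)
    n_m = min(n_g - n_f, males.size)
    chosen = np.concatenate(
        [rng.choice(females, n_f, replace=False), rng.choice(males, n_m, replace=False)]
    )
    order = {a: i for i, a in enumerate(phenos["animal_id"])}
    return sorted(chosen, key=order.__getitem__)


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: Pedigree
    panel_all: GenotypePanel  # dosages for every pedigree animal (truth)
    panel: GenotypePanel  # genotyped subset, as observed by the pipeline
    phenotypes: pd.DataFrame
    truth: TruthTable


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """End-to-end generation: pedigree, gene drop, phenotypes, genotyped
    subset."""
    ped, sex = simulate_pedigree(cfg)
    panel_all = drop_genotypes(ped, cfg)
    phenos, truth = simulate_phenotypes(ped, panel_all, cfg, sex)
    genotyped = select_genotyped(phenos, cfg)
    keep = np.array([ped.index[a] for a in genotyped])
    panel = panel_all.subset_animals(keep)
    return SimulatedDataset(cfg, ped, panel_all, panel, phenos, truth)
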