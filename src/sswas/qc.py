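"""Genotype quality control: call-rate, MAF, Hardy-Weinberg and autosome
filters applied sequentially, plus mean-dosage imputation of the survivors.

The filters mirror standard SNP-array practice (PLINK-style): animals with
call rate < 0.90 first, then SNPs by call rate < 0.90, minor allele
frequency < 0.01, Hardy-Weinberg disequilibrium at p < 1e-7 (1-df chi-square
on expected genotype counts), and finally non-autosomal loci.  Counts per
filter are order-dependent, so the report records the order applied and
re-running with the same order is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    animals_removed_callrate: int = 0
    snps_removed_callrate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    snps_removed_nonautosomal: int = 0
    retained_animals: int = 0
    retained_snps: int = 0
    filter_order: list[str] = field(
        default_factory=lambda: ["callrate", "maf", "hwe", "autosome"]
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("animals_removed_callrate", self.animals_removed_callrate),
            ("snps_removed_callrate", self.snps_removed_callrate),
            ("snps_removed_maf", self.snps_removed_maf),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_removed_nonautosomal", self.snps_removed_nonautosomal),
            ("retained_animals", self.retained_animals),
            ("retained_snps", self.retained_snps),
            ("filter_order", "->".join(self.filter_order)),
        ]
        return pd.DataFrame(rows, columns=["item", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_animals_callrate(
    panel: GenotypePanel, min_rate: float = 0.90
) -> tuple[GenotypePanel, int]:
    """Drop animals whose fraction of non-missing calls is below min_rate."""
    if panel.n_animals == 0 or panel.n_snps == 0:
        raise QCError("empty panel")
    called = np.mean(~np.isnan(panel.gene_content), axis=1)
    keep = np.flatnonzero(called >= min_rate)
    removed = panel.n_animals - keep.size
    if keep.size == 0:
        raise QCError(f"all {panel.n_animals} animals below call rate {min_rate}")
    if removed:
        logger.info("call-rate filter removed %d animals", removed)
    return panel.subset_animals(keep), removed


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    """Hardy-Weinberg 1-df chi-square p-value per SNP.

    Observed genotype counts (n0, n1, n2) are compared with the expected
    counts n*(q^2, 2pq, p^2) at the observed allele frequency p.  SNPs that
    are monomorphic among observed calls get p-value 1 (no test possible;
    the MAF filter removes them anyway).
    """
    g = panel.gene_content
    n0 = np.sum(g == 0, axis=0).astype(float)
    n1 = np.sum(g == 1, axis=0).astype(float)
    n2 = np.sum(g == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        x2 = np.zeros(g.shape[1])
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            x2 += term
    pvals = stats.chi2.sf(x2, df=1)
    mono = (n == 0) | (p <= 0) | (p >= 1)
    pvals[mono] = 1.0
    return pvals


def filter_snps(
    panel: GenotypePanel,
    min_callrate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-7,
    autosomes: set[int] | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Apply SNP filters sequentially: call rate, MAF, HWE, autosome.

    Each filter sees only the SNPs surviving the previous one, so the
    per-filter counts depend on (and are reported with) the order.
    """
    report = QCReport()
    # call rate
    called = np.mean(~np.isnan(panel.gene_content), axis=0)
    keep = np.flatnonzero(called >= min_callrate)
    report.snps_removed_callrate = panel.n_snps - keep.size
    panel = panel.subset_snps(keep)
    # MAF (monomorphic SNPs have maf 0 and are removed here)
    p = panel.freqs
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(maf >= min_maf)
    report.snps_removed_maf = panel.n_snps - keep.size
    panel = panel.subset_snps(keep)
    # HWE
    pvals = hwe_pvalues(panel)
    keep = np.flatnonzero(pvals >= hwe_alpha)
    report.snps_removed_hwe = panel.n_snps - keep.size
    panel = panel.subset_snps(keep)
    # autosomes
    if autosomes is not None:
        keep = np.flatnonzero(np.isin(panel.chrom, sorted(autosomes)))
        report.snps_removed_nonautosomal = panel.n_snps - keep.size
        panel = panel.subset_snps(keep)
    if panel.n_snps == 0:
        raise QCError("no SNPs survive quality control")
    report.retained_animals = panel.n_animals
    report.retained_snps = panel.n_snps
    logger.info(
        "SNP QC: removed %d (callrate) %d (maf) %d (hwe) %d (non-autosomal); "
        "%d retained",
        report.snps_removed_callrate, report.snps_removed_maf,
        report.snps_removed_hwe, report.snps_removed_nonautosomal,
        report.retained_snps,
    )
    return panel, report


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the column mean 2*p_i.

    Column means (hence allele frequencies) are preserved exactly; run after
    filtering so every column has at least one observed call.
    """
    g = panel.gene_content
    if not np.any(np.isnan(g)):
        return panel
    fill = 2.0 * panel.freqs
    g = np.where(np.isnan(g), fill[None, :], g)
    return GenotypePanel(
        list(panel.animal_ids), list(panel.snp_ids), g,
        panel.chrom.copy(), panel.pos.copy(),
    )


def run_qc(
    panel: GenotypePanel,
    min_animal_callrate: float = 0.90,
    min_snp_callrate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-7,
    autosomes: set[int] | None = None,
    impute: bool = True,
) -> tuple[GenotypePanel, QCReport]:
    """Full cascade: animal call rate, SNP filters, optional imputation."""
    panel, n_animals_removed = filter_animals_callrate(panel, min_animal_callrate)
    panel, report = filter_snps(panel, min_snp_callrate, min_maf, hwe_alpha, autosomes)
    report.animals_removed_callrate = n_animals_removed
    if impute:
        panel = impute_missing(panel)
    return panel, report
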