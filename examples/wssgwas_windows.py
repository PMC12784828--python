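"""Iteratively re-weighted association study with window decomposition.

Plants one QTL carrying 10% of the additive genetic variance, runs three
re-weighting iterations, decomposes the variance into 1-Mb windows and
reports the windows exceeding the 1%-of-genetic-variance rule, annotated
against a toy gene interval file.
"""

import tempfile
from pathlib import Path

import numpy as np

from sswas import (
    ModelSpec,
    SimConfig,
    annotate,
    define_windows,
    manhattan_plot,
    read_bed,
    run_wssgwas,
    significant_windows,
    simulate_dataset,
    window_variance,
)

cfg = SimConfig(n_founders=300, n_generations=3, offspring_per_mating=3,
                n_snps=800, prop_genotyped=0.8,
                n_qtl=1, qtl_var_fracs=(0.10,), seed=4)
ds = simulate_dataset(cfg)
qtl_chrom, qtl_bp, qtl_beta = ds.truth.qtl_positions[0]
print(f"planted QTL: chr{qtl_chrom}:{qtl_bp} effect {qtl_beta:+.3f} "
      f"(10% of additive variance)")

states, vc = run_wssgwas(ds.pedigree, ds.panel, ds.phenotypes,
                         ModelSpec("trait"), n_iter=3)
print(f"AIREML h2 = {vc.h2:.3f}; 3 re-weighting iterations, "
      f"tr(D) = {states[-1].weights.d.sum():.1f} (conserved)")

wins = define_windows(ds.panel.chrom, ds.panel.pos, size_bp=1_000_000)
table = window_variance(wins, ds.panel, states[-1].u_hat, vc.sigma2_a)
sig = significant_windows(table, threshold_pct=1.0)
print(f"{table.n_windows} windows; expected average share "
      f"{table.expected_avg_pct:.4f}%; 1% rule is "
      f"{sig.threshold_fold:.1f}x that average")

with tempfile.TemporaryDirectory() as tmp:
    bed = Path(tmp) / "genes.bed"
    bed.write_text(
        f"{qtl_chrom}\t{max(0, qtl_bp - 50_000)}\t{qtl_bp + 50_000}\tPLANTED_QTL\n"
    )
    sig = annotate(sig, read_bed(bed))
    manhattan_plot(table, 1.0, Path(tmp) / "manhattan.png", title="simulated trait")

print("\nwindows above 1% of the additive genetic variance:")
cols = ["chrom", "start_bp", "end_bp", "n_snp", "gvar_pct", "annotations"]
print(sig.table[cols].to_string(index=False))
hit = ((sig.table.chrom == qtl_chrom) & (sig.table.start_bp <= qtl_bp)
       & (qtl_bp < sig.table.end_bp)).any()
print(f"\nQTL window recovered: {bool(hit)} "
      "(a gvar_pct of e.g. 5 means that window's summed SNP effects explain "
      "5% of the additive genetic variance)")
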