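"""Simulate a partially genotyped population and fit the single-step model.

Builds a 3-generation pedigree with 600 animals (450 phenotyped, ~30%
genotyped with a female bias), estimates variance components by AIREML
under the combined pedigree-genomic H matrix, and compares GEBV accuracy
with a pedigree-only fit.
"""

import numpy as np

from sswas import (
    ModelSpec,
    SimConfig,
    blend_G,
    build_A22,
    build_A_inverse,
    build_G,
    build_H_inverse,
    build_design,
    estimate_aireml,
    simulate_dataset,
    solve_mme,
)

ds = simulate_dataset(SimConfig(seed=1))
ped, panel = ds.pedigree, ds.panel
print(f"pedigree: {ped.n} animals ({ped.founder_count} founders); "
      f"{len(ds.phenotypes)} phenotyped, {panel.n_animals} genotyped at "
      f"{panel.n_snps} SNPs")

y, X, Z = build_design(ds.phenotypes, ModelSpec("trait"), ped)
idx = np.array([ped.index[a] for a in panel.animal_ids])
A22 = build_A22(ped, panel.animal_ids)
G_star = blend_G(build_G(panel), A22, beta=0.05)
A_inv = build_A_inverse(ped)
H_inv = build_H_inverse(A_inv, G_star, A22, idx)

vc = estimate_aireml(y, X, Z, H_inv)
print(f"AIREML: sigma2_a={vc.sigma2_a:.3f} sigma2_e={vc.sigma2_e:.3f} "
      f"h2={vc.h2:.3f} (se {vc.se_h2:.3f}); simulated truth h2=0.30")

sol_h = solve_mme(y, X, Z, H_inv, vc, genotyped_index=idx)
sol_a = solve_mme(y, X, Z,
                  build_H_inverse(A_inv, None, None, np.array([], dtype=int)),
                  vc, genotyped_index=idx)
a_true = ds.truth.true_breeding_values[idx]
acc_h = np.corrcoef(sol_h.a_hat_g, a_true)[0, 1]
acc_a = np.corrcoef(sol_a.a_hat_g, a_true)[0, 1]
print(f"GEBV accuracy among genotyped animals: single-step {acc_h:.3f} vs "
      f"pedigree-only {acc_a:.3f}")
print("the gain is the genomic information sharpening within-family ranking")
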