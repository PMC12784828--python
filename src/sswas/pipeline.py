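"""End-to-end orchestration: QC -> variance components / GEBVs -> iterative
re-weighting -> window decomposition -> report and plot.

Every stage is a pure function of (inputs, config); a run writes its
resolved configuration, a provenance log (package version, seed, config
hash) and per-stage artifacts into the output directory, so reruns with the
same config are numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    read_bed,
    read_dosage,
    read_genotypes,
    read_pedigree,
    read_phenotypes,
    write_table,
)
from .mixed_model import ModelSpec
from .qc import run_qc
from .windows import (
    annotate,
    define_windows,
    manhattan_plot,
    significant_windows,
    window_variance,
)
from .wssgwas import run_wssgwas

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    pedigree: str
    phenotypes: str
    trait: str
    genotype_ped: str | None = None  # PLINK .ped (with genotype_map)
    genotype_map: str | None = None
    genotype_dosage: str | None = None  # dosage TSV alternative
    annotation_bed: str | None = None
    fixed_factors: list[str] = field(
        default_factory=lambda: ["contemporary_group", "sex"]
    )
    covariates: list[str] = field(default_factory=lambda: ["slaughter_age"])
    min_animal_callrate: float = 0.90
    min_snp_callrate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 1e-7
    autosomes: list[int] | None = None
    n_iter: int = 3
    blend_beta: float = 0.05
    window_size_bp: int = 1_000_000
    threshold_pct: float = 1.0
    seed: int = 0
    out_dir: str = "sswas_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig):
    """Run the full analysis; returns a dict of the in-memory results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    for p in [cfg.pedigree, cfg.phenotypes, cfg.genotype_ped, cfg.genotype_map,
              cfg.genotype_dosage, cfg.annotation_bed]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    stage = "load"
    try:
        ped = read_pedigree(cfg.pedigree)
        phenos = read_phenotypes(cfg.phenotypes, cfg.trait)
        if cfg.genotype_dosage:
            panel = read_dosage(cfg.genotype_dosage, cfg.genotype_map)
        elif cfg.genotype_ped:
            panel = read_genotypes(cfg.genotype_ped, cfg.genotype_map)
        else:
            raise ValueError("no genotype input configured")

        stage = "qc"
        autosomes = set(cfg.autosomes) if cfg.autosomes else None
        panel, report = run_qc(
            panel,
            cfg.min_animal_callrate,
            cfg.min_snp_callrate,
            cfg.min_maf,
            cfg.hwe_alpha,
            autosomes,
        )
        report.to_tsv(out / "qc_report.tsv")
        # genotyped animals must be phenotyped/pedigreed to enter H
        keep = [i for i, a in enumerate(panel.animal_ids) if a in ped.index]
        if len(keep) < panel.n_animals:
            logger.warning(
                "dropping %d genotyped animals absent from pedigree",
                panel.n_animals - len(keep),
            )
            panel = panel.subset_animals(np.array(keep))

        stage = "fit+gwas"
        spec = ModelSpec(cfg.trait, list(cfg.fixed_factors), list(cfg.covariates))
        states, vc = run_wssgwas(
            ped, panel, phenos, spec, n_iter=cfg.n_iter, beta=cfg.blend_beta
        )
        import pandas as pd

        write_table(
            pd.DataFrame(
                {
                    "sigma2_a": [vc.sigma2_a],
                    "sigma2_e": [vc.sigma2_e],
                    "h2": [vc.h2],
                    "se_h2": [vc.se_h2],
                }
            ),
            out / "variance_components.tsv",
        )
        final = states[-1]
        write_table(
            pd.DataFrame(
                {"animal_id": ped.ids, "gebv": final.solutions.a_hat}
            ),
            out / "gebv.tsv",
        )
        for st in states:
            write_table(st.effects_frame(panel), out / f"snp_effects_iter{st.t}.tsv")

        stage = "windows"
        wins = define_windows(panel.chrom, panel.pos, cfg.window_size_bp)
        table = window_variance(
            wins, panel, final.u_hat, vc.sigma2_a, cfg.threshold_pct
        )
        sig = significant_windows(table)
        if cfg.annotation_bed:
            sig = annotate(sig, read_bed(cfg.annotation_bed))
        write_table(table.table, out / "windows.tsv")
        write_table(sig.table, out / "significant_windows.tsv")
        manhattan_plot(table, cfg.threshold_pct, out / "manhattan.png",
                       title=cfg.trait)

        stage = "provenance"
        cfg_hash = hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16]
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "sswas_version": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "seed": cfg.seed,
                    "config_sha256_16": cfg_hash,
                    "n_pedigree": ped.n,
                    "n_phenotyped": len(phenos),
                    "n_genotyped": panel.n_animals,
                    "n_snps": panel.n_snps,
                    "n_windows": table.n_windows,
                    "n_significant": len(sig.table),
                },
                fh,
                indent=2,
            )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return {
        "pedigree": ped,
        "panel": panel,
        "qc_report": report,
        "vc": vc,
        "states": states,
        "windows": table,
        "significant": sig,
    }
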