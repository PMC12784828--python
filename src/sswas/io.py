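"""Readers and writers for the external file formats.

Pedigrees are plain CSV triplets (animal, sire, dam), genotypes are either
PLINK-style .ped/.map text files or an additive-dosage matrix with a SNP map,
phenotypes are CSV, and annotation intervals are BED.  Everything is loaded
into small dataclass containers with string identifiers externally and dense
integer indices internally.

Conventions
-----------
* Unknown parents: ``0``, empty string or ``NA`` on input; written as ``0``.
* Missing genotypes: ``0 0`` allele pairs in .ped, ``NA`` in dosage files;
  kept as NaN in memory and imputed only by :mod:`sswas.qc`.
* Map positions are 1-based base pairs; downstream windows use half-open
  ``[start, end)`` base-pair intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = -1

_MISSING_PARENT = {"0", "", "NA", "nan", ".", "na"}


class PedigreeError(ValueError):
    """Raised for cyclic, duplicated or otherwise invalid pedigrees."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``ids[i]`` is the external identifier of the animal at internal index
    ``i``; ``sire[i]``/``dam[i]`` are internal indices of its parents, or
    :data:`UNKNOWN`.  Parents always precede offspring (``sire[i] < i``).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founder_count(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    def is_topological(self) -> bool:
        idx = np.arange(self.n)
        ok_s = (self.sire == UNKNOWN) | (self.sire < idx)
        ok_d = (self.dam == UNKNOWN) | (self.dam < idx)
        return bool(np.all(ok_s & ok_d))

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, str]]
    ) -> "Pedigree":
        """Build a topologically sorted pedigree from (animal, sire, dam).

        Parents referenced but absent as records are added as founders.
        Raises :class:`PedigreeError` on duplicates or cycles (the error
        message names the offending chain).
        """
        seen: set[str] = set()
        parents: dict[str, tuple[str | None, str | None]] = {}
        for a, s, d in records:
            a = str(a).strip()
            if a in seen:
                raise PedigreeError(f"duplicate animal_id {a!r}")
            seen.add(a)
            sv = None if str(s).strip() in _MISSING_PARENT else str(s).strip()
            dv = None if str(d).strip() in _MISSING_PARENT else str(d).strip()
            parents[a] = (sv, dv)
        # implicit founders: parents never given their own record
        for a, (s, d) in list(parents.items()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)

        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 on stack, 2 done

        def visit(node: str, chain: list[str]) -> None:
            st = state.get(node, 0)
            if st == 2:
                return
            if st == 1:
                cycle = chain[chain.index(node):] + [node]
                raise PedigreeError(
                    "pedigree cycle detected: " + " -> ".join(cycle)
                )
            state[node] = 1
            chain.append(node)
            for p in parents[node]:
                if p is not None:
                    visit(p, chain)
            chain.pop()
            state[node] = 2
            order.append(node)

        for a in parents:
            visit(a, [])

        index = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a, (s, d) in parents.items():
            i = index[a]
            if s is not None:
                sire[i] = index[s]
            if d is not None:
                dam[i] = index[d]
        return cls(ids=order, sire=sire, dam=dam, index=index)


@dataclass
class GenotypePanel:
    """Animals x SNPs additive gene content with a genomic map.

    ``gene_content`` holds dosages in {0, 1, 2} of the counted allele with
    NaN for missing calls.  ``freqs`` is the counted-allele frequency per
    SNP computed from non-missing entries only.  The map is kept sorted by
    (chromosome, position).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    gene_content: np.ndarray  # float64, NaN = missing
    chrom: np.ndarray  # int
    pos: np.ndarray  # int, 1-based bp

    def __post_init__(self) -> None:
        self.gene_content = np.asarray(self.gene_content, dtype=np.float64)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.gene_content.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("gene_content shape does not match ids/map")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_ids = [self.snp_ids[j] for j in order]
            self.gene_content = self.gene_content[:, order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
        # contiguous storage keeps downstream linear algebra bit-reproducible
        self.gene_content = np.ascontiguousarray(self.gene_content)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def freqs(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls (NaN if
        a column has no calls at all)."""
        g = self.gene_content
        called = np.sum(~np.isnan(g), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                called > 0, np.nansum(g, axis=0) / np.maximum(called, 1), np.nan
            ) / 2.0

    def subset_animals(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            [self.animal_ids[i] for i in keep],
            list(self.snp_ids),
            self.gene_content[keep],
            self.chrom.copy(),
            self.pos.copy(),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            list(self.animal_ids),
            [self.snp_ids[j] for j in keep],
            self.gene_content[:, keep],
            self.chrom[keep],
            self.pos[keep],
        )


@dataclass
class AnnotationIntervals:
    """Named genomic intervals, half-open [start_bp, end_bp)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start >= self.end):
            raise ValueError("annotation intervals require start_bp < end_bp")

    def __len__(self) -> int:
        return len(self.name)


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path) -> Pedigree:
    """Read an animal/sire/dam CSV (header optional) into a Pedigree."""
    df = pd.read_csv(path, dtype=str, header=None, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree CSV needs at least 3 columns")
    first = [str(v).lower() for v in df.iloc[0, :3]]
    if any(v in {"animal", "animal_id", "id", "sire", "dam"} for v in first):
        df = df.iloc[1:]
    records = [
        (row[0], row[1], row[2]) for row in df.itertuples(index=False)
    ]
    ped = Pedigree.from_records(records)
    logger.info("read pedigree: %d animals, %d founders", ped.n, ped.founder_count)
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam\n")
        for i, a in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] != UNKNOWN else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] != UNKNOWN else "0"
            fh.write(f"{a},{s},{d}\n")


# ---------------------------------------------------------------------------
# genotypes


def read_map(map_path) -> pd.DataFrame:
    """Read a SNP map: PLINK .map (chrom, snp, [cM,] bp, headerless) or a
    headered TSV with snp/chrom/bp columns in any order."""
    df = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment="#")
    first = [str(v).lower() for v in df.iloc[0]]
    if {"snp", "chrom", "bp"} <= set(first):
        out = df.iloc[1:].reset_index(drop=True)
        out.columns = first
        out = out[["snp", "chrom", "bp"]]
    elif df.shape[1] >= 4:
        out = df.iloc[:, [1, 0, 3]].copy()
        out.columns = ["snp", "chrom", "bp"]
    elif df.shape[1] == 3:
        out = df.iloc[:, [1, 0, 2]].copy()
        out.columns = ["snp", "chrom", "bp"]
    else:
        raise ValueError("map file needs 3 or 4 columns")
    out["chrom"] = out["chrom"].astype(int)
    out["bp"] = out["bp"].astype(int)
    return out


def read_genotypes(ped_path, map_path) -> GenotypePanel:
    """Read PLINK .ped/.map text files into a GenotypePanel.

    The counted allele at each locus is the alphabetically first observed
    allele.  Loci with more than two alleles are rejected individually with
    a log entry; a row whose allele count disagrees with the map is a file
    error.
    """
    m = read_map(map_path)
    n_snp = len(m)
    animal_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snp:
                raise ValueError(
                    f"{ped_path}: line {line_no} has {len(tok)} fields, "
                    f"expected {6 + 2 * n_snp}"
                )
            animal_ids.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U8"))
    alleles = np.array(allele_rows).reshape(len(animal_ids), n_snp, 2)

    dosage = np.full((len(animal_ids), n_snp), np.nan)
    bad: list[int] = []
    for j in range(n_snp):
        col = alleles[:, j, :]
        obs = np.unique(col[col != "0"])
        if obs.size > 2:
            bad.append(j)
            continue
        if obs.size == 0:
            continue  # all-missing: left NaN, flagged later by QC
        counted = sorted(obs)[0]
        miss = np.any(col == "0", axis=1)
        dosage[:, j] = np.sum(col == counted, axis=1)
        dosage[miss, j] = np.nan
    if bad:
        logger.warning(
            "rejected %d loci with >2 alleles: %s",
            len(bad), [m.iloc[j]["snp"] for j in bad[:10]],
        )
        keep = np.setdiff1d(np.arange(n_snp), bad)
        dosage = dosage[:, keep]
        m = m.iloc[keep].reset_index(drop=True)
    return GenotypePanel(
        animal_ids, list(m["snp"]), dosage,
        m["chrom"].to_numpy(), m["bp"].to_numpy(),
    )


def read_dosage(matrix_path, map_path) -> GenotypePanel:
    """Read an animals x SNPs dosage TSV (first column = animal id, header =
    SNP ids, NA = missing) plus a map TSV."""
    m = read_map(map_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df = df[list(m["snp"])]  # order columns by map
    return GenotypePanel(
        [str(a) for a in df.index],
        list(m["snp"]),
        df.to_numpy(dtype=np.float64),
        m["chrom"].to_numpy(),
        m["bp"].to_numpy(),
    )


def write_dosage(panel: GenotypePanel, matrix_path, map_path) -> None:
    df = pd.DataFrame(
        panel.gene_content, index=panel.animal_ids, columns=panel.snp_ids
    )
    df.index.name = "animal"
    df.to_csv(matrix_path, sep="\t", na_rep="NA")
    pd.DataFrame(
        {"snp": panel.snp_ids, "chrom": panel.chrom, "bp": panel.pos}
    ).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes / annotation


def read_phenotypes(path, trait: str) -> pd.DataFrame:
    """Load a phenotype CSV keeping animal_id, the trait, contemporary_group,
    sex and slaughter_age.

    Rows with a missing trait value are dropped (count logged); duplicate
    records per animal keep the first occurrence (count logged).
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    required = {"animal_id", trait}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=[trait])
    if len(df) < n0:
        logger.info("dropped %d rows with missing %s", n0 - len(df), trait)
    n0 = len(df)
    df = df.drop_duplicates(subset="animal_id", keep="first")
    if len(df) < n0:
        logger.info("dropped %d duplicate records (kept first)", n0 - len(df))
    return df.reset_index(drop=True)


def read_bed(path) -> AnnotationIntervals:
    """Read a BED3+1 file of named intervals (half-open, as in BED)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    name = (
        list(df.iloc[:, 3].astype(str))
        if df.shape[1] >= 4
        else [f"iv{i}" for i in range(len(df))]
    )
    return AnnotationIntervals(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].astype(int).to_numpy(),
        df.iloc[:, 2].astype(int).to_numpy(),
        name,
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV."""
    df.to_csv(path, sep="\t", index=False)
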