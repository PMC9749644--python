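"""Cohort containers and I/O: genotype matrices, covariates, QC, matching.

Genotypes are stored ordinally — 0 homozygous major, 1 heterozygous,
2 homozygous minor, -1 missing — in a dense ``int8`` samples x SNPs array.
At UK-Biobank-like scale a dense int8 matrix of a few thousand samples by a
few hundred thousand SNPs fits comfortably in memory, and dense boolean
arithmetic is what the combinatorial mining stage needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import hwe_exact_p

MISSING = np.int8(-1)

__all__ = [
    "GenotypeMatrix",
    "MatchingSpec",
    "QcParams",
    "QcReport",
    "read_genotypes",
    "write_genotypes",
    "read_covariates",
    "write_covariates",
    "qc_filter",
    "match_controls",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs ordinal genotype store with case/control labels.

    ``snp_meta`` is indexed by SNP id and carries ``chrom``, ``pos``
    (1-based), ``ref`` and ``alt`` columns; it may be empty for matrices
    read from a bare TSV.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    genotypes: np.ndarray  # int8, -1 = missing
    is_case: np.ndarray  # bool per sample
    snp_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.genotypes.shape != (self.sample_ids.size, self.snp_ids.size):
            raise ValueError("genotype matrix shape does not match ids")
        if self.is_case.size != self.sample_ids.size:
            raise ValueError("labels do not align with samples")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2} or -1 (missing)")
        if len(set(self.snp_ids)) != self.snp_ids.size:
            raise ValueError("duplicate SNP ids")

    # ---- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(idx[0])

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, ignoring missing genotypes."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        mask = self._sample_mask(mask_or_ids)
        return replace(
            self,
            sample_ids=self.sample_ids[mask],
            genotypes=self.genotypes[mask],
            is_case=self.is_case[mask],
        )

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            keep = set(mask_or_ids)
            mask = np.array([s in keep for s in self.snp_ids])
        meta = self.snp_meta
        if not meta.empty:
            meta = meta.loc[self.snp_ids[mask]]
        return replace(
            self,
            snp_ids=self.snp_ids[mask],
            genotypes=self.genotypes[:, mask],
            snp_meta=meta,
        )

    def with_labels(self, case_ids) -> "GenotypeMatrix":
        case_set = set(case_ids)
        return replace(
            self, is_case=np.array([s in case_set for s in self.sample_ids])
        )

    def _sample_mask(self, mask_or_ids) -> np.ndarray:
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            return mask_or_ids
        keep = set(mask_or_ids)
        return np.array([s in keep for s in self.sample_ids])


@dataclass(frozen=True)
class MatchingSpec:
    """Stratified case:control matching on categorical covariates."""

    ratio: int = 2
    keys: tuple[str, ...] = ("sex", "ancestry")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("matching ratio must be >= 1")


@dataclass(frozen=True)
class QcParams:
    """Genotype QC thresholds.

    Defaults are conventional array-QC values (1% MAF, 5% missingness,
    HWE exact p 1e-6 in controls); every threshold is configurable.
    """

    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.snp_missing_max, self.sample_missing_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QcReport:
    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_missingness: int = 0
    snps_removed_non_autosomal: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = None, case_ids=None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (v4.2, biallelic) or TSV.

    ``case_ids`` optionally labels samples as cases; all samples default to
    controls until labels are attached.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        gm = _read_vcf(path)
    elif fmt == "tsv":
        gm = _read_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {fmt}")
    if case_ids is not None:
        gm = gm.with_labels(case_ids)
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids, rows, meta = [], [], []
    seen = set()
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at line {i + 1} ({rec.CHROM}:{rec.POS}); "
                "split multi-allelics before loading"
            )
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if rid in seen:
            raise ValueError(f"duplicate SNP id {rid!r} at record {i + 1}")
        seen.add(rid)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(np.int8)
        dosage = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt)).astype(np.int8)
        snp_ids.append(rid)
        rows.append(dosage)
        meta.append((rid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if not snp_ids:
        raise ValueError(f"no records in {path}")
    meta_df = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    ).set_index("snp_id")
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=np.asarray(snp_ids, dtype=object),
        genotypes=np.column_stack(rows),
        is_case=np.zeros(samples.size, dtype=bool),
        snp_meta=meta_df,
    )


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    try:
        geno = df.apply(pd.to_numeric).fillna(MISSING).astype(np.int8)
    except ValueError as exc:
        raise ValueError(f"malformed genotype value in {path}: {exc}") from exc
    return GenotypeMatrix(
        sample_ids=df.index.to_numpy(dtype=object),
        snp_ids=df.columns.to_numpy(dtype=object),
        genotypes=geno.to_numpy(),
        is_case=np.zeros(len(df), dtype=bool),
    )


def write_genotypes(gm: GenotypeMatrix, path, fmt: str = "tsv") -> None:
    """Write genotypes as a TSV matrix or a minimal biallelic VCF v4.2."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(map(str, gm.snp_ids)) + "\n")
            for sid, row in zip(gm.sample_ids, gm.genotypes):
                vals = ["NA" if v == MISSING else str(int(v)) for v in row]
                fh.write(str(sid) + "\t" + "\t".join(vals) + "\n")
    elif fmt == "vcf":
        _write_vcf(gm, path)
    else:
        raise ValueError(f"unknown genotype format: {fmt}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    meta = gm.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = (
            meta["chrom"].unique() if not meta.empty else ["1"]
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.sample_ids))
            + "\n"
        )
        for j, rid in enumerate(gm.snp_ids):
            if not meta.empty and rid in meta.index:
                row = meta.loc[rid]
                chrom, pos, ref, alt = row["chrom"], row["pos"], row["ref"], row["alt"]
            else:
                chrom, pos, ref, alt = "1", j + 1, "A", "G"
            gts = "\t".join(_GT_CODE[int(v)] for v in gm.genotypes[:, j])
            fh.write(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_covariates(path) -> pd.DataFrame:
    """Per-sample covariate table, indexed by sample id, 'NA' = missing."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, params: QcParams = QcParams()) -> tuple[GenotypeMatrix, QcReport]:
    """Apply genotype QC in a fixed order: sample missingness, then SNP
    missingness, MAF and HWE (exact test in controls).  Non-autosomal SNPs
    are dropped first when ``autosomes_only`` is set."""
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_samples_in=gm.n_samples, n_snps_in=gm.n_snps)

    if params.autosomes_only and not gm.snp_meta.empty:
        chrom = gm.snp_meta.loc[gm.snp_ids, "chrom"].astype(str).to_numpy()
        keep = np.isin(chrom, list(_AUTOSOMES))
        report.snps_removed_non_autosomal = int((~keep).sum())
        gm = gm.subset_snps(keep)

    missing = gm.genotypes == MISSING

    sample_miss = missing.mean(axis=1)
    keep_samples = sample_miss <= params.sample_missing_max
    report.samples_removed_missingness = int((~keep_samples).sum())
    gm = gm.subset_samples(keep_samples)

    missing = gm.genotypes == MISSING
    snp_miss = missing.mean(axis=0)
    keep = snp_miss <= params.snp_missing_max
    report.snps_removed_missingness = int((~keep).sum())
    gm = gm.subset_snps(keep)

    maf = gm.maf()
    keep = maf >= params.maf_min
    report.snps_removed_maf = int((~keep).sum())
    gm = gm.subset_snps(keep)

    if params.hwe_p_min > 0 and gm.n_controls > 0:
        ctrl = gm.genotypes[~gm.is_case]
        keep = np.ones(gm.n_snps, dtype=bool)
        for j in range(gm.n_snps):
            col = ctrl[:, j]
            col = col[col != MISSING]
            counts = np.bincount(col, minlength=3)
            if hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])) < params.hwe_p_min:
                keep[j] = False
        report.snps_removed_hwe = int((~keep).sum())
        gm = gm.subset_snps(keep)

    if gm.n_snps == 0:
        raise ValueError("QC removed every SNP")
    report.n_samples_out = gm.n_samples
    report.n_snps_out = gm.n_snps
    return gm, report


# ---------------------------------------------------------------------------
# control matching
# ---------------------------------------------------------------------------

def match_controls(
    case_covariates: pd.DataFrame,
    pool_covariates: pd.DataFrame,
    spec: MatchingSpec = MatchingSpec(),
) -> list:
    """Select ratio x controls per case stratum, matched on the key
    covariates, sampled without replacement with a fixed seed.

    Returns the selected control sample ids.  Raises if any stratum cannot
    supply enough controls, naming the stratum and the deficit.
    """
    overlap = case_covariates.index.intersection(pool_covariates.index)
    if len(overlap) > 0:
        raise ValueError("control pool must be disjoint from cases")
    keys = list(spec.keys)
    rng = np.random.default_rng(spec.seed)
    selected: list = []
    case_strata = case_covariates.groupby(keys, sort=True, dropna=False)
    pool_groups = dict(iter(pool_covariates.groupby(keys, sort=True, dropna=False)))
    for stratum, cases in case_strata:
        need = spec.ratio * len(cases)
        avail = pool_groups.get(stratum)
        n_avail = 0 if avail is None else len(avail)
        if n_avail < need:
            raise ValueError(
                f"stratum {stratum}: need {need} controls, only {n_avail} available "
                f"(deficit {need - n_avail})"
            )
        ids = np.sort(avail.index.to_numpy())
        take = rng.choice(ids, size=need, replace=False)
        selected.extend(take.tolist())
    return selected
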