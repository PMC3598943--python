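"""Post-genotyping qualification of candidate SNPs.

Given validation genotypes (alt-allele dosage 0/1/2, or missing) this
module classifies assay conversion (polymorphic / monomorphic due to low
allele count / failed to convert), checks Mendelian transmission in
sire-dam-offspring trios, computes the exact conditional
Hardy-Weinberg test, and estimates minor-allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import lgamma, log
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


class ConversionClass(str, Enum):
    polymorphic = "polymorphic"
    monomorphic_low_allele_count = "monomorphic_low_allele_count"
    failed = "failed"


class GenotypeMatrix:
    """Samples x SNPs alt-dosage calls with -1 for missing.

    Optional per-sample line labels and per-SNP chromosome names enable
    line-subset MAF estimation and autosome-only trio checks.
    """

    def __init__(self, samples: Sequence[str], snp_ids: Sequence[str],
                 calls: np.ndarray, sample_lines: Sequence[str] | None = None,
                 snp_chroms: Sequence[str] | None = None):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(snp_ids)):
            raise ValueError("calls shape must be (n_samples, n_snps)")
        bad = ~np.isin(calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 for missing")
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.snp_ids = list(snp_ids)
        self.calls = calls
        self.sample_lines = list(sample_lines) if sample_lines is not None else None
        self.snp_chroms = list(snp_chroms) if snp_chroms is not None else None
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_idx(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample id {sample!r}") from None

    def snp_idx(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp id {snp_id!r}") from None

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, sample_lines: Sequence[str] | None = None,
                 snp_chroms: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Read a sample x SNP TSV with values {0,1,2,NA}."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         na_values=["NA", "."])
        calls = df.fillna(MISSING).to_numpy()
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   calls.astype(np.int8), sample_lines, snp_chroms)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.calls.astype(object), index=self.samples,
                          columns=self.snp_ids)
        df = df.where(df != MISSING, "NA")
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_vcf(cls, path, sample_lines: Sequence[str] | None = None,
                 ) -> "GenotypeMatrix":
        """Read GT fields from a VCF into alt-allele dosages."""
        import pysam

        snp_ids, chroms, columns = [], [], []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                snp_ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
                chroms.append(rec.chrom)
                col = np.full(len(samples), MISSING, dtype=np.int8)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    col[i] = sum(1 for a in gt if a != 0)
                columns.append(col)
        calls = (np.stack(columns, axis=1) if columns
                 else np.empty((len(samples), 0), dtype=np.int8))
        return cls(samples, snp_ids, calls, sample_lines, chroms)


@dataclass
class TrioSet:
    """Sire, dam, offspring sample-id triples."""

    trios: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        for sire, dam, off in self.trios:
            if off in (sire, dam):
                raise ValueError(f"offspring {off!r} duplicates a parent")

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    @classmethod
    def from_tsv(cls, path) -> "TrioSet":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = ["sire", "dam", "offspring"]
        if not all(c in df.columns for c in cols):
            raise ValueError(f"trio file needs columns {cols}")
        return cls([tuple(r) for r in df[cols].itertuples(index=False)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.trios, columns=["sire", "dam", "offspring"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Conversion classification
# ---------------------------------------------------------------------

def classify_conversion(matrix: GenotypeMatrix, call_rate_min: float = 0.98,
                        min_minor_count: int = 2) -> dict[str, ConversionClass]:
    """Per-SNP assay class.

    failed: call rate below call_rate_min; monomorphic_low_allele_count:
    minor-allele count over called genotypes below min_minor_count;
    otherwise polymorphic.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    calls = matrix.calls
    called = calls != MISSING
    rate = called.mean(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    minor = np.minimum(alt, total - alt)
    out = {}
    for j, sid in enumerate(matrix.snp_ids):
        if rate[j] < call_rate_min:
            out[sid] = ConversionClass.failed
        elif minor[j] < min_minor_count:
            out[sid] = ConversionClass.monomorphic_low_allele_count
        else:
            out[sid] = ConversionClass.polymorphic
    return out


# ---------------------------------------------------------------------
# Mendelian trio check
# ---------------------------------------------------------------------

def _consistency_table() -> np.ndarray:
    """ok[sire, dam, offspring] for dosages 0/1/2: the offspring can
    receive one allele from each parent."""
    ok = np.zeros((3, 3, 3), dtype=bool)
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    for s in range(3):
        for d in range(3):
            for o in range(3):
                ok[s, d, o] = any(a + b == o for a in alleles[s] for b in alleles[d])
    return ok


_MENDEL_OK = _consistency_table()
SEX_CHROMS = frozenset({"ChrZ", "ChrW", "chrZ", "chrW", "Z", "W"})


def mendelian_check(matrix: GenotypeMatrix, trios: TrioSet,
                    autosomes_only: bool = True,
                    ) -> tuple[dict[str, bool], pd.DataFrame]:
    """Flag SNPs inconsistent with Mendelian transmission in >= 1 trio.

    A trio with any missing genotype at a SNP carries no evidence and is
    treated as consistent.  Sex chromosomes are skipped by default
    (hemizygosity breaks the diploid rules).  Returns the per-SNP flag
    and a frame with the inconsistent-trio count per SNP.
    """
    n_bad = np.zeros(matrix.n_snps, dtype=int)
    checkable = np.ones(matrix.n_snps, dtype=bool)
    if autosomes_only and matrix.snp_chroms is not None:
        checkable = ~np.isin(matrix.snp_chroms, list(SEX_CHROMS))
    for sire, dam, off in trios:
        gs = matrix.calls[matrix.sample_idx(sire)]
        gd = matrix.calls[matrix.sample_idx(dam)]
        go = matrix.calls[matrix.sample_idx(off)]
        complete = (gs != MISSING) & (gd != MISSING) & (go != MISSING) & checkable
        idx = np.flatnonzero(complete)
        bad = ~_MENDEL_OK[gs[idx], gd[idx], go[idx]]
        n_bad[idx[bad]] += 1
    flags = {sid: bool(n_bad[j] > 0) for j, sid in enumerate(matrix.snp_ids)}
    counts = pd.DataFrame({"snp_id": matrix.snp_ids, "n_inconsistent_trios": n_bad})
    return flags, counts


# ---------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int, midp: bool = False) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates every
    feasible heterozygote count of matching parity, weighting each
    genotype configuration by n!/(n_AA! n_AB! n_BB!) * 2^n_AB.  The
    p-value sums the probabilities of all outcomes no more probable
    than the observed one (two-sided); with ``midp`` only half the
    observed outcome's probability is counted.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    rare = min(n_a, n_b)
    hets = range(rare % 2, rare + 1, 2)
    logw = []
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        lw = (lgamma(n + 1) - lgamma(hom_rare + 1) - lgamma(h + 1)
              - lgamma(hom_common + 1) + h * log(2.0))
        logw.append(lw)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs = list(hets).index(n_AB)
    le = probs <= probs[obs] * (1 + 1e-12)
    p = float(probs[le].sum())
    if midp:
        p -= 0.5 * float(probs[obs])
    return min(p, 1.0)


def hwe_pvalues(matrix: GenotypeMatrix, midp: bool = False) -> dict[str, float]:
    """Exact HWE p-value per SNP from called genotypes."""
    out = {}
    calls = matrix.calls
    for j, sid in enumerate(matrix.snp_ids):
        col = calls[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            continue
        counts = np.bincount(col, minlength=3)
        out[sid] = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]),
                                  midp=midp)
    return out


# ---------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------

def estimate_maf(matrix: GenotypeMatrix, snp_id: str,
                 line_subset: Sequence[str] | None = None) -> float:
    """Folded allele frequency min(p, 1-p) from called dosages.

    ``line_subset`` restricts to samples whose line label is listed;
    NaN when every genotype in scope is missing.
    """
    j = matrix.snp_idx(snp_id)
    col = matrix.calls[:, j]
    if line_subset is not None:
        if matrix.sample_lines is None:
            raise ValueError("matrix has no sample line labels")
        keep = np.isin(matrix.sample_lines, list(line_subset))
        col = col[keep]
    col = col[col != MISSING]
    if len(col) == 0:
        return float("nan")
    p = col.sum() / (2.0 * len(col))
    return float(min(p, 1.0 - p))


def maf_all(matrix: GenotypeMatrix, line_subset: Sequence[str] | None = None,
            ) -> pd.Series:
    """Folded frequencies for every SNP (vectorised)."""
    calls = matrix.calls
    if line_subset is not None:
        if matrix.sample_lines is None:
            raise ValueError("matrix has no sample line labels")
        calls = calls[np.isin(matrix.sample_lines, list(line_subset))]
    called = calls != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return pd.Series(np.minimum(p, 1 - p), index=matrix.snp_ids)
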