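"""Candidate-reduction filter cascade and genome k-mer masking.

The cascade shrinks a raw multi-line SNP catalog to an array-designable
candidate list: a quality/MAF screen with prior-panel rescue and an
exemption for the MHC-bearing chromosome 16 and the Z chromosome, a
close-proximity spacing screen, probe design-score thresholds, and a
per-line coverage-outlier exclusion targeting duplicated regions.  The
extreme Hardy-Weinberg exclusion applies after validation genotyping.

All filters only remove records; survivors are never mutated, so every
filter is idempotent and preserves sorted order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .catalog import SnpCatalog


@dataclass
class FilterPolicy:
    """Thresholds for the reduction cascade."""

    min_quality: float = 60.0
    min_maf: float = 0.05
    exempt_chroms: frozenset = frozenset({"Chr16", "ChrZ"})
    near_gap: int = 4      # SNP-free bases required on the less-constrained side
    far_gap: int = 10      # SNP-free bases required on the other side
    max_kmer16: int = 100
    min_pconvert: float = 0.2
    coverage_sd_k: float = 3.0
    hwe_alpha: float = 1e-5
    proximity_iterative: bool = False  # sensitivity option; default single pass

    def __post_init__(self):
        if self.near_gap > self.far_gap:
            raise ValueError("near_gap must not exceed far_gap")
        for name in ("min_quality", "min_maf", "near_gap", "far_gap",
                     "max_kmer16", "min_pconvert", "coverage_sd_k", "hwe_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.exempt_chroms = frozenset(self.exempt_chroms)


def filter_quality_maf(catalog: SnpCatalog, policy: FilterPolicy | None = None) -> SnpCatalog:
    """Quality >= 60 and MAF >= 0.05 screen with rescues.

    A record survives if its chromosome is exempt, if any single line
    shows both quality >= min_quality and MAF >= min_maf, if the global
    (all-lines-combined) analysis does, or if it was present in a prior
    panel.
    """
    policy = policy or FilterPolicy()
    df = catalog.df
    keep = df["chrom"].isin(policy.exempt_chroms).to_numpy()
    keep |= df["in_prior_panel"].to_numpy(dtype=bool)
    gq = df["global_quality"].to_numpy(dtype=float)
    gm = df["global_maf"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep |= (gq >= policy.min_quality) & (gm >= policy.min_maf)
        for name in catalog.line_names():
            q = df[f"{name}_qual"].to_numpy(dtype=float)
            m = df[f"{name}_maf"].to_numpy(dtype=float)
            keep |= (q >= policy.min_quality) & (m >= policy.min_maf)
    return catalog.subset(keep)


def _proximity_keep(pos: np.ndarray, near: int, far: int) -> np.ndarray:
    """Keep mask for sorted positions on one chromosome (single pass)."""
    n = len(pos)
    left = np.full(n, np.inf)
    right = np.full(n, np.inf)
    if n > 1:
        gaps = pos[1:] - pos[:-1] - 1  # intervening SNP-free bases
        left[1:] = gaps
        right[:-1] = gaps
    return ((left >= far) & (right >= near)) | ((left >= near) & (right >= far))


def filter_proximity(catalog: SnpCatalog, policy: FilterPolicy | None = None) -> SnpCatalog:
    """Spacing screen: >= far_gap SNP-free bases on one side and
    >= near_gap on the other.

    Evaluated in a single pass against the original SNP configuration
    (not re-evaluated as records drop out): the screen targets clusters
    of tightly spaced SNPs, and iterative removal would over-delete the
    cluster's flanks.  Chromosome-terminal sides count as infinite gaps.
    Exempt chromosomes bypass the filter.
    """
    policy = policy or FilterPolicy()
    df = catalog.df
    keep = np.zeros(len(df), dtype=bool)
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        if chrom in policy.exempt_chroms:
            keep[idx] = True
            continue
        pos = df["pos"].to_numpy()[idx]
        if policy.proximity_iterative:
            mask = np.ones(len(pos), dtype=bool)
            while True:
                sub = _proximity_keep(pos[mask], policy.near_gap, policy.far_gap)
                if sub.all():
                    break
                mask[np.flatnonzero(mask)[~sub]] = False
            keep[idx] = mask
        else:
            keep[idx] = _proximity_keep(pos, policy.near_gap, policy.far_gap)
    return catalog.subset(keep)


def filter_design_scores(catalog: SnpCatalog, policy: FilterPolicy | None = None,
                         ) -> SnpCatalog:
    """Probe design screen: some strand has 16-mer count <= 100 AND
    p-convert >= 0.2 (inclusive).  Records with no scores on either
    strand are removed and reported."""
    policy = policy or FilterPolicy()
    df = catalog.df
    with np.errstate(invalid="ignore"):
        fwd = ((df["fwd_16mer"].to_numpy(float) <= policy.max_kmer16)
               & (df["fwd_pconvert"].to_numpy(float) >= policy.min_pconvert))
        rev = ((df["rev_16mer"].to_numpy(float) <= policy.max_kmer16)
               & (df["rev_pconvert"].to_numpy(float) >= policy.min_pconvert))
    scoreless = (df[["fwd_16mer", "fwd_pconvert"]].isna().any(axis=1)
                 & df[["rev_16mer", "rev_pconvert"]].isna().any(axis=1)).to_numpy()
    n_scoreless = int(scoreless.sum())
    if n_scoreless:
        warnings.warn(f"{n_scoreless} records lack design scores on both strands; removed")
    return catalog.subset((fwd | rev) & ~scoreless)


def filter_coverage_outliers(catalog: SnpCatalog, policy: FilterPolicy | None = None,
                             ) -> SnpCatalog:
    """Remove records whose coverage, in any line where they segregate,
    exceeds that line's mean by more than coverage_sd_k sample SDs
    (strict inequality).  Lines with fewer than two segregating records
    contribute no exclusions."""
    policy = policy or FilterPolicy()
    df = catalog.df
    drop = np.zeros(len(df), dtype=bool)
    for name in catalog.line_names():
        seg = df[f"{name}_seg"].to_numpy(dtype=bool)
        cov = df[f"{name}_cov"].to_numpy(dtype=float)
        use = seg & ~np.isnan(cov)
        if use.sum() < 2:
            if use.sum() == 1:
                warnings.warn(f"line {name}: <2 segregating records, no coverage screen")
            continue
        mean = cov[use].mean()
        sd = cov[use].std(ddof=1)
        drop |= use & (cov > mean + policy.coverage_sd_k * sd)
    return catalog.subset(~drop)


def filter_hwe_extreme(catalog: SnpCatalog, hwe_pvalues: Mapping[str, float],
                       policy: FilterPolicy | None = None) -> SnpCatalog:
    """Remove records with an extreme Hardy-Weinberg departure
    (p < hwe_alpha, strict).  Records without a p-value are kept."""
    policy = policy or FilterPolicy()
    for sid, p in hwe_pvalues.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"HWE p-value out of [0,1] for {sid}: {p}")
    pvals = catalog.df["snp_id"].map(hwe_pvalues)
    keep = ~(pvals < policy.hwe_alpha)
    return catalog.subset(keep.to_numpy())


CASCADE = ("quality_maf", "proximity", "design_scores", "coverage_outliers")


def apply_cascade(catalog: SnpCatalog, policy: FilterPolicy | None = None,
                  ) -> tuple[SnpCatalog, list[dict]]:
    """Run the pre-genotyping cascade in order; returns the surviving
    catalog and a per-stage count ledger."""
    policy = policy or FilterPolicy()
    stages = {
        "quality_maf": filter_quality_maf,
        "proximity": filter_proximity,
        "design_scores": filter_design_scores,
        "coverage_outliers": filter_coverage_outliers,
    }
    ledger = []
    for name in CASCADE:
        before = len(catalog)
        catalog = stages[name](catalog, policy)
        ledger.append({"stage": name, "n_before": before, "n_after": len(catalog),
                       "n_removed": before - len(catalog)})
    return catalog, ledger


# ---------------------------------------------------------------------
# Genome k-mer masking
# ---------------------------------------------------------------------

def mask_frequent_kmers(sequences: Mapping[str, str], k: int = 16, max_occ: int = 5,
                        ) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Soft-mask every base covered by a k-mer occurring more than
    ``max_occ`` times across all sequences.

    Counting is forward-strand and overlap-inclusive; k-mers containing
    N are ignored.  Returns the masked (lowercased) sequences and the
    masked intervals per sequence, 0-based half-open, merged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    uppers = {name: seq.upper() for name, seq in sequences.items()}
    for seq in uppers.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    frequent = {km for km, c in counts.items() if c > max_occ}
    masked: dict[str, str] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for name, seq in uppers.items():
        cover = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - k + 1):
            if seq[i:i + k] in frequent:
                cover[i:i + k] = True
        out = "".join(c.lower() if m else c for c, m in zip(seq, cover))
        masked[name] = out
        ivs = []
        j = 0
        while j < len(seq):
            if cover[j]:
                start = j
                while j < len(seq) and cover[j]:
                    j += 1
                ivs.append((start, j))
            else:
                j += 1
        intervals[name] = ivs
    return masked, intervals
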