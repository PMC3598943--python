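"""Summary arithmetic and distributions for panel reports.

Percentages are rounded half-up to two decimals and group means to one
decimal of a million so that every printed figure recomputes exactly
from its own counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .catalog import SnpCatalog
from .genmap import GeneticMap

ANNOTATION_CATEGORIES = (
    "intergenic", "intronic", "non-synonymous", "synonymous",
    "stopgain_stoploss", "upstream1kb", "downstream1kb", "utr3", "utr5",
    "splicing", "ncRNA",
)


@dataclass
class ValidationSummary:
    total_validated: int
    polymorphic: int
    monomorphic: int
    failed: int
    trios: int
    mendel_fail: int
    percentages: dict[str, float] = field(default_factory=dict)


def validation_summary(total_validated: int, polymorphic: int, monomorphic: int,
                       failed: int, trios: int, mendel_fail: int,
                       ) -> ValidationSummary:
    """Marker-conversion and Mendelian summary with exact percentages."""
    counts = (total_validated, polymorphic, monomorphic, failed, trios, mendel_fail)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if polymorphic + monomorphic + failed != total_validated:
        raise ValueError("conversion classes must sum to total_validated")
    if mendel_fail > polymorphic:
        raise ValueError("mendel_fail cannot exceed polymorphic count")
    pct = {
        "polymorphic": percent(polymorphic, total_validated),
        "monomorphic": percent(monomorphic, total_validated),
        "failed": percent(failed, total_validated),
        "mendel_fail": percent(mendel_fail, total_validated),
    }
    return ValidationSummary(total_validated, polymorphic, monomorphic, failed,
                             trios, mendel_fail, pct)


@dataclass
class AnnotationSummary:
    total_panel: int
    annotated: int
    annotated_percent: float
    category_counts: dict[str, int]
    category_percent: dict[str, float]


def annotation_summary(panel_catalog: SnpCatalog | Mapping[str, int],
                       total_panel: int | None = None) -> AnnotationSummary:
    """Per-category annotation counts and percentages.

    Category percentages are of annotated SNPs; the annotated percentage
    is of the whole panel.  Accepts either a catalog (counting its
    annotation column) or a precomputed {category: count} mapping plus
    total_panel.
    """
    if isinstance(panel_catalog, SnpCatalog):
        ann = panel_catalog.df["annotation"]
        total = len(panel_catalog)
        counts = ann.dropna().value_counts().to_dict()
    else:
        counts = dict(panel_catalog)
        if total_panel is None:
            raise ValueError("total_panel required with precomputed counts")
        total = total_panel
    unknown = sorted(set(counts) - set(ANNOTATION_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown annotation categories: {unknown}")
    full = {c: int(counts.get(c, 0)) for c in ANNOTATION_CATEGORIES}
    annotated = sum(full.values())
    return AnnotationSummary(
        total_panel=total, annotated=annotated,
        annotated_percent=percent(annotated, total),
        category_counts=full,
        category_percent={c: percent(n, annotated) for c, n in full.items()},
    )


@dataclass
class SpacingStats:
    """Inter-marker spacing including chromosome-terminal distances."""

    gaps: np.ndarray           # all gaps (terminal + inter-SNP), bases
    inter_gaps: np.ndarray     # inter-SNP gaps only
    genome_length: int
    mean_gap: float
    sd_gap: float

    def cumulative_snp_fraction(self, g: float) -> float:
        """Fraction of inter-SNP gaps of size <= g."""
        if len(self.inter_gaps) == 0:
            return 0.0
        return float((self.inter_gaps <= g).mean())

    def genome_coverage_fraction(self, g: float) -> float:
        """Fraction of the genome not lying in gaps larger than g."""
        uncovered = self.gaps[self.gaps > g].sum()
        return float(1.0 - uncovered / self.genome_length)

    def curves(self, grid: Sequence[float] | None = None) -> pd.DataFrame:
        if grid is None:
            grid = np.unique(np.concatenate([[0], np.sort(self.gaps)]))
        return pd.DataFrame({
            "gap": grid,
            "cum_snp_fraction": [self.cumulative_snp_fraction(g) for g in grid],
            "genome_coverage_fraction": [self.genome_coverage_fraction(g) for g in grid],
        })


def spacing_stats(panel: pd.DataFrame, chrom_lengths: Mapping[str, int],
                  ) -> SpacingStats:
    """Gap statistics of a panel frame (snp_id, chrom, pos).

    Gaps are consecutive position differences plus, per chromosome, the
    distances from each end to the nearest SNP; the gap multiset of a
    chromosome sums exactly to its length.  A chromosome with no panel
    SNP contributes a single gap equal to its length, with a warning.
    """
    panel = panel.sort_values(["chrom", "pos"], kind="mergesort")
    gaps, inter = [], []
    for chrom, length in chrom_lengths.items():
        pos = panel.loc[panel["chrom"] == chrom, "pos"].to_numpy()
        if len(pos) == 0:
            warnings.warn(f"{chrom}: no panel SNPs, single whole-chromosome gap")
            gaps.append(float(length))
            continue
        if pos[-1] > length:
            raise ValueError(f"{chrom}: position {pos[-1]} beyond length {length}")
        d = np.diff(pos).astype(float)
        gaps.extend([float(pos[0])] + d.tolist() + [float(length - pos[-1])])
        inter.extend(d.tolist())
    extra = set(panel["chrom"]) - set(chrom_lengths)
    if extra:
        raise ValueError(f"panel chromosomes missing from length table: {sorted(extra)}")
    gaps = np.array(gaps)
    inter = np.array(inter)
    return SpacingStats(
        gaps=gaps, inter_gaps=inter,
        genome_length=int(sum(chrom_lengths.values())),
        mean_gap=float(gaps.mean()),
        sd_gap=float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0,
    )


def density_by_chromosome(panel: pd.DataFrame, gmap: GeneticMap,
                          chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """SNPs/Mb and SNPs/cM per chromosome."""
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int((panel["chrom"] == chrom).sum())
        mb = length / 1e6
        cm = gmap.map_length_cm(chrom) if chrom in gmap else np.nan
        if length <= 0:
            warnings.warn(f"{chrom}: zero length, density undefined")
            rows.append({"chrom": chrom, "n_snps": n, "snps_per_mb": np.nan,
                         "snps_per_cm": np.nan})
            continue
        rows.append({
            "chrom": chrom, "n_snps": n,
            "snps_per_mb": n / mb,
            "snps_per_cm": n / cm if cm and cm > 0 else (0.0 if n == 0 else np.nan),
        })
    return pd.DataFrame(rows)


def group_sharing(catalog: SnpCatalog, grouping: Mapping[str, str],
                  ) -> dict[frozenset, int]:
    """Three-set Venn region counts of segregation sharing.

    ``grouping`` maps line name -> group (each line in at most one
    group; exactly three groups).  A SNP counts toward the region of the
    exact combination of groups in which it segregates (in >= 1 line);
    SNPs segregating only in ungrouped lines are excluded.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) != 3:
        raise ValueError("group_sharing expects exactly three groups")
    seg = catalog.seg_matrix()
    names = catalog.line_names()
    in_group = {g: np.zeros(len(catalog), dtype=bool) for g in groups}
    for j, name in enumerate(names):
        g = grouping.get(name)
        if g is not None:
            in_group[g] |= seg[:, j]
    out: dict[frozenset, int] = {}
    flags = np.stack([in_group[g] for g in groups], axis=1)
    for combo in range(1, 8):
        bits = np.array([(combo >> i) & 1 for i in range(3)], dtype=bool)
        mask = (flags == bits).all(axis=1)
        out[frozenset(g for g, b in zip(groups, bits) if b)] = int(mask.sum())
    return out


def group_mean_counts(per_line_counts: Mapping[str, int],
                      grouping: Mapping[str, str]) -> dict[str, float | None]:
    """Mean SNP count per group, in millions rounded to one decimal."""
    if any(c < 0 for c in per_line_counts.values()):
        raise ValueError("counts must be non-negative")
    sums: dict[str, list[int]] = {}
    for line, g in grouping.items():
        if line in per_line_counts:
            sums.setdefault(g, []).append(per_line_counts[line])
    out: dict[str, float | None] = {}
    for g in set(grouping.values()):
        vals = sums.get(g, [])
        out[g] = round_half_up(np.mean(vals) / 1e6, 1) if vals else None
    return out


def maf_distribution(values, bins: np.ndarray | None = None):
    """Histogram of folded frequencies over (0, 0.5].

    Default bins have width 0.05; values of exactly 0 fall in the first
    bin.  ``values`` may be an array (one histogram) or a mapping
    group -> array (one histogram per group, as a DataFrame).
    """
    if bins is None:
        bins = np.round(np.arange(0.0, 0.5001, 0.05), 10)
    if isinstance(values, Mapping):
        return pd.DataFrame(
            {g: maf_distribution(v, bins) for g, v in values.items()})
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) and (vals.min() < 0 or vals.max() > bins[-1]):
        raise ValueError("MAF values must lie in [0, 0.5]")
    # left-open, right-closed bins; exact zeros fall in the first bin
    idx = np.clip(np.searchsorted(bins, vals, side="left") - 1, 0, len(bins) - 2)
    counts = np.bincount(idx, minlength=len(bins) - 1)
    labels = [f"({bins[i]:.2f},{bins[i + 1]:.2f}]" for i in range(len(bins) - 1)]
    return pd.Series(counts, index=labels, name="count")
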