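"""Synthetic multi-line SNP catalogs, genetic maps, genotypes and trios.

The generator emulates the inputs of a pooled-resequencing array-design
study: 24 chicken lines (4 broiler, 6 white egg layer, 5 brown egg
layer, 8 inbred, 1 unselected experimental layer) whose allele
frequencies diverge from a common ancestral frequency under the
Balding-Nichols drift model — first group-level drift, then line-level
drift within the group.  Inbred lines use a high drift coefficient so
that most sites are fixed, reproducing the order-of-magnitude contrast
between segregating-SNP counts of commercial and inbred lines.  A line
"segregates" at a site when both alleles appear in a simulated
sequencing pool of 2 x pool_size allele draws.

The synthetic genome is a scaled-down karyotype of seven chromosomes
(~60 Mb) with a macro/micro recombination-rate contrast (2-15 cM/Mb),
so that evenness in cM differs materially from evenness in bp.

All draws come from a single integer-seeded PCG64 generator: identical
configuration and seed give byte-identical outputs on any platform.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import LineInfo, SnpCatalog, _columns_for
from .genmap import GeneticMap
from .validation import MISSING, GenotypeMatrix, TrioSet


def default_lines() -> list[LineInfo]:
    """The emulated 24-line panel, with the per-line filling order
    (white layers, then brown, then broilers — increasing LD need last)."""
    lines = []
    rank = 0
    for i in range(1, 7):
        lines.append(LineInfo(f"WEL{i}", "WEL", True, rank, None)); rank += 1
    for i in range(1, 6):
        lines.append(LineInfo(f"BEL{i}", "BEL", True, rank, None)); rank += 1
    for i in range(1, 5):
        lines.append(LineInfo(f"B{i}", "broiler", True, rank, None)); rank += 1
    lines.append(LineInfo("RI-J", "experimental", False, None, None))
    for i in range(1, 9):
        lines.append(LineInfo(f"I{i}", "inbred", False, None, None))
    return lines


#: (name, length_bp, cM/Mb): scaled-down macro/micro karyotype.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int, float], ...] = (
    ("Chr1", 20_000_000, 2.5),
    ("Chr2", 15_000_000, 3.0),
    ("Chr5", 8_000_000, 5.0),
    ("Chr10", 4_000_000, 8.0),
    ("Chr16", 500_000, 15.0),
    ("Chr20", 2_000_000, 12.0),
    ("ChrZ", 10_000_000, 2.0),
)


@dataclass
class SimConfig:
    seed: int = 0
    lines: list[LineInfo] = field(default_factory=default_lines)
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    n_snps: int = 10_000
    f_group: float = 0.10
    f_line: float = 0.05
    f_inbred: float = 0.90
    pool_size: int = 10
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    quality_mean: float = 80.0
    quality_sd: float = 15.0
    coverage_mean: float = 12.0
    coverage_shape: float = 10.0
    pconvert_pass_rate: float = 0.73
    kmer_pass_rate: float = 0.93
    prior_panel_rate: float = 0.01
    coding_rate: float = 0.02
    annotated_rate: float = 0.85
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.01
    mendel_injection_rate: float = 0.0

    def __post_init__(self):
        for name in ("f_group", "f_line", "f_inbred", "pconvert_pass_rate",
                     "kmer_pass_rate", "prior_panel_rate", "coding_rate",
                     "annotated_rate", "genotype_error_rate", "missing_rate",
                     "mendel_injection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if any(length <= 0 for _, length, _ in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class CatalogTruth:
    """Latent frequencies behind a simulated catalog."""

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray
    ancestral: np.ndarray
    line_freq: pd.DataFrame   # snp x line alt-allele frequency
    lines: list[LineInfo]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"snp_id": self.snp_ids, "chrom": self.chroms,
                            "pos": self.positions, "ancestral": self.ancestral})
        return pd.concat([out, self.line_freq.reset_index(drop=True)], axis=1)


def _line_seed(config: SimConfig, line: str, salt: int) -> list[int]:
    return [config.seed & 0x7FFFFFFF, zlib.crc32(line.encode()) & 0x7FFFFFFF, salt]


def _balding_nichols(rng, f: float, p: np.ndarray) -> np.ndarray:
    """Drifted frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f <= 0:
        return p.copy()
    if f >= 1:
        return (rng.random(p.shape) < p).astype(float)
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b)


def simulate_map(config: SimConfig) -> GeneticMap:
    """Anchor map with within-chromosome rate variation (x0.8/1.0/1.3/0.9
    across four equal intervals around the chromosome's mean cM/Mb)."""
    multipliers = np.array([0.8, 1.0, 1.3, 0.9])
    anchors = {}
    for name, length, rate in config.chromosomes:
        bp = np.linspace(1, length, len(multipliers) + 1)
        seg_cm = np.diff(bp) / 1e6 * rate * multipliers
        cm = np.concatenate([[0.0], np.cumsum(seg_cm)])
        anchors[name] = (bp.astype(np.int64), cm)
    return GeneticMap(anchors)


def simulate_catalog(config: SimConfig) -> tuple[SnpCatalog, CatalogTruth]:
    """Draw a catalog: positions uniform per chromosome, ancestral
    frequency ~ U(0.05, 0.95), group then line drift, pooled segregation
    calls, per-line quality/coverage, and design scores at the
    configured pass rates."""
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    total = sum(length for _, length, _ in config.chromosomes)
    chroms_all, pos_all = [], []
    for name, length, _ in config.chromosomes:
        n_c = int(round(config.n_snps * length / total))
        pos = np.unique(rng.integers(1, length + 1, size=n_c))
        chroms_all.extend([name] * len(pos))
        pos_all.append(pos)
    positions = np.concatenate(pos_all) if pos_all else np.array([], dtype=np.int64)
    n = len(positions)
    snp_ids = [f"{c}_{p}" for c, p in zip(chroms_all, positions)]

    ancestral = rng.uniform(config.ancestral_low, config.ancestral_high, n)
    groups = sorted({l.group for l in config.lines})
    group_freq = {g: _balding_nichols(rng, config.f_group, ancestral) for g in groups}

    data = {
        "snp_id": snp_ids, "chrom": chroms_all, "pos": positions,
    }
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    data["ref"] = bases[ref_i]
    data["alt"] = bases[alt_i]
    data["global_quality"] = np.maximum(
        rng.normal(config.quality_mean, config.quality_sd, n), 0.0)
    data["global_maf"] = np.minimum(ancestral, 1 - ancestral)
    data["in_prior_panel"] = rng.random(n) < config.prior_panel_rate
    coding = rng.random(n) < config.coding_rate
    data["coding"] = coding

    coding_cats = np.array(["non-synonymous", "synonymous", "stopgain_stoploss"])
    noncoding_cats = np.array(["intergenic", "intronic", "upstream1kb",
                               "downstream1kb", "utr3", "utr5", "splicing", "ncRNA"])
    noncoding_w = np.array([0.55, 0.39, 0.015, 0.015, 0.01, 0.005, 0.01, 0.005])
    ann = np.full(n, None, dtype=object)
    annotated = rng.random(n) < config.annotated_rate
    ann[coding] = rng.choice(coding_cats, coding.sum(), p=[0.43, 0.555, 0.015])
    nc = annotated & ~coding
    ann[nc] = rng.choice(noncoding_cats, nc.sum(), p=noncoding_w / noncoding_w.sum())
    data["annotation"] = ann

    for prefix in ("fwd", "rev"):
        pass16 = rng.random(n) < config.kmer_pass_rate
        data[f"{prefix}_16mer"] = np.where(pass16, rng.integers(0, 101, n),
                                           rng.integers(101, 501, n)).astype(float)
        passpc = rng.random(n) < config.pconvert_pass_rate
        data[f"{prefix}_pconvert"] = np.where(passpc, rng.uniform(0.2, 1.0, n),
                                              rng.uniform(0.0, 0.2, n))

    line_freq = {}
    nb_p = config.coverage_shape / (config.coverage_shape + config.coverage_mean)
    for line in config.lines:
        f = config.f_inbred if line.group == "inbred" else config.f_line
        q = _balding_nichols(rng, f, group_freq[line.group])
        line_freq[line.name] = q
        pool_alt = rng.binomial(2 * config.pool_size, q)
        data[f"{line.name}_seg"] = (pool_alt > 0) & (pool_alt < 2 * config.pool_size)
        data[f"{line.name}_maf"] = np.minimum(q, 1 - q)
        data[f"{line.name}_qual"] = np.maximum(
            rng.normal(config.quality_mean, config.quality_sd, n), 0.0)
        data[f"{line.name}_cov"] = rng.negative_binomial(
            config.coverage_shape, nb_p, n).astype(float)

    df = pd.DataFrame(data, columns=_columns_for(config.lines))
    catalog = SnpCatalog(df, config.lines)
    # catalog construction sorts by (chrom, pos); realign truth to it
    order = df.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    truth = CatalogTruth(
        snp_ids=[snp_ids[i] for i in order],
        chroms=[chroms_all[i] for i in order],
        positions=positions[order],
        ancestral=ancestral[order],
        line_freq=pd.DataFrame({k: v[order] for k, v in line_freq.items()}),
        lines=list(config.lines),
    )
    return catalog, truth


def simulate_genotypes(truth: CatalogTruth, line: str, n_samples: int,
                       config: SimConfig, snp_ids: Sequence[str] | None = None,
                       ) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes at the line's latent frequencies, with
    configured genotyping-error and missingness rates."""
    if line not in truth.line_freq.columns:
        raise KeyError(f"line {line!r} not in truth record")
    rng = np.random.default_rng(_line_seed(config, line, 1))
    q, ids, chroms = _subset_freqs(truth, line, snp_ids)
    n_snps = len(q)
    calls = rng.binomial(2, q[None, :].repeat(n_samples, axis=0)).astype(np.int8)
    if config.genotype_error_rate > 0:
        flip = rng.random(calls.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    samples = [f"{line}_s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, ids, calls, [line] * n_samples, chroms)


def _subset_freqs(truth: CatalogTruth, line: str, snp_ids):
    q = truth.line_freq[line].to_numpy()
    if snp_ids is None:
        return q, list(truth.snp_ids), list(truth.chroms)
    index = {s: i for i, s in enumerate(truth.snp_ids)}
    idx = [index[s] for s in snp_ids]
    return q[idx], list(snp_ids), [truth.chroms[i] for i in idx]


#: offspring dosages incompatible with each parent-dosage pair
_INCOMPATIBLE: dict[tuple[int, int], tuple[int, ...]] = {}
for _s in range(3):
    for _d in range(3):
        _alleles = {0: (0,), 1: (0, 1), 2: (1,)}
        _poss = {a + b for a in _alleles[_s] for b in _alleles[_d]}
        _INCOMPATIBLE[(_s, _d)] = tuple(sorted(set(range(3)) - _poss))


def simulate_trios(truth: CatalogTruth, line: str, n_trios: int,
                   config: SimConfig, snp_ids: Sequence[str] | None = None,
                   ) -> tuple[GenotypeMatrix, TrioSet, dict[str, list[int]]]:
    """Trios with Mendelian transmission plus optional injected errors.

    At the injection rate, an offspring call is replaced by a genotype
    incompatible with its parents (chosen uniformly; parent pairs whose
    every offspring genotype is compatible are skipped, as are sex
    chromosomes, which the diploid transmission rules do not cover).
    Returns the matrix (sires, dams, offspring), the trio pedigree and
    the ledger {snp_id: [trio indices injected]}.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = np.random.default_rng(_line_seed(config, line, 2))
    q, ids, chroms = _subset_freqs(truth, line, snp_ids)
    n_snps = len(q)
    sires = rng.binomial(2, q[None, :].repeat(n_trios, axis=0)).astype(np.int8)
    dams = rng.binomial(2, q[None, :].repeat(n_trios, axis=0)).astype(np.int8)
    pat = (rng.random(sires.shape) < sires / 2.0).astype(np.int8)
    mat = (rng.random(dams.shape) < dams / 2.0).astype(np.int8)
    offs = (pat + mat).astype(np.int8)
    ledger: dict[str, list[int]] = {}
    if config.mendel_injection_rate > 0:
        from .validation import SEX_CHROMS

        inject = rng.random(offs.shape) < config.mendel_injection_rate
        inject &= ~np.isin(chroms, list(SEX_CHROMS))[None, :]
        for t, j in zip(*np.nonzero(inject)):
            bad = _INCOMPATIBLE[(int(sires[t, j]), int(dams[t, j]))]
            if not bad:
                continue
            offs[t, j] = bad[rng.integers(0, len(bad))]
            ledger.setdefault(ids[j], []).append(int(t))
    samples, rows = [], []
    trios = []
    for t in range(n_trios):
        s, d, o = f"{line}_sire{t}", f"{line}_dam{t}", f"{line}_off{t}"
        trios.append((s, d, o))
        samples += [s, d, o]
        rows += [sires[t], dams[t], offs[t]]
    matrix = GenotypeMatrix(samples, ids, np.stack(rows),
                            [line] * len(samples), chroms)
    return matrix, TrioSet(trios), ledger


# ---------------------------------------------------------------------
# VCF export of simulated genotypes
# ---------------------------------------------------------------------

def write_genotypes_vcf(matrix: GenotypeMatrix, path,
                        positions: dict[str, tuple[str, int]] | None = None) -> None:
    """Write dosage calls as a minimal VCF with GT fields.

    ``positions`` maps snp_id -> (chrom, pos); without it, ids of the
    form Chr_pos are parsed.
    """
    import pysam

    def locate(sid):
        if positions is not None:
            return positions[sid]
        chrom, _, pos = sid.rpartition("_")
        return chrom, int(pos)

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = []
    for sid in matrix.snp_ids:
        c, _ = locate(sid)
        if c not in chroms:
            chroms.append(c)
    for c in chroms:
        header.contigs.add(c, length=2**29)
    for s in matrix.samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(range(matrix.n_snps),
                       key=lambda j: (locate(matrix.snp_ids[j])))
        for j in order:
            sid = matrix.snp_ids[j]
            chrom, pos = locate(sid)
            rec = out.new_record(contig=chrom, start=pos - 1, stop=pos,
                                 alleles=("A", "C"), id=sid)
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_map[int(matrix.calls[i, j])]
            out.write(rec)
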