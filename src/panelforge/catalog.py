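"""SNP catalog data model and readers/writers.

A catalog holds one row per candidate variant with per-line evidence
(segregation status, folded minor-allele frequency, SNP quality score,
read-pool coverage), global-analysis evidence, prior-panel membership,
array design scores for the forward and reverse probes, and an optional
functional-annotation category.

Coordinates are 1-based and inclusive (VCF convention).  Missing numeric
fields are encoded as "." in the tab-separated dialect; missing is never
conflated with zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("broiler", "WEL", "BEL", "inbred", "experimental")

#: Fixed (non-per-line) catalog columns, in canonical order.
FIXED_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt",
    "global_quality", "global_maf", "in_prior_panel", "coding", "annotation",
    "fwd_16mer", "fwd_pconvert", "rev_16mer", "rev_pconvert",
]

PER_LINE_SUFFIXES = ("seg", "maf", "qual", "cov")


class CatalogError(ValueError):
    """Malformed catalog input."""


@dataclass(frozen=True)
class LineInfo:
    """One sequenced line: its group, role and selection parameters."""

    name: str
    group: str
    commercial: bool = True
    selection_rank: int | None = None
    target_density: float | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise CatalogError(f"unknown group {self.group!r} for line {self.name!r}")


@dataclass(frozen=True)
class SnpRecord:
    """One candidate variant with all evidence attached (a row view)."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    per_line: Mapping[str, dict]
    global_quality: float | None
    global_maf: float | None
    in_prior_panel: bool
    design: Mapping[str, dict]
    annotation: str | None
    coding: bool


def _check_lines(lines: Sequence[LineInfo]) -> None:
    names = [l.name for l in lines]
    if len(set(names)) != len(names):
        raise CatalogError("duplicate line names in registry")
    ranks = [l.selection_rank for l in lines if l.target_density is not None
             and l.selection_rank is not None]
    if len(set(ranks)) != len(ranks):
        raise CatalogError("selection_rank must be unique among filled lines")


class SnpCatalog:
    """A sorted table of candidate SNPs plus the line registry.

    Internally a pandas DataFrame with the canonical columns; rows are
    always kept sorted by (chrom, pos).  Filter and selection operations
    treat the frame as read-only and return new catalogs.
    """

    def __init__(self, df: pd.DataFrame, lines: Sequence[LineInfo]):
        _check_lines(lines)
        self.lines: list[LineInfo] = list(lines)
        missing = [c for c in FIXED_COLUMNS if c not in df.columns]
        if missing:
            raise CatalogError(f"catalog missing columns: {missing}")
        for line in self.lines:
            for suf in PER_LINE_SUFFIXES:
                col = f"{line.name}_{suf}"
                if col not in df.columns:
                    raise CatalogError(f"catalog missing per-line column {col}")
        if len(df) and (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise CatalogError(f"position < 1 (1-based convention) at row {bad}")
        for col in ["global_maf"] + [f"{l.name}_maf" for l in self.lines]:
            vals = df[col]
            if len(df) and (vals.dropna() > 0.5).any():
                raise CatalogError(f"{col} above 0.5: MAF must be folded")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        # annotation is an optional category: normalise missing to None
        df["annotation"] = df["annotation"].astype(object).where(
            df["annotation"].notna(), None)
        if len(df) and df.duplicated(["chrom", "pos", "alt"]).any():
            raise CatalogError("duplicate (chrom, pos, alt) records")
        self.df = df

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpCatalog):
            return NotImplemented
        if self.lines != other.lines:
            return False
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_dtype=False)
        except AssertionError:
            return False
        return True

    def line_names(self) -> list[str]:
        return [l.name for l in self.lines]

    def lines_in_group(self, *groups: str) -> list[str]:
        return [l.name for l in self.lines if l.group in groups]

    def seg_matrix(self) -> np.ndarray:
        """Boolean (n_snps, n_lines) segregation matrix, line order = registry."""
        cols = [f"{n}_seg" for n in self.line_names()]
        return self.df[cols].to_numpy(dtype=bool)

    def record(self, i: int) -> SnpRecord:
        row = self.df.iloc[i]
        per_line = {}
        for name in self.line_names():
            per_line[name] = {
                "segregating": bool(row[f"{name}_seg"]),
                "maf": _opt(row[f"{name}_maf"]),
                "quality": _opt(row[f"{name}_qual"]),
                "coverage": _opt(row[f"{name}_cov"]),
            }
        design = {
            "forward": {"kmer16_count": _opt(row["fwd_16mer"]),
                        "p_convert": _opt(row["fwd_pconvert"])},
            "reverse": {"kmer16_count": _opt(row["rev_16mer"]),
                        "p_convert": _opt(row["rev_pconvert"])},
        }
        ann = row["annotation"]
        return SnpRecord(
            snp_id=row["snp_id"], chrom=row["chrom"], pos=int(row["pos"]),
            ref_allele=row["ref"], alt_allele=row["alt"], per_line=per_line,
            global_quality=_opt(row["global_quality"]),
            global_maf=_opt(row["global_maf"]),
            in_prior_panel=bool(row["in_prior_panel"]),
            design=design, annotation=None if pd.isna(ann) else ann,
            coding=bool(row["coding"]),
        )

    def __iter__(self):
        return (self.record(i) for i in range(len(self)))

    def subset(self, mask) -> "SnpCatalog":
        """New catalog with rows where ``mask`` is true; order preserved."""
        return SnpCatalog(self.df.loc[np.asarray(mask, dtype=bool)]
                          .reset_index(drop=True), self.lines)


def _opt(v):
    return None if pd.isna(v) else float(v)


def segregation_set(record: SnpRecord) -> set[str]:
    """Names of lines in which the record segregates."""
    return {name for name, ev in record.per_line.items() if ev["segregating"]}


# ---------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------

def _columns_for(lines: Sequence[LineInfo]) -> list[str]:
    cols = list(FIXED_COLUMNS)
    for line in lines:
        cols += [f"{line.name}_{s}" for s in PER_LINE_SUFFIXES]
    return cols


_BOOL_COLS = ("in_prior_panel", "coding")


def read_catalog(path, line_config: Sequence[LineInfo]) -> SnpCatalog:
    """Read the canonical tab-separated catalog dialect.

    Unknown columns are ignored with a warning; per-line columns that do
    not match a registered line are an error.
    """
    _check_lines(line_config)
    expected = set(_columns_for(line_config))
    header = pd.read_csv(path, sep="\t", nrows=0, comment="#")
    known_suffix = tuple(f"_{s}" for s in PER_LINE_SUFFIXES)
    for col in header.columns:
        if col in expected:
            continue
        if col.endswith(known_suffix) and col not in expected:
            raise CatalogError(f"per-line column {col!r} names an unregistered line")
        warnings.warn(f"ignoring unknown catalog column {col!r}")
    usecols = [c for c in header.columns if c in expected]
    missing = expected - set(usecols)
    if missing:
        raise CatalogError(f"catalog header missing columns: {sorted(missing)}")
    df = pd.read_csv(path, sep="\t", usecols=usecols, na_values=["."],
                     keep_default_na=False, comment="#",
                     dtype={"snp_id": str, "chrom": str, "ref": str, "alt": str,
                            "annotation": str})
    df = df[_columns_for(line_config)]
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        bad = df.index[pd.to_numeric(df["pos"], errors="coerce").isna()]
        lineno = (bad[0] + 2) if len(bad) else "?"
        raise CatalogError(f"malformed pos at file line {lineno}: {exc}") from exc
    for col in _BOOL_COLS + tuple(f"{l.name}_seg" for l in line_config):
        try:
            df[col] = df[col].astype(np.int64).astype(bool)
        except (ValueError, TypeError) as exc:
            raise CatalogError(f"malformed boolean column {col}: {exc}") from exc
    if (df["pos"] < 1).any():
        lineno = int(df.index[df["pos"] < 1][0]) + 2
        raise CatalogError(f"pos < 1 at file line {lineno} (positions are 1-based)")
    return SnpCatalog(df, line_config)


def write_catalog(catalog: SnpCatalog, path) -> None:
    """Write the canonical dialect; read(write(c)) == c field-for-field."""
    df = catalog.df.copy()
    for col in _BOOL_COLS + tuple(f"{l.name}_seg" for l in catalog.lines):
        df[col] = df[col].astype(int)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "."
    if isinstance(v, float):
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    if isinstance(v, (np.integer, int)):
        return str(int(v))
    return str(v) if str(v) != "" and not pd.isna(v) else "."


# ---------------------------------------------------------------------
# VCF import and panel export
# ---------------------------------------------------------------------

def read_catalog_vcf(path, line_config: Sequence[LineInfo]) -> SnpCatalog:
    """Import catalog rows from a VCF.

    Per-line evidence is read from INFO keys SEG_<line>, MAF_<line>,
    QUAL_<line> and COV_<line>; global quality from the QUAL column;
    global MAF from INFO/GMAF; prior-panel and coding status from the
    PRIOR and CODING flags; design scores from FWD16/FWDPC/REV16/REVPC;
    annotation category from ANN.
    """
    import pysam

    _check_lines(line_config)
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            row = {
                "snp_id": rec.id or f"{rec.chrom}_{rec.pos}",
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0] if rec.alts else ".",
                "global_quality": rec.qual if rec.qual is not None else np.nan,
                "global_maf": _info_num(info, "GMAF"),
                "in_prior_panel": bool(info.get("PRIOR", False)),
                "coding": bool(info.get("CODING", False)),
                "annotation": info.get("ANN", None),
                "fwd_16mer": _info_num(info, "FWD16"),
                "fwd_pconvert": _info_num(info, "FWDPC"),
                "rev_16mer": _info_num(info, "REV16"),
                "rev_pconvert": _info_num(info, "REVPC"),
            }
            for line in line_config:
                row[f"{line.name}_seg"] = bool(info.get(f"SEG_{line.name}", False))
                row[f"{line.name}_maf"] = _info_num(info, f"MAF_{line.name}")
                row[f"{line.name}_qual"] = _info_num(info, f"QUAL_{line.name}")
                row[f"{line.name}_cov"] = _info_num(info, f"COV_{line.name}")
            rows.append(row)
    df = pd.DataFrame(rows, columns=_columns_for(line_config))
    if not len(df):
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in _columns_for(line_config)})
        df["pos"] = df["pos"].astype(np.int64)
    return SnpCatalog(df, line_config)


def _info_num(info, key):
    v = info.get(key, None)
    if v is None:
        return np.nan
    if isinstance(v, tuple):
        v = v[0]
    return float(v)


@dataclass
class PanelSelection:
    """The selected SNP set with per-SNP provenance.

    Provenance records which pass placed each SNP: one of backbone_all,
    backbone_inbred, backbone_layer, backbone_broiler, coding, or
    line:<name> for gap-filling placements.
    """

    snp_ids: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, snp_id: str, source: str) -> None:
        if snp_id not in self.provenance:
            self.snp_ids.append(snp_id)
        self.provenance[snp_id] = source

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.provenance

    def to_frame(self, catalog: SnpCatalog) -> pd.DataFrame:
        """Panel as a (chrom,pos)-sorted frame with provenance attached."""
        unknown = set(self.snp_ids) - set(catalog.df["snp_id"])
        if unknown:
            raise CatalogError(f"panel ids not in catalog: {sorted(unknown)[:5]} ...")
        sub = catalog.df[catalog.df["snp_id"].isin(set(self.snp_ids))]
        out = sub[["snp_id", "chrom", "pos"]].copy()
        out["provenance"] = out["snp_id"].map(self.provenance)
        return out.reset_index(drop=True)


def write_panel(panel: PanelSelection, catalog: SnpCatalog, path) -> None:
    panel.to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_panel(path) -> PanelSelection:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"snp_id": str, "chrom": str})
    out = PanelSelection()
    for sid, prov in zip(df["snp_id"], df["provenance"]):
        out.add(sid, prov)
    return out


def write_panel_bed(panel: PanelSelection, catalog: SnpCatalog, path) -> None:
    """Panel as BED (0-based half-open) for genome-browser use."""
    frame = panel.to_frame(catalog)
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.snp_id}\n")
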