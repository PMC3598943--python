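"""Shared fixtures and catalog builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelforge.catalog import LineInfo, SnpCatalog, _columns_for
from panelforge.genmap import GeneticMap


def make_lines(*specs) -> list[LineInfo]:
    """specs: (name, group[, commercial, rank, density]) tuples."""
    out = []
    for s in specs:
        out.append(LineInfo(*s))
    return out


TRI_LINES = make_lines(
    ("B1", "broiler", True, 2, None),
    ("WEL1", "WEL", True, 0, None),
    ("I1", "inbred", False, None, None),
)


def make_catalog(rows, lines=None) -> SnpCatalog:
    """Build a catalog from row dicts with sensible defaults.

    Each row needs chrom and pos; everything else defaults to a record
    that passes every filter (design scores 50/0.5 both strands, no
    global evidence, not prior-panel, segregating nowhere).  Per-line
    fields are given as e.g. {"B1": {"seg": True, "qual": 70, "maf": 0.2,
    "cov": 10}}.
    """
    lines = lines if lines is not None else TRI_LINES
    recs = []
    for i, row in enumerate(rows):
        rec = {
            "snp_id": row.get("snp_id", f"s{i}"),
            "chrom": row["chrom"], "pos": row["pos"],
            "ref": row.get("ref", "A"), "alt": row.get("alt", "C"),
            "global_quality": row.get("global_quality", np.nan),
            "global_maf": row.get("global_maf", np.nan),
            "in_prior_panel": row.get("in_prior_panel", False),
            "coding": row.get("coding", False),
            "annotation": row.get("annotation", None),
            "fwd_16mer": row.get("fwd_16mer", 50.0),
            "fwd_pconvert": row.get("fwd_pconvert", 0.5),
            "rev_16mer": row.get("rev_16mer", 50.0),
            "rev_pconvert": row.get("rev_pconvert", 0.5),
        }
        for line in lines:
            per = row.get(line.name, {})
            rec[f"{line.name}_seg"] = per.get("seg", False)
            rec[f"{line.name}_maf"] = per.get("maf", np.nan)
            rec[f"{line.name}_qual"] = per.get("qual", np.nan)
            rec[f"{line.name}_cov"] = per.get("cov", np.nan)
        recs.append(rec)
    df = pd.DataFrame(recs, columns=_columns_for(lines))
    if not recs:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in _columns_for(lines)})
        df["pos"] = df["pos"].astype(np.int64)
    return SnpCatalog(df, lines)


@pytest.fixture
def tri_lines():
    return TRI_LINES


@pytest.fixture
def simple_map() -> GeneticMap:
    return GeneticMap({
        "Chr1": (np.array([1, 1_000_001]), np.array([0.0, 3.0])),
        "Chr2": (np.array([1, 500_001, 1_000_001]), np.array([0.0, 1.0, 5.0])),
    })
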