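"""Genetic map: bp <-> cM conversion per chromosome.

Panel evenness is measured in genetic-map distance rather than physical
distance, so that micro-chromosomes (high cM/Mb) receive proportionally
more markers per Mb than macro-chromosomes.  The map is an anchor table
of (bp, cM) pairs per chromosome, strictly increasing in both
coordinates; positions between anchors are linearly interpolated and
positions outside the anchor range are extrapolated at the terminal
interval's rate, floored at 0 cM.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class MapError(ValueError):
    pass


class GeneticMap:
    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or len(bp) < 1:
                raise MapError(f"{chrom}: anchors must be parallel non-empty arrays")
            if len(bp) == 1:
                warnings.warn(f"{chrom}: single-anchor chromosome, map length 0")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise MapError(f"{chrom}: anchors must be strictly increasing in bp and cM")
            if np.any(cm < 0):
                raise MapError(f"{chrom}: negative cM anchor")
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._anchors

    def _get(self, chrom: str):
        try:
            return self._anchors[chrom]
        except KeyError:
            raise MapError(f"chromosome {chrom!r} not in genetic map") from None

    def interpolate_cm(self, chrom: str, pos) -> float | np.ndarray:
        """cM position(s) for 1-based bp position(s) on ``chrom``.

        Linear between anchors; beyond the anchor range, linear at the
        terminal interval's cM/bp rate, floored at 0 cM.
        """
        bp, cm = self._get(chrom)
        p = np.asarray(pos, dtype=float)
        if len(bp) == 1:
            out = np.full_like(p, cm[0])
            return float(out) if np.isscalar(pos) else out
        out = np.interp(p, bp, cm)
        lo = p < bp[0]
        hi = p > bp[-1]
        if np.any(lo):
            rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
            out = np.where(lo, cm[0] + (p - bp[0]) * rate, out)
        if np.any(hi):
            rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            out = np.where(hi, cm[-1] + (p - bp[-1]) * rate, out)
        out = np.maximum(out, 0.0)
        return float(out) if np.isscalar(pos) else out

    def map_length_cm(self, chrom: str) -> float:
        """Map length: last anchor cM minus first anchor cM."""
        bp, cm = self._get(chrom)
        return float(cm[-1] - cm[0])

    def bounds_cm(self, chrom: str) -> tuple[float, float]:
        """(first, last) anchor cM — virtual segment boundaries."""
        bp, cm = self._get(chrom)
        return float(cm[0]), float(cm[-1])

    def total_length_cm(self, chroms=None) -> float:
        chroms = self.chromosomes if chroms is None else chroms
        return float(sum(self.map_length_cm(c) for c in chroms))

    def interval_rates(self) -> pd.DataFrame:
        """cM/Mb per anchor interval (map-check report)."""
        rows = []
        for chrom, (bp, cm) in self._anchors.items():
            for i in range(len(bp) - 1):
                rows.append({
                    "chrom": chrom, "start_bp": int(bp[i]), "end_bp": int(bp[i + 1]),
                    "cM_per_Mb": (cm[i + 1] - cm[i]) / (bp[i + 1] - bp[i]) * 1e6,
                })
        return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "cM_per_Mb"])


def read_map(path) -> GeneticMap:
    """Read a map TSV with columns chrom, pos_bp, pos_cM.

    Non-monotone anchor input is a hard error, never silently repaired.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "pos_bp", "pos_cM"):
        if col not in df.columns:
            raise MapError(f"map file missing column {col!r}")
    anchors = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        anchors[chrom] = (sub["pos_bp"].to_numpy(), sub["pos_cM"].to_numpy())
    return GeneticMap(anchors)


def write_map(gmap: GeneticMap, path) -> None:
    rows = []
    for chrom in gmap.chromosomes:
        bp, cm = gmap._get(chrom)
        for b, c in zip(bp, cm):
            rows.append((chrom, int(b), c))
    pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"]).to_csv(
        path, sep="\t", index=False)
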