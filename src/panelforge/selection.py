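"""Iterative backbone + gap-filling panel selection.

The selection problem: from a filtered multi-line candidate catalog,
pick a panel of a given size whose markers are spread evenly in
genetic-map (cM) distance *for every line* — a SNP only informs a line
in which it segregates — under a broiler:layer ratio.

The divide-and-conquer strategy first lays down backbones of widely
shared SNPs (segregating in all lines, then in all inbred lines, all
layer lines, all broiler lines), each pass accepting candidates more
than ``t`` bases from every already-accepted SNP on the chromosome.
Backbone SNPs partition each chromosome into short segments.  Then, one
line at a time, every segment bounded by SNPs segregating in that line
is filled with ``n`` further line-segregating SNPs, where ``n`` follows
from the line's target density (SNPs/cM) and the segment length; the
chosen subset minimises the sum of squared consecutive cM gaps
(including the segment bounds), i.e. sits closest to the ideal evenly
spaced positions.  Placements for one line become boundaries for the
next, which keeps SNPs of different lines from crowding together.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import PanelSelection, SnpCatalog
from .genmap import GeneticMap


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    """Parameters of the backbone + gap-filling algorithm.

    t is the minimum backbone spacing in bases (2 kb approximates the
    expected spacing of a 600 K panel on a 1 Gb genome).  Densities are
    SNPs/cM per filled line; when absent they are calibrated against
    ``budget`` with group weights ``group_ratio`` (e.g. broiler 3,
    layer 2 for the final panel; 1:1 for a pre-screening panel).
    """

    t: int = 2000
    budget: int | None = None
    group_ratio: dict[str, float] = field(default_factory=dict)
    line_order: list[str] = field(default_factory=list)
    densities: dict[str, float] | None = None
    coding_ids: set[str] | None = None
    quota_rule: str = "half_up"
    budget_tolerance: float = 0.02
    inbred_any: bool = False

    def __post_init__(self):
        if self.t < 0:
            raise SelectionError("t must be >= 0")
        if self.budget is not None and self.budget <= 0:
            raise SelectionError("budget must be > 0")
        if any(w <= 0 for w in self.group_ratio.values()):
            raise SelectionError("group_ratio weights must be > 0")


@dataclass
class Segment:
    """One inter-boundary interval on a chromosome for one line."""

    chrom: str
    left_cm: float
    right_cm: float
    cand_rows: np.ndarray   # catalog row indices, sorted by (cM, snp_id)
    cand_cm: np.ndarray

    @property
    def length_cm(self) -> float:
        return self.right_cm - self.left_cm


@dataclass
class SelectionState:
    """Bookkeeping across backbone passes and per-line filling."""

    panel: PanelSelection
    selected: np.ndarray          # bool per catalog row
    cm: np.ndarray                # cM per catalog row
    counters: dict[str, int] = field(default_factory=dict)
    F: dict[str, int] = field(default_factory=dict)  # panel SNPs not segregating in line
    S: dict[str, int] = field(default_factory=dict)  # SNPs placed for line

    @property
    def X(self) -> int:
        return len(self.panel)


# ---------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------

def _spaced_accept(accepted: list[int], pos: int, t: int) -> bool:
    """Accept pos iff strictly more than t bases from every accepted."""
    i = bisect.bisect_left(accepted, pos)
    if i > 0 and pos - accepted[i - 1] <= t:
        return False
    if i < len(accepted) and accepted[i] - pos <= t:
        return False
    accepted.insert(i, pos)
    return True


def build_backbones(catalog: SnpCatalog, config: SelectionConfig,
                    gmap: GeneticMap | None = None,
                    coding_ids: set[str] | None = None) -> SelectionState:
    """Run the four backbone passes (+ coding additions in final mode).

    Pass order: SNPs segregating in all lines (N), in all inbred lines
    (I), in all layer lines (L), in all broiler lines (B).  Each pass
    scans positions left to right and accepts a candidate iff it is more
    than t bases from every already-accepted SNP on that chromosome.
    Coding additions (C) bypass the spacing constraint.
    """
    df = catalog.df
    n = len(df)
    cm = np.zeros(n)
    if gmap is not None and n:
        for chrom, idx in df.groupby("chrom", sort=False).indices.items():
            cm[idx] = gmap.interpolate_cm(chrom, df["pos"].to_numpy()[idx])
    state = SelectionState(panel=PanelSelection(), selected=np.zeros(n, dtype=bool), cm=cm)
    if n == 0:
        warnings.warn("empty catalog: empty selection state")
        state.counters = dict.fromkeys("N I I_u L L_u B C".split(), 0)
        return state

    seg = catalog.seg_matrix()
    names = catalog.line_names()
    col = {name: j for j, name in enumerate(names)}

    def group_mask(line_names, require_all=True):
        if not line_names:
            return None
        cols = [col[ln] for ln in line_names]
        return seg[:, cols].all(axis=1) if require_all else seg[:, cols].any(axis=1)

    inbred = catalog.lines_in_group("inbred")
    layers = catalog.lines_in_group("WEL", "BEL")
    broilers = catalog.lines_in_group("broiler")
    commercial = [l.name for l in catalog.lines if l.commercial]

    passes = [
        ("backbone_all", group_mask(names)),
        ("backbone_inbred", group_mask(inbred, require_all=not config.inbred_any)),
        ("backbone_layer", group_mask(layers)),
        ("backbone_broiler", group_mask(broilers)),
    ]

    pos = df["pos"].to_numpy()
    chroms = df["chrom"].to_numpy()
    ids = df["snp_id"].to_numpy()
    accepted: dict[str, list[int]] = {}
    pass_counts: dict[str, int] = {}
    broiler_any = group_mask(broilers, require_all=False)
    commercial_any = group_mask(commercial, require_all=False)
    i_u = l_u = 0
    for source, mask in passes:
        count = 0
        if mask is not None:
            for i in np.flatnonzero(mask & ~state.selected):
                acc = accepted.setdefault(chroms[i], [])
                if _spaced_accept(acc, int(pos[i]), config.t):
                    state.panel.add(ids[i], source)
                    state.selected[i] = True
                    count += 1
                    if source == "backbone_inbred" and commercial_any is not None \
                            and not commercial_any[i]:
                        i_u += 1
                    if source == "backbone_layer" and broiler_any is not None \
                            and not broiler_any[i]:
                        l_u += 1
        pass_counts[source] = count

    c_count = 0
    if coding_ids:
        for i in np.flatnonzero(np.isin(ids, list(coding_ids)) & ~state.selected):
            state.panel.add(ids[i], "coding")
            state.selected[i] = True
            c_count += 1

    state.counters = {
        "N": pass_counts["backbone_all"], "I": pass_counts["backbone_inbred"],
        "I_u": i_u, "L": pass_counts["backbone_layer"], "L_u": l_u,
        "B": pass_counts["backbone_broiler"], "C": c_count,
    }
    return state


# ---------------------------------------------------------------------
# Segments and quotas
# ---------------------------------------------------------------------

def segments_for_line(state: SelectionState, line: str, catalog: SnpCatalog,
                      gmap: GeneticMap) -> list[Segment]:
    """Segments for one line: per chromosome, the boundaries are the
    panel SNPs segregating in the line (in cM) plus the chromosome's
    map ends; candidates are line-segregating, unselected SNPs strictly
    inside each segment."""
    df = catalog.df
    seg_col = df[f"{line}_seg"].to_numpy(dtype=bool)
    segments: list[Segment] = []
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        if chrom not in gmap:
            raise SelectionError(f"chromosome {chrom!r} missing from genetic map")
        lo, hi = gmap.bounds_cm(chrom)
        sel = state.selected[idx] & seg_col[idx]
        bound_cm = np.sort(state.cm[idx][sel])
        lo = min(lo, bound_cm[0]) if len(bound_cm) else lo
        hi = max(hi, bound_cm[-1]) if len(bound_cm) else hi
        bounds = np.concatenate([[lo], bound_cm, [hi]])
        cand = idx[seg_col[idx] & ~state.selected[idx]]
        # catalog rows are position-sorted and the map is monotone, so
        # candidate cM values are already non-decreasing
        ccm = state.cm[cand]
        for b in range(len(bounds) - 1):
            left, right = float(bounds[b]), float(bounds[b + 1])
            i0 = np.searchsorted(ccm, left, side="right")
            i1 = np.searchsorted(ccm, right, side="left")
            segments.append(Segment(chrom, left, right, cand[i0:i1], ccm[i0:i1]))
    return segments


def compute_segment_quota(length_cm: float, density: float,
                          quota_rule: str = "half_up") -> int:
    """Number of SNPs a segment should receive.

    Zero when the segment is shorter than one inter-marker interval at
    the target density (1/density cM); otherwise length*density rounded
    half-up."""
    if density <= 0:
        raise SelectionError("density must be > 0")
    if quota_rule != "half_up":
        raise SelectionError(f"unknown quota_rule {quota_rule!r}")
    v = length_cm * density
    if v < 1.0 - 1e-9:
        return 0
    return int(np.floor(v + 0.5))


# ---------------------------------------------------------------------
# Segment filling (dynamic programme)
# ---------------------------------------------------------------------

def choose_even_positions(x: np.ndarray, a: float, b: float, n: int) -> list[int]:
    """Indices of the size-n subset of sorted positions ``x`` in (a, b)
    minimising sum_{j=0..n} (x_{j+1}-x_j)^2 with x_0=a, x_{n+1}=b.

    Dynamic programme over (candidate, count), O(m^2 n).  Ties resolved
    to the lexicographically smallest index tuple (x is sorted, so that
    is the smallest position tuple)."""
    m = len(x)
    if n >= m:
        return list(range(m))
    if n == 0:
        return []
    x = np.asarray(x, dtype=float)
    INF = np.inf
    # g[k][j]: min cost from x_j (the k-th chosen) through the remaining
    # n-k chosen to b
    g = np.full((n + 1, m), INF)
    g[n] = (b - x) ** 2
    for k in range(n - 1, 0, -1):
        for j in range(m - 1, -1, -1):
            if j + 1 < m:
                d = x[j + 1:] - x[j]
                g[k][j] = np.min(d * d + g[k + 1][j + 1:])
    start = (x - a) ** 2 + g[1]
    best = float(np.min(start))
    tol = 1e-9 * max(1.0, abs(best))
    chosen: list[int] = []
    prev_pos, prev_j, acc = a, -1, 0.0
    for k in range(1, n + 1):
        for j in range(prev_j + 1, m):
            step = (x[j] - prev_pos) ** 2
            if acc + step + g[k][j] <= best + tol:
                chosen.append(j)
                acc += step
                prev_pos, prev_j = x[j], j
                break
        else:  # numeric safety net; cannot occur for consistent g
            raise SelectionError("segment fill reconstruction failed")
    return chosen


def fill_segment(segment: Segment, n: int) -> np.ndarray:
    """Catalog row indices of the candidates chosen for a segment."""
    if n <= 0 or len(segment.cand_rows) == 0:
        return segment.cand_rows[:0]
    idx = choose_even_positions(segment.cand_cm, segment.left_cm,
                                segment.right_cm, n)
    return segment.cand_rows[idx]


# ---------------------------------------------------------------------
# Whole-panel selection
# ---------------------------------------------------------------------

def select_panel(catalog: SnpCatalog, config: SelectionConfig, gmap: GeneticMap,
                 mode: str = "prescreen",
                 ) -> tuple[PanelSelection, SelectionState]:
    """Backbones, then per-line gap filling in config.line_order.

    In "final" mode all coding SNPs (config.coding_ids, defaulting to
    the catalog's coding flag) join the backbone without a spacing
    constraint.  Deterministic for identical inputs."""
    if mode not in ("prescreen", "final"):
        raise SelectionError(f"unknown mode {mode!r}")
    densities = config.densities
    if densities is None:
        if config.budget is None:
            raise SelectionError("either densities or a budget must be given")
        densities = calibrate_densities(catalog, config, gmap, mode=mode)
    missing = [ln for ln in config.line_order if ln not in densities]
    if missing:
        raise SelectionError(f"no density for lines {missing}")
    if config.budget is not None and config.budget > len(catalog):
        warnings.warn("budget exceeds candidate count: selecting all candidates")

    coding_ids = None
    if mode == "final":
        coding_ids = config.coding_ids
        if coding_ids is None:
            df = catalog.df
            coding_ids = set(df.loc[df["coding"].astype(bool), "snp_id"])
    state = build_backbones(catalog, config, gmap, coding_ids=coding_ids)
    ids = catalog.df["snp_id"].to_numpy()
    seg = catalog.seg_matrix()
    col = {name: j for j, name in enumerate(catalog.line_names())}
    for line in config.line_order:
        if line not in col:
            raise SelectionError(f"line {line!r} not in catalog registry")
        state.F[line] = int((~seg[state.selected][:, col[line]]).sum())
        placed = 0
        for segment in segments_for_line(state, line, catalog, gmap):
            n = compute_segment_quota(segment.length_cm, densities[line],
                                      config.quota_rule)
            if n == 0:
                continue
            rows = fill_segment(segment, n)
            for i in rows:
                state.panel.add(ids[i], f"line:{line}")
                state.selected[i] = True
            placed += len(rows)
        state.S[line] = placed
    return state.panel, state


def calibrate_densities(catalog: SnpCatalog, config: SelectionConfig,
                        gmap: GeneticMap, mode: str = "prescreen",
                        max_iter: int = 60) -> dict[str, float]:
    """Find per-line densities d_i = s * w_group(i) / (lines in group *
    total map length) with the scalar s bisected so the final panel size
    lands within budget*(1 +/- budget_tolerance).

    Panel size is non-decreasing in s (asserted while bracketing).  In
    the saturated regime (budget at or above the candidate supply) the
    full candidate list is returned with a warning."""
    if config.budget is None:
        raise SelectionError("calibration requires a budget")
    if not config.line_order:
        raise SelectionError("calibration requires a non-empty line_order")
    group_of = {l.name: l.group for l in catalog.lines}
    filled_groups: dict[str, int] = {}
    for ln in config.line_order:
        filled_groups[group_of[ln]] = filled_groups.get(group_of[ln], 0) + 1
    ratio = config.group_ratio or {g: 1.0 for g in filled_groups}
    for g in filled_groups:
        if g not in ratio:
            raise SelectionError(f"group_ratio missing weight for group {g!r}")
    chroms = [c for c in catalog.df["chrom"].unique()]
    total_cm = gmap.total_length_cm(chroms)
    if total_cm <= 0:
        raise SelectionError("total map length is zero")
    base = {ln: ratio[group_of[ln]] / (filled_groups[group_of[ln]] * total_cm)
            for ln in config.line_order}

    history: list[tuple[float, int]] = []

    def panel_size(s: float) -> int:
        dens = {ln: s * b for ln, b in base.items()}
        cfg = SelectionConfig(
            t=config.t, budget=None, group_ratio=config.group_ratio,
            line_order=config.line_order, densities=dens,
            coding_ids=config.coding_ids, quota_rule=config.quota_rule,
            inbred_any=config.inbred_any)
        panel, _ = select_panel(catalog, cfg, gmap, mode=mode)
        history.append((s, len(panel)))
        return len(panel)

    budget, tol = config.budget, config.budget_tolerance
    lo_ok = lambda size: size <= budget * (1 + tol)
    hit = lambda size: abs(size - budget) <= tol * budget

    s = max(budget, 1) / sum(ratio[g] for g in filled_groups)
    size = panel_size(s)
    if hit(size):
        return {ln: s * b for ln, b in base.items()}
    if size < budget:
        s_lo, size_lo = s, size
        s_hi = s * 2
        size_hi = panel_size(s_hi)
        tries = 0
        while size_hi < budget * (1 - tol) and tries < max_iter:
            if size_hi < size_lo:
                raise SelectionError(f"panel size not monotone in density scale: {history}")
            if size_hi == size_lo and size_hi >= len(catalog):
                warnings.warn("budget infeasible: densities saturate the candidate supply")
                return {ln: s_hi * b for ln, b in base.items()}
            s_lo, size_lo = s_hi, size_hi
            s_hi *= 2
            size_hi = panel_size(s_hi)
            tries += 1
        if size_hi < budget * (1 - tol):
            warnings.warn("budget infeasible: densities saturate the candidate supply")
            return {ln: s_hi * b for ln, b in base.items()}
    else:
        s_hi, size_hi = s, size
        # at a vanishing scale every quota is zero: the panel reduces to
        # the backbone floor, which bounds the achievable minimum
        s_floor = s * 1e-12
        floor_size = panel_size(s_floor)
        if floor_size > budget * (1 + tol):
            raise SelectionError(
                f"backbone alone holds {floor_size} SNPs, above the budget "
                f"{budget} (tolerance {tol}); increase t or the budget "
                f"(t ~ genome length / budget). Evaluated (s, size): "
                f"{history[:3]} ... {history[-1]}")
        if floor_size > size_hi:
            raise SelectionError(f"panel size not monotone in density scale: {history}")
        s_lo, size_lo = s_floor, floor_size
    if hit(size_lo):
        return {ln: s_lo * b for ln, b in base.items()}
    if hit(size_hi):
        return {ln: s_hi * b for ln, b in base.items()}
    for _ in range(max_iter):
        s_mid = 0.5 * (s_lo + s_hi)
        size_mid = panel_size(s_mid)
        if hit(size_mid):
            return {ln: s_mid * b for ln, b in base.items()}
        if size_mid < budget:
            s_lo, size_lo = s_mid, size_mid
        else:
            s_hi, size_hi = s_mid, size_mid
    raise SelectionError(
        f"calibration did not converge within {max_iter} bisections; "
        f"evaluated (s, size): {history}")
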