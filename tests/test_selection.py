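"""Backbone construction, segment quotas and the gap-filling DP."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelforge.catalog import LineInfo
from panelforge.genmap import GeneticMap
from panelforge.selection import (SelectionConfig, build_backbones,
                                  calibrate_densities, choose_even_positions,
                                  compute_segment_quota, fill_segment,
                                  segments_for_line, select_panel)

from conftest import make_catalog, make_lines


def flat_map(length_bp=1_000_000, cm=10.0, chroms=("Chr1",)):
    return GeneticMap({c: (np.array([1.0, length_bp]), np.array([0.0, cm]))
                       for c in chroms})


ONE_LINE = make_lines(("B1", "broiler", True, 0, None))


def one_line_catalog(positions, chrom="Chr1"):
    return make_catalog([{"chrom": chrom, "pos": p, "B1": {"seg": True}}
                         for p in positions], lines=ONE_LINE)


# -- backbones --------------------------------------------------------

def test_backbone_greedy_spacing():
    cat = one_line_catalog([1000, 2000, 4000, 7000, 8000])
    state = build_backbones(cat, SelectionConfig(t=2000), flat_map())
    chosen = sorted(cat.df.loc[state.selected, "pos"])
    assert chosen == [1000, 4000, 7000]
    # with one line, "all lines" is the first pass to see these SNPs
    assert state.counters["N"] == 3
    assert state.counters["B"] == 0


def test_backbone_pass_order_and_counters():
    lines = make_lines(("B1", "broiler", True, 0, None),
                       ("WEL1", "WEL", True, 1, None),
                       ("I1", "inbred", False, None, None))
    rows = [
        # segregates everywhere -> backbone_all
        {"chrom": "Chr1", "pos": 1000, "snp_id": "all1",
         "B1": {"seg": True}, "WEL1": {"seg": True}, "I1": {"seg": True}},
        # inbred only -> backbone_inbred, unique to inbred (I_u)
        {"chrom": "Chr1", "pos": 10_000, "snp_id": "inb1", "I1": {"seg": True}},
        # all layers, no broiler -> backbone_layer and L_u
        {"chrom": "Chr1", "pos": 20_000, "snp_id": "lay1", "WEL1": {"seg": True}},
        # all broilers -> backbone_broiler
        {"chrom": "Chr1", "pos": 30_000, "snp_id": "bro1", "B1": {"seg": True}},
        # too close to all1 for any pass
        {"chrom": "Chr1", "pos": 1500, "snp_id": "near", "B1": {"seg": True}},
    ]
    cat = make_catalog(rows, lines=lines)
    state = build_backbones(cat, SelectionConfig(t=2000), flat_map())
    assert state.counters == {"N": 1, "I": 1, "I_u": 1, "L": 1, "L_u": 1,
                              "B": 1, "C": 0}
    assert state.panel.provenance["all1"] == "backbone_all"
    assert state.panel.provenance["inb1"] == "backbone_inbred"
    assert "near" not in state.panel


def test_coding_added_without_spacing():
    cat = one_line_catalog([1000, 1003])
    cat.df.loc[cat.df["pos"] == 1003, "coding"] = True
    state = build_backbones(cat, SelectionConfig(t=2000), flat_map(),
                            coding_ids={"s1"})
    assert set(state.panel.snp_ids) == {"s0", "s1"}
    assert state.panel.provenance["s1"] == "coding"
    assert state.counters["C"] == 1


def test_empty_catalog_empty_state():
    cat = make_catalog([], lines=ONE_LINE)
    with pytest.warns(UserWarning, match="empty"):
        state = build_backbones(cat, SelectionConfig(), flat_map())
    assert state.X == 0


# -- segments ---------------------------------------------------------

def test_segment_counts_are_boundaries_plus_one():
    cat = one_line_catalog([100_000, 500_000, 900_000, 300_000, 700_000])
    gmap = flat_map()
    state = build_backbones(cat, SelectionConfig(t=10**9), gmap)  # one backbone SNP
    assert state.X == 1
    segs = segments_for_line(state, "B1", cat, gmap)
    assert len(segs) == 2  # k=1 boundary SNP -> 2 segments
    state.selected[:] = False
    state.panel.snp_ids.clear(); state.panel.provenance.clear()
    segs = segments_for_line(state, "B1", cat, gmap)
    assert len(segs) == 1 and segs[0].length_cm == pytest.approx(10.0)


def test_candidates_at_boundary_excluded():
    cat = one_line_catalog([100_000, 500_000, 500_001, 900_000])
    gmap = GeneticMap({"Chr1": (np.array([1.0, 1_000_000]),
                                np.array([0.0, 10.0]))})
    state = build_backbones(cat, SelectionConfig(t=300_000), gmap)
    segs = segments_for_line(state, "B1", cat, gmap)
    for seg in segs:
        assert np.all(seg.cand_cm > seg.left_cm)
        assert np.all(seg.cand_cm < seg.right_cm)


# -- quotas -----------------------------------------------------------

@pytest.mark.parametrize("length, d, expected", [
    (0.4, 1.0, 0),     # gap smaller than target spacing
    (3.7, 2.0, 7),     # round half up of 7.4
    (0.5, 2.0, 1),     # exactly 1/d
    (0.75, 2.0, 2),    # 1.5 rounds half up
    (0.0, 5.0, 0),
])
def test_segment_quota(length, d, expected):
    assert compute_segment_quota(length, d) == expected


# -- DP fill ----------------------------------------------------------

def brute_force_fill(x, a, b, n):
    """Exhaustive minimisation of the squared-gap objective."""
    if n >= len(x):
        return list(range(len(x))), None
    best_cost, best = np.inf, None
    for combo in itertools.combinations(range(len(x)), n):
        pts = [a] + [x[i] for i in combo] + [b]
        cost = sum((q - p) ** 2 for p, q in zip(pts, pts[1:]))
        if cost < best_cost - 1e-12:
            best_cost, best = cost, combo
    return list(best), best_cost


def test_fill_midpoint_forced():
    x = np.array([1.0, 2, 5, 8, 9])
    assert choose_even_positions(x, 0, 10, 1) == [2]  # position 5


def test_fill_tie_breaks_lexicographically():
    x = np.array([1.0, 2, 5, 8, 9])
    # {2,5} and {5,8} both cost 38; smallest position tuple wins
    assert [x[i] for i in choose_even_positions(x, 0, 10, 2)] == [2, 5]


def test_fill_saturation_returns_all():
    x = np.array([1.0, 2, 5, 8, 9])
    assert choose_even_positions(x, 0, 10, 5) == [0, 1, 2, 3, 4]
    assert choose_even_positions(x, 0, 10, 9) == [0, 1, 2, 3, 4]


@settings(deadline=None, derandomize=True, max_examples=120)
@given(st.lists(st.floats(0.01, 9.99), min_size=1, max_size=12, unique=True),
       st.integers(1, 5))
def test_fill_matches_bruteforce(cands, n):
    x = np.array(sorted(cands))
    got = choose_even_positions(x, 0.0, 10.0, n)
    want, want_cost = brute_force_fill(list(x), 0.0, 10.0, n)
    if want_cost is None:
        assert got == want
    else:
        pts = [0.0] + [x[i] for i in got] + [10.0]
        got_cost = sum((q - p) ** 2 for p, q in zip(pts, pts[1:]))
        assert got_cost == pytest.approx(want_cost, rel=1e-9)


# -- whole selection --------------------------------------------------

def uniform_catalog(n, lines, seed, length=1_000_000, seg_prob=1.0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(10, length), size=n, replace=False))
    rows = []
    for p in pos:
        rows.append({"chrom": "Chr1", "pos": int(p),
                     **{l.name: {"seg": bool(rng.random() < seg_prob)}
                        for l in lines}})
    return make_catalog(rows, lines=lines)


def test_select_empty_line_order_is_backbones_only():
    cat = one_line_catalog([1000, 5000, 9000])
    cfg = SelectionConfig(t=2000, densities={}, line_order=[])
    panel, state = select_panel(cat, cfg, flat_map())
    assert all(v.startswith("backbone") for v in panel.provenance.values())


def test_second_identical_line_places_nothing_more():
    lines = make_lines(("WEL1", "WEL", True, 0, None), ("WEL2", "WEL", True, 1, None))
    cat = uniform_catalog(200, lines, seed=1)
    cfg = SelectionConfig(t=10**9, densities={"WEL1": 2.0, "WEL2": 2.0},
                          line_order=["WEL1", "WEL2"])
    panel, state = select_panel(cat, cfg, flat_map())
    assert state.S["WEL1"] > 0
    # the first line's placements already roughly satisfy the shared
    # density, so the second pass only tops up long-ish gaps
    assert state.S["WEL2"] < state.S["WEL1"]


def test_selection_deterministic():
    lines = make_lines(("B1", "broiler", True, 0, None), ("WEL1", "WEL", True, 1, None))
    cat = uniform_catalog(300, lines, seed=2, seg_prob=0.8)
    cfg = SelectionConfig(t=50_000, densities={"B1": 1.5, "WEL1": 1.0},
                          line_order=["WEL1", "B1"])
    p1, s1 = select_panel(cat, cfg, flat_map())
    p2, s2 = select_panel(cat, cfg, flat_map())
    assert p1.snp_ids == p2.snp_ids and p1.provenance == p2.provenance


def test_pass_by_pass_matches_bruteforce_small_instance():
    """Each line pass must reach the exhaustive optimum of its segments."""
    lines = make_lines(("WEL1", "WEL", True, 0, None), ("B1", "broiler", True, 1, None))
    cat = uniform_catalog(20, lines, seed=3, seg_prob=0.9)
    gmap = flat_map()
    cfg = SelectionConfig(t=10**9, densities={"WEL1": 0.4, "B1": 0.4},
                          line_order=["WEL1", "B1"])
    panel, state = select_panel(cat, cfg, gmap)
    # replay: same backbones, then brute-force each line's segments
    state2 = build_backbones(cat, cfg, gmap)
    ids = cat.df["snp_id"].to_numpy()
    for line in cfg.line_order:
        for seg in segments_for_line(state2, line, cat, gmap):
            n = compute_segment_quota(seg.length_cm, cfg.densities[line])
            if n == 0:
                continue
            got = fill_segment(seg, n)
            want, want_cost = brute_force_fill(list(seg.cand_cm), seg.left_cm,
                                               seg.right_cm, n)
            if want_cost is not None:
                pts = ([seg.left_cm] + [seg.cand_cm[list(seg.cand_rows).index(i)]
                                        for i in got] + [seg.right_cm])
                cost = sum((q - p) ** 2 for p, q in zip(pts, pts[1:]))
                assert cost == pytest.approx(want_cost, rel=1e-9)
            for i in got:
                state2.panel.add(ids[i], f"line:{line}")
                state2.selected[i] = True
    assert state2.panel.snp_ids == panel.snp_ids


def test_budget_monotone_and_calibration_ratio():
    lines = make_lines(("B1", "broiler", True, 0, None),
                       ("B2", "broiler", True, 1, None),
                       ("WEL1", "WEL", True, 2, None),
                       ("WEL2", "WEL", True, 3, None))
    cat = uniform_catalog(2000, lines, seed=4, seg_prob=0.95)
    gmap = flat_map()
    order = ["WEL1", "WEL2", "B1", "B2"]

    def run(budget):
        cfg = SelectionConfig(t=3_000_000 // budget, budget=budget,
                              group_ratio={"broiler": 3, "WEL": 2},
                              line_order=order)
        return select_panel(cat, cfg, gmap)

    p1, s1 = run(300)
    assert abs(len(p1) - 300) <= 0.02 * 300
    p2, s2 = run(600)
    assert abs(len(p2) - 600) <= 0.02 * 600
    # per-line density targets honour the 3:2 group ratio (each group
    # has two filled lines, so the per-line weight ratio is also 3:2)
    dens = calibrate_densities(cat, SelectionConfig(
        t=3_000_000 // 600, budget=600, group_ratio={"broiler": 3, "WEL": 2},
        line_order=order), gmap)
    assert dens["B1"] / dens["WEL1"] == pytest.approx(1.5)


def test_budget_saturation_selects_all():
    cat = one_line_catalog([1000 * i for i in range(1, 30)])
    cfg = SelectionConfig(t=500, budget=10_000, group_ratio={"broiler": 1},
                          line_order=["B1"])
    with pytest.warns(UserWarning):
        panel, _ = select_panel(cat, cfg, flat_map())
    assert len(panel) == 29


def test_placed_snps_respect_density_scale():
    lines = make_lines(("B1", "broiler", True, 0, None))
    cat = uniform_catalog(300, lines, seed=5)
    cfg = SelectionConfig(t=10**9, densities={"B1": 5.0}, line_order=["B1"])
    panel, state = select_panel(cat, cfg, flat_map())
    # 5 SNPs/cM over a 10 cM map: within quota rounding of 50 placements
    assert abs(state.S["B1"] - 50) <= 3
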