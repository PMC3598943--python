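"""Published reference counts for the chicken 600 K Axiom array design.

These are the printed inputs of the original design study: per-line
segregating-SNP counts from the 24-line pooled resequencing panel, the
validation (conversion + trio) summary of the ~1.8 M pre-screening
panel, and the functional-annotation breakdown of the final 580,954-SNP
panel.  They serve as worked-example inputs for the report arithmetic;
nothing in the package derives them.
"""

from __future__ import annotations

from .catalog import LineInfo

#: Per-line segregating SNP counts (quality score >= 20), 24-line panel.
LINE_SNP_COUNTS: dict[str, int] = {
    "B1": 9_525_306, "B2": 10_760_626, "B3": 9_305_545, "B4": 10_422_420,
    "WEL1": 8_605_672, "WEL2": 9_900_302, "WEL3": 7_340_262, "WEL4": 7_951_423,
    "WEL5": 11_139_255, "WEL6": 2_630_343,
    "BEL1": 8_182_562, "BEL2": 7_876_558, "BEL3": 11_593_980, "BEL4": 3_236_749,
    "BEL5": 3_751_628,
    "RI-J": 10_358_702,
    "I1": 447_683, "I2": 1_816_948, "I3": 1_109_100, "I4": 1_055_257,
    "I5": 801_052, "I6": 1_395_679, "I7": 803_892, "I8": 603_338,
}

#: Reporting grouping used for the group-mean arithmetic: the broiler
#: lines, the layer lines (white + brown egg layers and the unselected
#: experimental layer RI-J), and the inbred lines.
REPORT_GROUPING: dict[str, str] = {
    **{f"B{i}": "broiler" for i in range(1, 5)},
    **{f"WEL{i}": "layer" for i in range(1, 7)},
    **{f"BEL{i}": "layer" for i in range(1, 6)},
    "RI-J": "layer",
    **{f"I{i}": "inbred" for i in range(1, 9)},
}


def reference_lines() -> list[LineInfo]:
    """The 24-line registry of the design study."""
    lines = []
    rank = 0
    for i in range(1, 7):
        lines.append(LineInfo(f"WEL{i}", "WEL", True, rank)); rank += 1
    for i in range(1, 6):
        lines.append(LineInfo(f"BEL{i}", "BEL", True, rank)); rank += 1
    for i in range(1, 5):
        lines.append(LineInfo(f"B{i}", "broiler", True, rank)); rank += 1
    lines.append(LineInfo("RI-J", "experimental", False))
    for i in range(1, 9):
        lines.append(LineInfo(f"I{i}", "inbred", False))
    return lines


#: Validation summary counts of the 1.8 M pre-screening panel.
VALIDATION_COUNTS = {
    "total_validated": 1_829_290,
    "polymorphic": 1_187_482,
    "monomorphic": 313_000,
    "failed": 328_808,
    "trios": 32,
    "mendel_fail": 10_674,
}

#: Annotation breakdown of the final panel.
FINAL_PANEL_SIZE = 580_954
ANNOTATION_COUNTS = {
    "intergenic": 266_636,
    "intronic": 189_128,
    "non-synonymous": 9_345,
    "synonymous": 12_069,
    "stopgain_stoploss": 120,
    "upstream1kb": 5_892,
    "downstream1kb": 6_456,
    "utr3": 2_497,
    "utr5": 302,
    "splicing": 83,
    "ncRNA": 44,
}
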