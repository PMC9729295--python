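#!/usr/bin/env python
"""Pull-down interactor enrichment on the two synthetic cell lines.

Zero-substitutes and median-ratio-normalises the bait/IgG tables, writes the
scatter coordinates (x = log2 average bait/IgG ratio, y = log10 summed
average intensity) with candidate flags, and compares the planted interactor
(CLIP170) across cell lines, mirroring the "how much more of this protein is
bait-bound when CDK4 is overexpressed" question.
"""

from pathlib import Path

from phosphoscreen.io import write_results_table
from phosphoscreen.pulldown import (compare_cell_lines, prepare,
                                    read_pulldown_table, score_and_filter)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tables = {name: read_pulldown_table(ROOT / "data" / f"pulldown_{name}.tsv")
              for name in ("wt", "cdk4")}
    for name, table in tables.items():
        points = score_and_filter(prepare(table))
        write_results_table(points, ROOT / f"pulldown_points_{name}.tsv")
        cands = [p for p in points if p.is_candidate]
        print(f"{name.upper()} line: {len(points)} proteins, "
              f"{len(cands)} candidates at the default filter "
              f"(log2 ratio > 2 or IgG-absent, with the psm floor)")
        clip = next(p for p in points if p.protein_id == "CLIP170")
        print(f"  CLIP170: x = {clip.x:+.2f}, candidate = {clip.is_candidate}, "
              f"IgG-undetected = {clip.igg_undetected}")

    fc = compare_cell_lines(tables["wt"], tables["cdk4"], "CLIP170")
    print(f"CLIP170 bait-bound intensity, CDK4-overexpressing vs WT: "
          f"{fc:.0f}-fold")


if __name__ == "__main__":
    main()
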