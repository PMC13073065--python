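#!/usr/bin/env python
"""Standardize CPPs to z-scores and score gene-drug interactions.

z = (CPP - deletion-array median) / SD(matched reference array), per
concentration; the adjusted z-score z_drug - z_nodrug measures the
gene-drug interaction. Writes results/interactions.tsv and prints the
ten strongest drug-enhancing deletions by adjusted K at 10 ug/mL and the
ten strongest drug-suppressing deletions by adjusted L at 20 ug/mL, the
screen's two canonical outlier lists.
"""

from pathlib import Path

from qhtcp import plate_io
from qhtcp.growth import qc_arrays
from qhtcp.interactions import rank_outliers, score_screen

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series_dir = ROOT / "screen"
    fits = plate_io.read_table(ROOT / "cpp.tsv")
    layouts = plate_io.read_layouts(series_dir / "layouts.tsv")
    design = plate_io.read_design(series_dir / "manifest.tsv")
    qc = qc_arrays(fits)
    table = score_screen(fits, design, layouts, qc)
    plate_io.write_table(table, ROOT / "interactions.tsv")

    counts = table["class_20ugml"].value_counts()
    print(f"scored {len(table)} strain entries at threshold |z| >= 2:")
    print(counts.to_string())
    print("\nten most drug-enhancing deletions (lowest adjusted K z at 10 ug/mL):")
    print(rank_outliers(table, "K", 2, "lowest", 10).round(2).to_string(index=False))
    print("\nten most drug-suppressing deletions (lowest adjusted L z at 20 ug/mL):")
    print(rank_outliers(table, "L", 3, "lowest", 10).round(2).to_string(index=False))


if __name__ == "__main__":
    main()
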