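#!/usr/bin/env python
"""Generate the synthetic deletion-collection screen used by the analysis.

Emulates a 500-gene chemogenomic screen: 384-spot deletion arrays
replicated on 0/10/20 ug/mL drug with matched reference-strain arrays,
5% planted drug-enhancing and 5% drug-suppressing gene deletions
(4-10 reference-SD effects), 30% of genes with mild baseline fitness
defects, and imaging every 3.5 h over 120 h. Writes the raw time series,
plate layouts, manifest, and ground-truth tables under results/screen/.
"""

from pathlib import Path

from qhtcp import plate_io
from qhtcp.simulate import ScreenSimConfig, simulate_screen

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main() -> None:
    cfg = ScreenSimConfig(n_genes=500, frac_duplicate=0.04, seed=SEED)
    screen = simulate_screen(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    plate_io.write_timeseries(screen.series, OUT / "timeseries.tsv")
    plate_io.write_layouts(screen.layouts, OUT / "layouts.tsv")
    plate_io.write_design(screen.design, OUT / "manifest.tsv")
    plate_io.write_table(screen.truth.genes, OUT / "truth_genes.tsv", seed=SEED)
    plate_io.write_table(screen.truth.interactions, OUT / "truth_interactions.tsv",
                         seed=SEED)
    plate_io.write_table(screen.truth.entries, OUT / "truth_entries.tsv", seed=SEED)

    report = plate_io.validate_design(screen.design, screen.layouts, screen.series)
    n_enh = len(screen.truth.planted_genes("enhancer"))
    n_sup = len(screen.truth.planted_genes("suppressor"))
    print(f"simulated screen: {len(screen.series)} spot time series "
          f"({len(screen.layouts)} plates, seed {SEED})")
    print(f"planted truth: {n_enh} enhancers, {n_sup} suppressors, "
          f"{int((screen.truth.genes['defect_dk'] < 0).sum())} genes with fitness defects")
    print(f"design validation: {'OK' if report.ok else report.issues}")


if __name__ == "__main__":
    main()
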