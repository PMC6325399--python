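"""Simulate the full study and write its input tables.

Generates the crossed design — 3 ruminant species x 4 animals x 2 diets
(high forage vs high concentrate) — as electropherogram peak tables,
replicate qPCR Ct tables, fermentation records and sample metadata,
with the planted ground truth saved alongside for later comparison.
"""

import sys
from pathlib import Path

from rumenprof import SimConfig, simulate_study
from rumenprof import io as rio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260927
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    study = simulate_study(SimConfig(), seed=SEED)
    rio.write_table(study.peaks_frame(), OUT / "peaks.tsv")
    rio.write_table(study.ct_frame(), OUT / "ct.tsv")
    rio.write_table(study.fermentation, OUT / "fermentation.tsv")
    rio.write_table(study.meta, OUT / "meta.tsv")
    rio.write_table(study.planted_abundance, OUT / "planted_abundance.tsv")
    n_peaks = sum(len(t) for t in study.peak_tables.values())
    print(
        f"simulated {len(study.meta)} samples ({n_peaks} raw peaks), "
        f"{len(study.ct_records)} Ct records, "
        f"{study.fermentation['response'].nunique()} fermentation responses -> {OUT}"
    )


if __name__ == "__main__":
    main()
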