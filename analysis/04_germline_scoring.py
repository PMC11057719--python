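"""Score germline progeny phenotypes and summarize by parental sex.

Reads the simulated progeny tables (scratch/sim/progeny_male.csv,
scratch/sim/progeny_female.csv), scores each fly's eye/body phenotype into an
outcome, tallies per-vial proportions, and writes the per-vial table and
the per-sex summary (unweighted vial means with SEM, plus pooled
proportions) to results/.

Run from the repository root after 01:  python analysis/04_germline_scoring.py
"""

from pathlib import Path

import pandas as pd

from drwhite import aggregate_germline, read_progeny_csv, tally_progeny_table, vials_to_frame

RESULTS = Path("results")
SIM_DIR = Path("scratch/sim")


def main() -> None:
    vials = []
    for sex in ("male", "female"):
        progeny = read_progeny_csv(SIM_DIR / f"progeny_{sex}.csv")
        vials.extend(tally_progeny_table(progeny))
    vials_to_frame(vials).to_csv(RESULTS / "germline_vials.csv", index=False)
    summary = aggregate_germline(vials)
    summary.to_csv(RESULTS / "germline_summary.csv", index=False)
    cols = [
        "parent_sex", "n_vials", "total_progeny",
        "HR_mean", "HR_sem", "NoDSB_NHEJ_mean", "NoDSB_NHEJ_sem", "SSA_mean", "SSA_sem",
    ]
    print(summary[cols].to_string(index=False, float_format="%.2f"))


if __name__ == "__main__":
    main()
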