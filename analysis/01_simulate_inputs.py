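"""Generate every input the downstream analyses consume.

Simulates, with full seed control: a reference construct (FASTA + TOML
metadata), control/sample trace pairs for each preset tissue cohort at its
reported sample size, and germline progeny tables for both parental sexes.
Trace tables, progeny CSVs and full per-sample manifests are bulky and go
under scratch/sim/; a compact table of the true group means goes under
results/.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import json
from pathlib import Path

import pandas as pd

from drwhite import (
    TraceSimParams,
    make_reference,
    simulate_cohort,
    simulate_germline_cohort,
    write_reference_fasta,
    write_trace_table,
)
from drwhite.profiles import GERMLINE_PROFILES, GROUP_SAMPLE_SIZES, TRACE_PROFILES

SEED = 2024
SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    ref = make_reference(SEED)
    write_reference_fasta(ref, SIM_DIR / "reference.fasta")
    (SIM_DIR / "reference.toml").write_text(
        f"recognition_start = {ref.recognition_start}\n"
        f"insertion_len = {ref.insertion_len}\n"
        f"cut_offset = {ref.cut_offset}\n"
    )

    manifests = {}
    truth_rows = []
    for i, (label, profile) in enumerate(sorted(TRACE_PROFILES.items())):
        n = GROUP_SAMPLE_SIZES[label]
        cohort = simulate_cohort(
            profile, n, TraceSimParams(seed=SEED + 10 + i), ref=ref
        )
        group_dir = SIM_DIR / label
        group_dir.mkdir(exist_ok=True)
        for sim in cohort:
            write_trace_table(sim.control, group_dir / f"{sim.sample_id}_control.tsv")
            write_trace_table(sim.sample, group_dir / f"{sim.sample_id}_sample.tsv")
        manifests[label] = {
            "n": n,
            "true_rel_hr_pct": profile.rel_hr_truth,
            "samples": [
                {k: v for k, v in s.manifest.items() if k != "truth"}
                | {"truth": {str(k): v for k, v in s.truth.items()}}
                for s in cohort
            ],
        }
        truth_rows.append(
            {
                "label": label, "tissue": profile.tissue, "sex": profile.sex,
                "condition": profile.condition, "n": n,
                "true_rel_hr_pct": profile.rel_hr_truth,
            }
        )
        print(f"{label}: {n} trace pairs (true rel HR {profile.rel_hr_truth:.1f}%)")
    # full per-sample manifests are bulky -> scratch; compact truths -> results
    (SIM_DIR / "trace_cohort_manifest.json").write_text(
        json.dumps(manifests, indent=2) + "\n"
    )
    pd.DataFrame(truth_rows).to_csv(RESULTS / "cohort_truth.csv", index=False)

    for j, (label, gp) in enumerate(sorted(GERMLINE_PROFILES.items())):
        progeny, manifest = simulate_germline_cohort(
            gp.p, gp.n_vials, gp.mean_progeny,
            seed=SEED + 50 + j, parent_sex=gp.parent_sex,
            out_csv=SIM_DIR / f"progeny_{gp.parent_sex}.csv",
        )
        print(
            f"{label}: {gp.n_vials} vials, {manifest['total_progeny']} progeny "
            f"(true HR {100 * gp.p_HR:.1f}%)"
        )
        (SIM_DIR / f"progeny_{gp.parent_sex}_manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )


if __name__ == "__main__":
    main()
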