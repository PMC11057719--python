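"""Decompose every simulated trace pair and call repair outcomes.

Reads the trace tables written by 01_simulate_inputs.py from scratch/sim/,
registers and decomposes each sample against its control, classifies the
spectrum into HR / NHEJ-with-indels / no-DSB, and writes the per-sample
calls table to results/calls.csv.  Samples failing background QC are
excluded and counted.

Run from the repository root after 01:  python analysis/02_decompose_and_classify.py
"""

from pathlib import Path

from drwhite import (
    QCError,
    calls_to_frame,
    classify_spectrum,
    decompose,
    read_reference_fasta,
    read_trace_table,
)
from drwhite.profiles import TRACE_PROFILES

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    ref = read_reference_fasta(SIM_DIR / "reference.fasta", SIM_DIR / "reference.toml")
    calls, n_qc_fail = [], 0
    for label, profile in sorted(TRACE_PROFILES.items()):
        group_dir = SIM_DIR / label
        for control_path in sorted(group_dir.glob("*_control.tsv")):
            sample_id = control_path.name.removesuffix("_control.tsv")
            control = read_trace_table(control_path)
            sample = read_trace_table(group_dir / f"{sample_id}_sample.tsv")
            spectrum = decompose(control, sample, ref)
            try:
                calls.append(
                    classify_spectrum(
                        spectrum, -23,
                        sample_id=sample_id, sex=profile.sex,
                        tissue=profile.tissue, condition=profile.condition,
                    )
                )
            except QCError:
                n_qc_fail += 1
        print(f"{label}: {len([c for c in calls if c.sample_id.startswith(label)])} calls")

    df = calls_to_frame(calls)
    df.to_csv(RESULTS / "calls.csv", index=False, float_format="%.6g")
    print(
        f"\nwrote {len(df)} calls to results/calls.csv "
        f"({n_qc_fail} excluded by background QC)"
    )


if __name__ == "__main__":
    main()
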