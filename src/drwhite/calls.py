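"""Map indel spectra to DR-*white* repair outcomes and summarize cohorts.

The spectrum's weight at the HR-diagnostic shift (-23 for the canonical
construct) is homologous recombination; the weight at zero is "no DSB"
(which also absorbs molecularly invisible outcomes: precise end-joining and
intersister HR); everything else within +/-K is NHEJ with indels.

Relative proportions (rel_HR, rel_NHEJ) are percentages of detectable
repair events only (shift-0 excluded) and are undefined — not zero — when
no detectable repair is present.  Absolute proportions are percentages of
all events.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tide import IndelSpectrum

logger = logging.getLogger(__name__)

STAT_COLUMNS = ("rel_HR", "rel_NHEJ", "abs_HR", "abs_total_repair")


class QCError(ValueError):
    """Spectrum failed quality control; classification is refused."""


@dataclass(frozen=True)
class RepairCall:
    """Per-sample repair-outcome proportions with metadata labels."""

    p_noDSB: float
    p_HR: float
    p_NHEJ: float
    rel_HR: float  # NaN when no detectable repair
    rel_NHEJ: float
    abs_HR: float
    abs_total_repair: float
    sample_id: str = ""
    sex: str = ""
    tissue: str = ""
    condition: str = ""
    qc_pass: bool = True

    @property
    def rel_defined(self) -> bool:
        return not math.isnan(self.rel_HR)


def classify_spectrum(
    spec: IndelSpectrum,
    hr_shift: int = -23,
    *,
    sample_id: str = "",
    sex: str = "",
    tissue: str = "",
    condition: str = "",
) -> RepairCall:
    """Classify a QC-passing spectrum into HR / NHEJ / no-DSB proportions."""
    if not spec.qc_pass:
        raise QCError(
            f"sample {sample_id or '<unnamed>'}: high background "
            f"({spec.background:.3f}); excluded from classification"
        )
    if not (-spec.max_indel <= hr_shift <= -1):
        raise ValueError(f"hr_shift {hr_shift} must be a deletion within -K..-1")
    p_hr = spec.weight(hr_shift)
    p_no = spec.weight(0)
    p_nhej = max(0.0, 1.0 - p_hr - p_no)
    detectable = p_hr + p_nhej
    if detectable > 0:
        rel_hr = 100.0 * p_hr / detectable
        rel_nhej = 100.0 - rel_hr
    else:
        logger.info("sample %s: no detectable repair; rel_* undefined", sample_id)
        rel_hr = rel_nhej = float("nan")
    return RepairCall(
        p_noDSB=p_no,
        p_HR=p_hr,
        p_NHEJ=p_nhej,
        rel_HR=rel_hr,
        rel_NHEJ=rel_nhej,
        abs_HR=100.0 * p_hr,
        abs_total_repair=100.0 * detectable,
        sample_id=sample_id,
        sex=sex,
        tissue=tissue,
        condition=condition,
        qc_pass=True,
    )


def calls_to_frame(calls: list[RepairCall]) -> pd.DataFrame:
    """Long-format per-sample table of repair calls."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "sex": c.sex,
                "tissue": c.tissue,
                "condition": c.condition,
                "p_noDSB": c.p_noDSB,
                "p_HR": c.p_HR,
                "p_NHEJ": c.p_NHEJ,
                "rel_HR": c.rel_HR,
                "rel_NHEJ": c.rel_NHEJ,
                "abs_HR": c.abs_HR,
                "abs_total_repair": c.abs_total_repair,
                "qc_pass": c.qc_pass,
            }
            for c in calls
        ]
    )


def aggregate_group(
    calls: pd.DataFrame | list[RepairCall],
    keys: list[str],
) -> pd.DataFrame:
    """Group means and SEMs of the repair statistics.

    Samples with undefined relative proportions (no detectable repair) are
    excluded — the relative statistics are conditional on detectable events
    by definition — and the excluded count is reported per group.  SEM is
    sd/sqrt(n) (ddof=1), NaN for n = 1.  Groups are emitted in sorted key
    order; groups left empty after exclusions are omitted with a warning.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    if not keys:
        raise ValueError("at least one grouping key is required")
    usable = df[df["rel_HR"].notna()]
    n_excluded_total = len(df) - len(usable)
    if n_excluded_total:
        logger.warning(
            "%d sample(s) with no detectable repair excluded from group means",
            n_excluded_total,
        )
    rows = []
    for key_vals, grp in sorted(df.groupby(keys, sort=True), key=lambda kv: kv[0]):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        sub = grp[grp["rel_HR"].notna()]
        if sub.empty:
            logger.warning("group %s empty after exclusions; omitted", key_vals)
            continue
        row = dict(zip(keys, key_vals))
        n = len(sub)
        row["n"] = n
        row["n_excluded"] = len(grp) - n
        for stat in STAT_COLUMNS:
            vals = sub[stat].to_numpy(dtype=float)
            row[f"{stat}_mean"] = float(vals.mean())
            row[f"{stat}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
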