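"""Preset outcome profiles for each reported experimental group.

Each trace preset records the group's mean HR percentage of detectable
repair events together with the fraction of all events that are detectable
(indel-bearing).  The detectable fraction is only reported for some groups
(65.2% for 0-3 h embryos, 79.8% for 6-20 h embryos, ~20% for the
heat-shock whole-fly experiments); where it is not, a plausible assumed
value is used and marked — it does not enter the relative HR/NHEJ
statistics that the groups are compared on.

Germline presets record the per-vial outcome means (HR, NoDSB/NHEJ, SSA),
the number of vials scored, and the mean progeny per vial implied by the
reported totals (5,894 progeny over 66 male vials; 2,759 over 59 female
vials).
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import OutcomeProfile


def _from_relative(
    label: str,
    rel_hr_pct: float,
    detectable_frac: float,
    sex: str,
    tissue: str,
    condition: str = "",
) -> OutcomeProfile:
    f_hr = detectable_frac * rel_hr_pct / 100.0
    return OutcomeProfile(
        label=label,
        f_noDSB=1.0 - detectable_frac,
        f_HR=f_hr,
        f_NHEJ=detectable_frac - f_hr,
        sex=sex,
        tissue=tissue,
        condition=condition,
    )


# Groups with a reported detectable-event fraction.
_REPORTED = [
    ("embryo_0_3h", 56.2, 0.652, "mixed", "embryo", "constitutive 0-3 h"),
    ("embryo_6_20h", 63.9, 0.798, "mixed", "embryo", "constitutive 6-20 h"),
    ("whole_fly_male", 47.3, 0.20, "male", "whole_fly", "heat shock"),
    ("whole_fly_female", 48.1, 0.20, "female", "whole_fly", "heat shock"),
    ("hs_embryo_male", 33.7, 0.20, "male", "whole_fly", "heat shock 0-1 d"),
    ("hs_larva_2_3d_male", 58.3, 0.20, "male", "whole_fly", "heat shock 2-3 d"),
]

# Groups where only the relative proportions are reported; the detectable
# fraction is an assumed, documented stand-in (0.72 for 3-6 h embryos
# interpolates the flanking reported values; 0.5 elsewhere).
_ASSUMED = [
    ("embryo_3_6h", 60.5, 0.72, "mixed", "embryo", "constitutive 3-6 h"),
    ("salivary_gland_male", 14.1, 0.5, "male", "salivary_gland", "heat shock"),
    ("salivary_gland_female", 14.9, 0.5, "female", "salivary_gland", "heat shock"),
    ("larval_brain_male", 80.4, 0.5, "male", "larval_brain", "heat shock"),
    ("larval_brain_female", 79.7, 0.5, "female", "larval_brain", "heat shock"),
    ("wing_disc_male", 63.6, 0.5, "male", "wing_disc", "heat shock"),
    ("adult_head_male", 28.1, 0.5, "male", "adult_head", "heat shock"),
    ("adult_head_female", 25.7, 0.5, "female", "adult_head", "heat shock"),
]

TRACE_PROFILES: dict[str, OutcomeProfile] = {
    label: _from_relative(label, rel, det, sex, tissue, condition)
    for label, rel, det, sex, tissue, condition in _REPORTED + _ASSUMED
}

# Reported sample sizes per group (samples analyzed by decomposition).
GROUP_SAMPLE_SIZES: dict[str, int] = {
    "embryo_0_3h": 22,
    "embryo_3_6h": 22,
    "embryo_6_20h": 22,
    "whole_fly_male": 35,
    "whole_fly_female": 33,
    "salivary_gland_male": 11,
    "salivary_gland_female": 11,
    "larval_brain_male": 23,
    "larval_brain_female": 25,
    "adult_head_male": 38,
    "adult_head_female": 38,
    "wing_disc_male": 8,
    "hs_embryo_male": 15,
    "hs_larva_2_3d_male": 15,
}


@dataclass(frozen=True)
class GermlineProfile:
    """Per-sex germline outcome probabilities and cohort geometry."""

    label: str
    parent_sex: str
    p_HR: float
    p_NoDSB_NHEJ: float
    p_SSA: float
    n_vials: int
    mean_progeny: float

    @property
    def p(self) -> tuple[float, float, float]:
        return (self.p_HR, self.p_NoDSB_NHEJ, self.p_SSA)


GERMLINE_PROFILES: dict[str, GermlineProfile] = {
    "germline_male": GermlineProfile(
        "germline_male", "male", 0.330, 0.621, 0.049, 66, 5894 / 66
    ),
    "germline_female": GermlineProfile(
        "germline_female", "female", 0.118, 0.866, 0.016, 59, 2759 / 59
    ),
}
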