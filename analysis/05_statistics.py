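"""Run the comparison statistics over the per-sample tables.

Runs the assay's comparison statistics on the simulated data:
  - Wilcoxon paired test of HR vs NHEJ proportions within a tissue;
  - Welch t test of absolute HR between two conditions;
  - two-way pathway-by-stage ANOVA (complementary HR/NHEJ rows) with
    Tukey HSD for male larval brain vs adult head;
  - three-way stage-by-sex-by-pathway ANOVA across both sexes;
  - two-way outcome-by-sex ANOVA with Tukey HSD on the germline vials.

Writes results/stats_effects.csv and results/stats_tukey.csv.

Run from the repository root after 02 and 04:  python analysis/05_statistics.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from drwhite import (
    FactorialDesign,
    factorial_anova,
    format_p,
    melt_pathway,
    tukey_hsd,
    welch_t_test,
    wilcoxon_signed_rank,
)

RESULTS = Path("results")


def main() -> None:
    calls = pd.read_csv(RESULTS / "calls.csv")
    effects_rows, tukey_rows = [], []

    # paired pathway comparison within wing disc (small-n tissue)
    wing = calls[calls["tissue"] == "wing_disc"].dropna(subset=["rel_HR"])
    w, p = wilcoxon_signed_rank(wing["rel_HR"], wing["rel_NHEJ"])
    print(f"wing disc HR vs NHEJ (Wilcoxon paired): W = {w:.1f}, p = {format_p(p)}")
    effects_rows.append(
        {"analysis": "wing_disc_paired", "effect": "HR vs NHEJ", "stat": w,
         "df1": np.nan, "df2": np.nan, "p": p}
    )

    # Welch: absolute HR, larval brain vs adult head males
    brain = calls.query("tissue == 'larval_brain' and sex == 'male'")["abs_HR"]
    head = calls.query("tissue == 'adult_head' and sex == 'male'")["abs_HR"]
    t, df, p = welch_t_test(brain, head)
    print(f"abs HR larval brain vs adult head (Welch): t = {t:.2f}, "
          f"df = {df:.1f}, p = {format_p(p)}")
    effects_rows.append(
        {"analysis": "abs_hr_welch", "effect": "larval_brain vs adult_head",
         "stat": t, "df1": 1, "df2": df, "p": p}
    )

    # factorial ANOVAs on the complementary-rows layout
    brains = calls[calls["tissue"].isin(["larval_brain", "adult_head"])].copy()
    brains["stage"] = np.where(brains["tissue"] == "larval_brain", "larva", "adult")
    long = melt_pathway(brains, id_vars=["sample_id", "sex", "stage"])

    males = long[long["sex"] == "male"]
    design2 = FactorialDesign("value", ("pathway", "stage"), males)
    res2 = factorial_anova(design2)
    for r in res2.table.itertuples():
        print(f"two-way (males) {r.effect}: F({r.df1:.0f},{r.df2:.0f}) = "
              f"{r.F:.1f}, p = {format_p(r.p)}")
        effects_rows.append(
            {"analysis": "two_way_male_brain", "effect": r.effect,
             "stat": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        )
    tk = tukey_hsd(design2, anova=res2)
    tk.insert(0, "analysis", "two_way_male_brain")
    tukey_rows.append(tk)

    design3 = FactorialDesign("value", ("stage", "sex", "pathway"), long)
    res3 = factorial_anova(design3)
    for r in res3.table.itertuples():
        effects_rows.append(
            {"analysis": "three_way_brain", "effect": r.effect,
             "stat": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        )
    sex_row = res3.table.set_index("effect").loc["sex"]
    print(f"three-way sex term: F({sex_row['df1']:.0f},{sex_row['df2']:.0f}) = "
          f"{sex_row['F']:.3f}, p = {format_p(sex_row['p'])}")

    # germline: outcome-by-sex two-way ANOVA over per-vial percentages
    vials = pd.read_csv(RESULTS / "germline_vials.csv")
    germ_long = vials.melt(
        id_vars=["vial_id", "parent_sex"],
        value_vars=["HR_pct", "NoDSB_NHEJ_pct", "SSA_pct"],
        var_name="outcome", value_name="value",
    )
    germ_long["outcome"] = germ_long["outcome"].str.removesuffix("_pct")
    design_g = FactorialDesign("value", ("outcome", "parent_sex"), germ_long)
    res_g = factorial_anova(design_g)
    inter = res_g.table.set_index("effect").loc["outcome:parent_sex"]
    print(f"germline outcome x sex: F({inter['df1']:.0f},{inter['df2']:.0f}) = "
          f"{inter['F']:.1f}, p = {format_p(inter['p'])}")
    for r in res_g.table.itertuples():
        effects_rows.append(
            {"analysis": "germline_two_way", "effect": r.effect,
             "stat": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        )
    tkg = tukey_hsd(design_g, anova=res_g)
    tkg.insert(0, "analysis", "germline_two_way")
    tukey_rows.append(tkg)

    pd.DataFrame(effects_rows).to_csv(RESULTS / "stats_effects.csv", index=False)
    pd.concat(tukey_rows, ignore_index=True).to_csv(
        RESULTS / "stats_tukey.csv", index=False
    )
    print("\nwrote results/stats_effects.csv and results/stats_tukey.csv")


if __name__ == "__main__":
    main()
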