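#!/usr/bin/env python
"""Descriptive tables: demographics and lipid profiles by sex and by age group.

Reads results/cohort.csv (run 01_simulate_cohort.py first) and writes the
demographic summary plus the two lipid tables as CSVs under results/tables/.
Reports which analytes separate by sex and by the age-13 split.
"""

from pathlib import Path

import pandas as pd

from pedlipid import chi_square_2x2, lipid_table, rank_sum_test, read_cohort, summarize

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panels = read_cohort(RESULTS / "cohort.csv")
    outdir = RESULTS / "tables"
    outdir.mkdir(parents=True, exist_ok=True)

    # demographics: age by sex + sex composition of the age groups
    by_sex = {
        s: [p.age_years for p in panels if p.sex.value == s] for s in ("boy", "girl")
    }
    print("age by sex:")
    for s, ages in by_sex.items():
        print(f"  {s}: {summarize(ages)} (n={len(ages)})")
    _, p_age = rank_sum_test(by_sex["boy"], by_sex["girl"])
    print(f"  rank-sum p = {p_age:.3f}")
    table = [
        [sum(1 for a in by_sex["girl"] if a < 13), sum(1 for a in by_sex["girl"] if a >= 13)],
        [sum(1 for a in by_sex["boy"] if a < 13), sum(1 for a in by_sex["boy"] if a >= 13)],
    ]
    chi2, p_chi = chi_square_2x2(table)
    print(f"sex x age-group: chi2={chi2:.2f}, p={p_chi:.3f}")
    pd.DataFrame(
        table, index=["girl", "boy"], columns=["<13", ">=13"]
    ).to_csv(outdir / "table1_sex_by_age_group.csv")

    for grouping, fname in [("sex", "table2_lipids_by_sex.csv"),
                            ("age_lt_13", "table3_lipids_by_age.csv")]:
        tbl = lipid_table(panels, grouping)
        tbl.round(3).to_csv(outdir / fname, index=False)
        sig = tbl[tbl["p"] < 0.05]["analyte"].tolist()
        print(f"{grouping}: significant (p<0.05) differences in: {sig or 'none'}")

    print(f"wrote tables to {outdir}")


if __name__ == "__main__":
    main()
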