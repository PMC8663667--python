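#!/usr/bin/env python
"""Respondent characteristics and bivariate associations.

Compares rural and urban patients on income, age and in-person visits
(chi-square / pooled t tests) and reports the correlations the structural
model builds on: SM use with in-person utilization, and self-management
with A1c%TIC.
"""

from pathlib import Path

import pandas as pd

from smglyc import io
from smglyc.cohort_stats import pearson_correlation, table2_summary

OUT = Path("results")


def main():
    merged = pd.read_csv(OUT / "merged.csv")

    table = table2_summary(merged)
    io.write_csv(table, OUT / "table_characteristics.csv")
    print("respondent characteristics by rurality:")
    print(table.to_string(index=False))

    r_xu, p_xu = pearson_correlation(merged["sm_months"], merged["visits"])
    r_my, p_my = pearson_correlation(merged["dsmq_composite"], merged["a1c_tic_percent"])
    print(f"\nSM months x in-person visits: r={r_xu:.2f} (p={p_xu:.3g})")
    print(f"self-management x A1c%TIC:    r={r_my:.2f} (p={p_my:.3g})")


if __name__ == "__main__":
    main()
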