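#!/usr/bin/env python
"""Score the three measures and assemble the analysis table.

Reads the cohort written by 01_simulate_cohort.py and computes, per
patient: A1c%TIC for 2018 (Rosendaal interpolation, covered span),
months-with-use for 2017, and the DSMQ composite; merges them with
rurality and covariates into results/merged.csv and logs any exclusions.
"""

from pathlib import Path

import pandas as pd

from smglyc import dsmq, glycemic, io, sm_metrics
from smglyc.mediation import ModelSpec
from smglyc.pipeline import build_analysis_table

COHORT = Path("results/cohort")
OUT = Path("results")


def main():
    patients = io.read_patients(COHORT / "patients.csv")
    labs = io.read_hba1c(COHORT / "hba1c.csv")
    messages = io.read_messages(COHORT / "messages.csv")
    responses = io.read_dsmq(COHORT / "dsmq.csv")

    glyc = glycemic.summarize_all(labs, 2018)
    sm = sm_metrics.summarize_all(messages, patients["patient_id"], 2017)
    scores = dsmq.score_all(responses)
    merged, exclusions = build_analysis_table(patients, glyc, sm, scores, ModelSpec())

    io.write_csv(glyc, OUT / "glycemic_summary.csv")
    io.write_csv(sm, OUT / "sm_summary.csv")
    io.write_csv(scores, OUT / "dsmq_scores.csv")
    io.write_csv(merged, OUT / "merged.csv")
    io.write_csv(exclusions, OUT / "exclusions.csv")

    print(f"analysis table: {len(merged)} patients ({len(exclusions)} excluded)")
    print(f"  A1c%TIC      mean {merged['a1c_tic_percent'].mean():.1f} "
          f"(SD {merged['a1c_tic_percent'].std():.1f})")
    print(f"  SM months    mean {merged['sm_months'].mean():.1f} "
          f"(SD {merged['sm_months'].std():.1f})")
    print(f"  DSMQ         mean {merged['dsmq_composite'].mean():.1f} "
          f"(SD {merged['dsmq_composite'].std():.1f})")
    print(f"  control class: {glyc['control_class'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
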