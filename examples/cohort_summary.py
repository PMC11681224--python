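"""Summarize the five-athlete validation cohort.

Each athlete ran two maximal 100-m trials; the summary reports the mean and
sample SD of the trial times and of the per-athlete average speeds
(100 m / time, rounded to 3 decimals before averaging), alongside the
demographics.
"""

from sprintvision import average_speed, round_half_up, summarize_cohort, validation_cohort

cohort = validation_cohort()
print(cohort.to_string(index=False))

print("\nper-athlete first-trial speeds (m/s):")
for _, row in cohort.iterrows():
    v = round_half_up(average_speed(100.0, row["time_trial1_s"]), 3)
    print(f"  {row['participant']}: {v:.3f}")

summary = summarize_cohort(cohort)
print("\ncohort summary (mean, SD):")
for col in summary.columns:
    print(f"  {col:24s} {summary[col]['mean']:8.3f}  ({summary[col]['sd']:.3f})")
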