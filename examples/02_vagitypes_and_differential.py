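"""Vagitype assignment and the differential-abundance screen.

Each sample is labelled by its predominant taxon (>= 30% of reads, else
unassigned); earliest early-pregnancy samples (days 42-167) are screened
taxon-by-taxon with Mann-Whitney U tests and Benjamini-Hochberg FDR.
Printed: vagitype composition by outcome, the L. crispatus Fisher contrast,
and the significant taxa with their per-group medians.
"""

import pandas as pd

import vmptb as v

cohort = v.simulate_cohort(v.SyntheticConfig(seed=1))
table = v.filter_min_reads(cohort.table)  # 1,000-read QC floor
records = cohort.records[cohort.records["sample_id"].isin(table.sample_ids)]

calls = v.assign_vagitypes(table)
outcome = records.set_index("sample_id")["outcome"]
print("vagitype frequencies by outcome (%):")
print(pd.crosstab(calls.set_index("sample_id")["vagitype"], outcome,
                  normalize="columns").mul(100).round(1))

contrast = v.lcrispatus_vagitype_contrast(calls, outcome)
print(f"\nL. crispatus vagitype x outcome Fisher p = {contrast['p_value']:.2e}")
# Term pregnancies are enriched for L. crispatus dominance.

chosen = v.earliest_sample_in_window(records, (42, 167))
frame = table.to_frame().loc[chosen["sample_id"]]
taxa = v.filter_low_abundance(frame)
outcomes = pd.Series(chosen["outcome"].to_numpy(), index=chosen["sample_id"])
screen = v.differential_screen(frame[taxa], outcomes)
sig = screen[screen["significant"]].sort_values("q_value")
print(f"\n{len(taxa)} taxa pass the abundance filter; "
      f"{len(sig)} differ at FDR 5%:")
print(sig[["taxon", "q_value", "median_ptb", "median_tb", "direction"]]
      .to_string(index=False))
# direction +1 = more abundant before preterm birth, -1 = before term birth.
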