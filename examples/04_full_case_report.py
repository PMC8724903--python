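"""Run the full per-case analysis and a small simulated cohort summary.

The per-case report mirrors the clinical question: how much of each
modality's segmented volume (and hot spot) lies outside the
contrast-enhancement volume that conventional treatment targets?
"""

from gbmpar.pipeline import CaseConfig, run_case, summarize_cohort

reports = [run_case(CaseConfig(case_id=f"case{i}", seed=i))
           for i in range(5)]

print("case0 per-modality metrics:")
print(reports[0].metrics[["modality", "volume_ml", "ce_volume_ml",
                          "peripheral_volume_pct",
                          "peripheral_hotspot_pct"]].to_string(index=False))
print()
print("cohort summary (peripheral volume %, bins 0-20 / 20-40 / >40):")
print(summarize_cohort(reports).to_string(index=False))
print()
print("A peripheral volume of 100% means tissue equal in size to the whole")
print("CE volume is active outside it; values above 100% are possible and")
print("occur when a modality's ROI extends far beyond the enhancing rim.")
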