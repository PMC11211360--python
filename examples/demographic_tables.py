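"""Recompute summary-table percentages from published marginal counts.

Builds a database whose marginals equal the published esketamine
nasal-spray count tables (6,887 cases; 14,606 reaction records across 25
system organ classes) and lets the summary operations recompute the
percentages the publication prints next to each count.
"""

from pvsignal import (
    AgeGroup, ReporterType, Seriousness, Sex,
    database_from_marginals, demographics_summary, soc_summary,
)

db = database_from_marginals(
    sex_counts={Sex.FEMALE: 3652, Sex.MALE: 2037, Sex.UNKNOWN: 1198},
    age_counts={AgeGroup.UNDER_18: 55, AgeGroup.ADULT: 3395,
                AgeGroup.ELDERLY: 532, AgeGroup.UNKNOWN: 2905},
    reporter_counts={ReporterType.HEALTHCARE_PROFESSIONAL: 5428,
                     ReporterType.CONSUMER: 1456, ReporterType.UNKNOWN: 3},
    country_counts={"United States": 5494, "France": 244, "Brazil": 135,
                    "Germany": 97, "Spain": 94},
    year_counts={2019: 677, 2020: 1082, 2021: 1311, 2022: 1540, 2023: 2277},
    serious_counts={Seriousness.SERIOUS: 4161, Seriousness.NON_SERIOUS: 2726},
    soc_record_counts={
        "Psychiatric disorders": 4849,
        "Nervous system disorders": 2435,
        "General disorders and administration site conditions": 2075,
        "Injury, poisoning, and procedural complications": 1136,
        "Gastrointestinal disorders": 1041,
        "Investigations": 500,
        "Vascular disorders": 415,
        "Surgical and medical procedures": 376,
        "Product issues": 282,
        "Respiratory, thoracic, and mediastinal disorders": 273,
        "Infections and infestations": 229,
        "Renal and urinary disorders": 159,
        "Eye disorders": 148,
        "Cardiac disorders": 138,
        "Musculoskeletal and connective tissue disorders": 129,
        "Skin and subcutaneous tissue disorders": 125,
        "Ear and labyrinth disorders": 81,
        "Metabolism and nutrition disorders": 72,
        "Immune system disorders": 37,
        "Benign, malignant, and unspecified neoplasms (including cysts and polyps)": 35,
        "Social circumstances": 24,
        "Hepatobiliary disorders": 24,
        "Pregnancy, puerperium, and perinatal conditions": 14,
        "Endocrine disorders": 5,
        "Reproductive system and breast disorders": 4,
    },
)

demo = demographics_summary(db)
print(f"case denominator: {demo.denominator}")
for sex, (count, pct) in demo.blocks["sex"].items():
    print(f"  {sex:8s} {count:5d}  {pct:5.2f}%")
serious = demo.blocks["seriousness"]["serious"]
print(f"  serious  {serious[0]:5d}  {serious[1]:5.2f}%")

socs = soc_summary(db, target_ingredient="esketamine")
print(f"\nreaction-record denominator: {socs.denominator}")
for soc, (count, pct, _) in list(socs.rows.items())[:5]:
    print(f"  {soc:55s} {count:5d}  {pct:5.2f}%")
print(f"  ... and {len(socs.rows) - 5} smaller organ classes")
print("\nPercentages use two denominators on purpose: demographic blocks "
      "are per case, SOC blocks are per reaction record.")
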