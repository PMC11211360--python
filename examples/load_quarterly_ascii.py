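"""Load a FAERS-style quarterly ASCII extract (dollar-delimited tables).

Writes a miniature DEMO/DRUG/REAC/OUTC fixture to a temporary directory,
loads it, and shows the joined case reports.  Real quarterly files use the
same column subset at scale.
"""

import tempfile
from pathlib import Path

from pvsignal import load_faers_ascii, select_target_reports

FILES = {
    "demo.txt": (
        "primaryid$caseid$caseversion$sex$age$age_cod$occr_country$occp_cod$event_dt\n"
        "1001$100$1$F$34$YR$US$MD$20200110\n"
        "1002$101$0$M$52$YR$FR$CN$20210302\n"
        "1003$102$0$F$29$YR$US$MD$20220815\n"
    ),
    "drug.txt": (
        "primaryid$drugname$prod_ai$role_cod\n"
        "1001$SPRAVATO$ESKETAMINE$PS\n"
        "1001$ZOLOFT$SERTRALINE$C\n"
        "1002$SPRAVATO$ESKETAMINE$PS\n"
        "1003$SEROQUEL$QUETIAPINE$PS\n"
    ),
    "reac.txt": (
        "primaryid$pt\n"
        "1001$Dissociation\n"
        "1001$Sedation\n"
        "1002$Nausea\n"
        "1003$Somnolence\n"
    ),
    "outc.txt": "primaryid$outc_cod\n1001$HO\n",
}

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    for name, content in FILES.items():
        (root / name).write_text(content)
    db = load_faers_ascii(root / "demo.txt", root / "drug.txt",
                          root / "reac.txt", root / "outc.txt")

print(f"loaded {len(db)} case reports")
for r in db.reports:
    drugs = ", ".join(f"{d.active_ingredient} ({d.role.value})"
                      for d in r.drugs)
    pts = ", ".join(f"{x.pt} [{x.soc}]" for x in r.reactions)
    print(f"  case {r.case_id} v{r.version} {r.sex.value:7s} "
          f"{r.seriousness.value:11s} drugs: {drugs}; reactions: {pts}")

target = select_target_reports(db, "esketamine")
print(f"\n{len(target)} reports name esketamine as the primary suspect — "
      "the subset a target-drug analysis keeps.")
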