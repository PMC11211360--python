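"""Domain types, FAERS-style loaders and the PT->SOC mapping."""

from __future__ import annotations

import textwrap

import pytest

from pvsignal import (
    AgeGroup,
    DrugRole,
    FormatError,
    Sex,
    default_config,
    generate_database,
    load_dashboard_csv,
    load_faers_ascii,
    map_pt_to_soc,
    write_dashboard_csv,
)
from pvsignal.types import DrugMention, age_group_from_years, normalize_ingredient


class TestAgeGrouping:
    @pytest.mark.parametrize(
        "age, expected",
        [
            (0, AgeGroup.UNDER_18),
            (17.9, AgeGroup.UNDER_18),
            (18, AgeGroup.ADULT),       # boundary goes to the higher bin
            (64.9, AgeGroup.ADULT),
            (65, AgeGroup.ELDERLY),     # boundary goes to the higher bin
            (90, AgeGroup.ELDERLY),
            (None, AgeGroup.UNKNOWN),
        ],
    )
    def test_bins(self, age, expected):
        assert age_group_from_years(age) == expected


class TestDrugNormalization:
    def test_case_and_punctuation_insensitive(self):
        assert normalize_ingredient("ESKETAMINE ") == "esketamine"
        assert normalize_ingredient("Esketamine-Hydrochloride") == \
            "esketamine hydrochloride"

    def test_product_name_resolves_target(self):
        m = DrugMention("ESKETAMINE", DrugRole.PRIMARY_SUSPECT,
                        product_name="SPRAVATO")
        assert m.matches("esketamine")
        assert m.matches("Spravato")
        assert not m.matches("ketamine")


class TestPtSocMapping:
    @pytest.mark.parametrize(
        "pt, soc",
        [
            ("Dissociation", "Psychiatric disorders"),
            ("Sedation", "Nervous system disorders"),
            ("Zzz-not-a-term", "Unmapped"),
        ],
    )
    def test_lookup(self, pt, soc):
        assert map_pt_to_soc(pt) == soc

    def test_lookup_is_case_insensitive(self):
        assert map_pt_to_soc("dissociation") == "Psychiatric disorders"


def _write_ascii_fixture(tmp_path):
    """Five primaryids across the four quarterly tables."""
    demo = textwrap.dedent("""\
        primaryid$caseid$caseversion$sex$age$age_cod$wt$occr_country$occp_cod$event_dt$fda_dt
        1001$100$1$F$34$YR$70$US$MD$20200110$20200115
        1002$101$0$M$17$YR$$US$CN$20210302$20210310
        1003$102$0$U$70$YR$80$FR$PH$$20220101
        1004$103$2$F$540$MON$65$BR$$20230505$20230510
        1005$104$0$$$$$$$$20190401
        """)
    drug = textwrap.dedent("""\
        primaryid$drugname$prod_ai$role_cod
        1001$SPRAVATO$ESKETAMINE$PS
        1001$ZOLOFT$SERTRALINE$C
        1002$SPRAVATO$ESKETAMINE$PS
        1003$SEROQUEL$QUETIAPINE$PS
        1003$SPRAVATO$ESKETAMINE$C
        1004$SPRAVATO$ESKETAMINE$PS
        1005$LITHIUM$LITHIUM$PS
        """)
    reac = textwrap.dedent("""\
        primaryid$pt
        1001$Dissociation
        1001$Sedation
        1002$Nausea
        1003$Dizziness
        1004$Suicidal ideation
        1004$Dissociation
        1005$Headache
        """)
    outc = textwrap.dedent("""\
        primaryid$outc_cod
        1001$HO
        1004$DE
        1004$HO
        """)
    paths = {}
    for name, content in [("demo", demo), ("drug", drug),
                          ("reac", reac), ("outc", outc)]:
        p = tmp_path / f"{name}.txt"
        p.write_text(content)
        paths[name] = p
    return paths


class TestFaersAsciiLoader:
    def test_join_cardinalities(self, tmp_path):
        p = _write_ascii_fixture(tmp_path)
        db = load_faers_ascii(p["demo"], p["drug"], p["reac"], p["outc"])
        assert len(db) == 5
        by_case = {r.case_id: r for r in db.reports}
        assert set(by_case) == {"100", "101", "102", "103", "104"}
        # hand-joined cardinalities
        assert len(by_case["100"].drugs) == 2
        assert len(by_case["100"].reactions) == 2
        assert len(by_case["102"].drugs) == 2
        assert len(by_case["103"].reactions) == 2
        assert len(by_case["104"].drugs) == 1
        # versions from caseversion column
        assert by_case["100"].version == 1
        assert by_case["103"].version == 2

    def test_field_parsing(self, tmp_path):
        p = _write_ascii_fixture(tmp_path)
        db = load_faers_ascii(p["demo"], p["drug"], p["reac"], p["outc"])
        by_case = {r.case_id: r for r in db.reports}
        assert by_case["100"].sex == Sex.FEMALE
        assert by_case["100"].age_group == AgeGroup.ADULT
        assert by_case["100"].seriousness.value == "serious"
        assert by_case["101"].age_group == AgeGroup.UNDER_18
        assert by_case["102"].age_group == AgeGroup.ELDERLY
        # 540 months = 45 years
        assert by_case["103"].age_group == AgeGroup.ADULT
        assert "death" in {o.value for o in by_case["103"].serious_outcomes}
        # unparseable optional fields degrade to unknown, row kept
        assert by_case["104"].sex == Sex.UNKNOWN
        assert by_case["104"].age_group == AgeGroup.UNKNOWN
        assert by_case["104"].seriousness.value == "non_serious"
        assert by_case["100"].has_drug("esketamine", DrugRole.PRIMARY_SUSPECT)
        assert not by_case["102"].has_drug("esketamine", DrugRole.PRIMARY_SUSPECT)

    def test_header_only_files_give_empty_database(self, tmp_path):
        for name, header in [("demo", "primaryid$caseid"),
                             ("drug", "primaryid$drugname$role_cod"),
                             ("reac", "primaryid$pt"),
                             ("outc", "primaryid$outc_cod")]:
            (tmp_path / f"{name}.txt").write_text(header + "\n")
        with pytest.warns(UserWarning):
            db = load_faers_ascii(tmp_path / "demo.txt", tmp_path / "drug.txt",
                                  tmp_path / "reac.txt", tmp_path / "outc.txt")
        assert len(db) == 0

    def test_missing_role_cod_is_format_error(self, tmp_path):
        p = _write_ascii_fixture(tmp_path)
        bad = tmp_path / "drug_bad.txt"
        bad.write_text("primaryid$drugname$prod_ai\n1001$SPRAVATO$ESKETAMINE\n")
        with pytest.raises(FormatError, match="role_cod"):
            load_faers_ascii(p["demo"], bad, p["reac"], p["outc"])


class TestDashboardCsv:
    def test_semicolon_reaction_split(self, tmp_path):
        csv = tmp_path / "dash.csv"
        csv.write_text(
            "case_id,version,sex,reactions,drugs,received_year\n"
            "A1,0,F,Dissociation; Sedation,esketamine:primary_suspect,2020\n"
            "A2,0,M,Nausea,quetiapine:primary_suspect,2021\n"
            "A3,0,U,Headache,esketamine:concomitant,2021\n"
        )
        db = load_dashboard_csv(csv)
        assert len(db) == 3
        first = db.reports[0]
        assert [r.pt for r in first.reactions] == ["Dissociation", "Sedation"]
        assert first.reactions[0].soc == "Psychiatric disorders"
        # unknown sex code falls back to unknown
        assert db.reports[2].sex == Sex.UNKNOWN

    def test_column_mapping(self, tmp_path):
        csv = tmp_path / "dash.csv"
        csv.write_text(
            "Case ID,Reactions,Suspect Product Active Ingredients\n"
            "B1,Sedation,esketamine\n"
        )
        db = load_dashboard_csv(csv, column_map={
            "case_id": "case id",
            "reactions": "reactions",
            "drugs": "suspect product active ingredients",
        })
        assert len(db) == 1
        assert db.reports[0].drugs[0].role == DrugRole.PRIMARY_SUSPECT

    def test_trailing_digit_version_heuristic(self, tmp_path):
        csv = tmp_path / "dash.csv"
        csv.write_text(
            "case_id,reactions\n"
            "1234567,Nausea\n"
        )
        db = load_dashboard_csv(csv)
        assert db.reports[0].case_id == "123456"
        assert db.reports[0].version == 7

    def test_round_trip_preserves_counted_fields(self, tmp_path, generated):
        _, db, _ = generated
        out = tmp_path / "rt.csv"
        write_dashboard_csv(db, out)
        back = load_dashboard_csv(out)
        assert len(back) == len(db)
        for orig, rt in zip(db.reports, back.reports):
            assert rt.case_id == orig.case_id
            assert rt.version == orig.version
            assert sorted(r.pt for r in rt.reactions) == \
                sorted(r.pt for r in orig.reactions)
            assert rt.sex == orig.sex
            assert rt.age_group == orig.age_group
            assert rt.reporter_type == orig.reporter_type
            assert rt.seriousness == orig.seriousness
            assert rt.country == orig.country
            assert rt.received_year == orig.received_year
            assert rt.event_date == orig.event_date
            assert {(d.active_ingredient, d.role) for d in rt.drugs} == \
                {(d.active_ingredient, d.role) for d in orig.drugs}


def test_soc_consistency_database_wide(generated):
    """Every stored SOC equals the mapping's answer for its PT."""
    _, db, _ = generated
    for r in db.reports:
        for rec in r.reactions:
            assert rec.soc == map_pt_to_soc(rec.pt)


def test_generate_database_rejects_invalid_config():
    cfg = default_config(n_reports=10, seed=0, duplicate_rate=1.0)
    with pytest.raises(ValueError):
        generate_database(cfg)
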