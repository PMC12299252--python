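import math
import random

import pytest

from screenclean import activity_io
from screenclean.activity_io import (
    CHEMBL_COLMAP,
    ColumnMap,
    ColumnMapError,
    read_activity_table,
    read_dock_scores,
    read_interaction_table,
    write_activity_table,
)
from screenclean.records import ActivityRecord, CuratedDataset

from conftest import make_record


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestReadActivityTable:
    def test_three_row_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        write_lines(p, [
            "molecule_id,smiles,standard_type,value,units,relation,assay_id",
            "M1,CCO,IC50,100,nM,=,A1",
            "M2,CCC,IC50,200,nM,=,A1",
            "M3,CCN,IC50,5,uM,=,A2",
        ])
        ds = read_activity_table(p)
        assert ds.stage == "raw"
        assert len(ds.records) == 3
        assert [r.molecule_id for r in ds.records] == ["M1", "M2", "M3"]
        assert ds.provenance[0].step == "read_activity_table"

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        p = tmp_path / "t.csv"
        write_lines(p, ["molecule_id,smiles,standard_type,value,units,relation", "M1,CCO,IC50,1,nM,="])
        with pytest.raises(ColumnMapError, match="assay_id"):
            read_activity_table(p)

    def test_chembl_dialect(self, tmp_path):
        p = tmp_path / "chembl.csv"
        write_lines(p, [
            '"Molecule ChEMBL ID","Smiles","Standard Type","Standard Value","Standard Units",'
            '"Standard Relation","Assay ChEMBL ID","Assay Description","Source ID"',
            "CHEMBL1,CCO,IC50,57,nM,'=',CHEMBL-A1,binding assay,1",
            "CHEMBL2,c1ccccc1,IC50,2.5,uM,'>',CHEMBL-A2,functional assay,1",
        ])
        ds = read_activity_table(p, CHEMBL_COLMAP)
        assert len(ds.records) == 2
        r1, r2 = ds.records
        assert r1.molecule_id == "CHEMBL1"
        assert r1.smiles_raw == "CCO"
        assert r1.standard_type == "IC50"
        assert r1.value == 57.0
        assert r1.units == "nM"
        assert r1.relation == "="
        assert r1.assay_id == "CHEMBL-A1"
        assert r1.assay_description == "binding assay"
        assert r2.value == 2.5
        assert r2.relation == ">"

    def test_tab_delimited_autodetected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(p, [
            "molecule_id\tsmiles\tstandard_type\tvalue\tunits\trelation\tassay_id",
            "M1\tCCO\tIC50\t100\tnM\t=\tA1",
        ])
        assert len(read_activity_table(p).records) == 1

    def test_unparseable_value_retained_as_missing(self, tmp_path):
        p = tmp_path / "t.csv"
        write_lines(p, [
            "molecule_id,smiles,standard_type,value,units,relation,assay_id",
            "M1,CCO,IC50,not_a_number,nM,=,A1",
        ])
        ds = read_activity_table(p)
        assert len(ds.records) == 1
        assert ds.records[0].value is None

    def test_colmap_requires_all_fields(self):
        with pytest.raises(ColumnMapError):
            ColumnMap(mapping={"molecule_id": "id"})


class TestRoundTrip:
    def test_five_records(self, tmp_path):
        recs = [make_record(mol=f"M{i}", assay=f"A{i % 2}", value=float(i + 1)) for i in range(5)]
        ds = CuratedDataset(records=recs, stage="raw")
        p = tmp_path / "out.csv"
        write_activity_table(ds, p)
        back = read_activity_table(p)
        assert back.records == recs

    def test_empty_dataset_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_activity_table(CuratedDataset(records=[]), tmp_path / "x.csv")

    def test_unicode_description_preserved(self, tmp_path):
        rec = make_record(assay_description="Kd à 25 °C — ± contrôle µM")
        ds = CuratedDataset(records=[rec], stage="raw")
        p = tmp_path / "u.csv"
        write_activity_table(ds, p)
        assert read_activity_table(p).records[0].assay_description == rec.assay_description

    def test_round_trip_random_fixtures(self, tmp_path):
        rng = random.Random(7)
        for trial in range(20):
            recs = []
            for i in range(rng.randint(1, 15)):
                recs.append(
                    ActivityRecord(
                        molecule_id=f"M{rng.randint(0, 5)}",
                        smiles_raw=rng.choice(["CCO", "c1ccccc1", "CC(=O)O"]),
                        standard_type=rng.choice(["IC50", "Ki"]),
                        value=rng.choice([None, round(rng.uniform(0.1, 1e4), 4)]),
                        units=rng.choice([None, "nM", "uM"]),
                        relation=rng.choice([None, "=", ">", "<"]),
                        assay_id=f"A{rng.randint(0, 3)}",
                        smiles_std=rng.choice([None, "CCO"]),
                        pic50=rng.choice([None, round(rng.uniform(4, 9), 6)]),
                    )
                )
            ds = CuratedDataset(records=recs, stage="raw")
            p = tmp_path / f"rt{trial}.csv"
            write_activity_table(ds, p)
            assert read_activity_table(p).records == recs


class TestReadDockScores:
    TABLE5 = [
        "Ligand,MDM4,BCL2,MDM2_p1,MDM2_p2,Vina_MDM2,GOLD_MDM2",
        "MP,−9.6,−6.6,−7.6,−7.1,−7.7,72.7",
        "OT,−9.4,−7.4,−7.5,−6.9,−8.1,64.0",
        "AT,−11.1,−7.3,−8.4,−8.1,−7.8,61.4",
        "BI,−10.1,−7.1,−7.4,−7.5,−8.0,65.4",
        "DR,−9.3,−6.4,−7.2,−6.8,−8.0,72.1",
    ]

    def test_five_ligand_layout(self, tmp_path):
        p = tmp_path / "t5.csv"
        write_lines(p, self.TABLE5)
        rows = read_dock_scores(p)
        assert len(rows) == 5
        assert rows[0].ligand_id == "MP"
        assert rows[0].score("MDM4") == -9.6  # unicode minus normalized
        assert rows[2].score("GOLD_MDM2") == 61.4

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        assert read_dock_scores(p) == []

    def test_blank_cell_is_absent_not_zero(self, tmp_path):
        p = tmp_path / "b.csv"
        write_lines(p, ["Ligand,BCL2,MDM2_p1", "MP,,−7.6"])
        rows = read_dock_scores(p)
        assert rows[0].score("BCL2") is None
        assert rows[0].score("MDM2_p1") == -7.6

    def test_duplicate_ligand_errors(self, tmp_path):
        p = tmp_path / "d.csv"
        write_lines(p, ["Ligand,MDM2_p1", "MP,−7.6", "MP,−7.0"])
        with pytest.raises(ValueError, match="MP"):
            read_dock_scores(p)


class TestReadInteractionTable:
    def test_four_row_fixture(self, tmp_path):
        p = tmp_path / "i.csv"
        write_lines(p, [
            "residue,ligand,interaction,energy",
            "Arg65,MP,hydrogen bond,-3.2",
            "Leu54,AT,hydrogen bond,-4.1",
            "Ile61,MP,C-H...F,-1.5",
            "Gln72,AT,hydrogen bond,-0.4",
        ])
        recs = read_interaction_table(p)
        assert len(recs) == 4
        assert recs[0].residue == "Arg65"
        assert recs[1].energy == -4.1

    def test_unicode_minus_energy(self, tmp_path):
        p = tmp_path / "u.csv"
        write_lines(p, ["residue,ligand,interaction,energy", "Arg65,MP,hb,−2.0"])
        assert read_interaction_table(p)[0].energy == -2.0

    def test_missing_ligand_column_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        write_lines(p, ["residue,interaction,energy", "Arg65,hb,-2.0"])
        with pytest.raises(ColumnMapError, match="ligand"):
            read_interaction_table(p)

    def test_non_numeric_energy_names_row(self, tmp_path):
        p = tmp_path / "n.csv"
        write_lines(p, [
            "residue,ligand,interaction,energy",
            "Arg65,MP,hb,-2.0",
            "Leu54,MP,hb,strong",
        ])
        with pytest.raises(ValueError, match=":3"):
            read_interaction_table(p)


def test_parse_number_missing_tokens():
    for token in ("", "  ", "NA", "nan", "None"):
        assert activity_io.parse_number(token) is None
    assert activity_io.parse_number("−1.5") == -1.5
    assert math.isclose(activity_io.parse_number("1e-3"), 1e-3)
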