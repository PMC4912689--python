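import numpy as np
import pandas as pd
import pytest

from alascan.datamodel import HeatCategory, SummaryClass
from alascan.simulate import make_synthetic_structure
from alascan.structure import (
    DEFAULT_REGIONS,
    RegionDefinition,
    assign_regions,
    read_structure_annotation,
    summarize_across_ligands,
    summarize_table,
    write_legend,
    write_structure_annotation,
)

R = HeatCategory.fold_5_10
NE = HeatCategory.no_effect
EN = HeatCategory.enhanced
ND = HeatCategory.not_determined


class TestRegions:
    def test_bundled_loop_sizes(self):
        sizes = {r.name: len(r) for r in DEFAULT_REGIONS}
        assert sizes == {"ECL1": 23, "ECL2": 23, "ECL3": 16}

    def test_assignment_covers_spans_and_other(self):
        out = assign_regions([201, 223, 285, 307, 372, 387, 250]).set_index("position")
        assert out.loc[201, "region"] == out.loc[223, "region"] == "ECL1"
        assert out.loc[285, "region"] == out.loc[307, "region"] == "ECL2"
        assert out.loc[372, "region"] == out.loc[387, "region"] == "ECL3"
        assert out.loc[250, "region"] == "other"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assign_regions([1], [RegionDefinition("A", 1, 10),
                                 RegionDefinition("B", 10, 20)])

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            RegionDefinition("X", 10, 5)


class TestSummary:
    @pytest.mark.parametrize("cats,expected", [
        ({"GLP-1": R, "oxm": R, "ex4": R}, SummaryClass.global_all_ligands),
        ({"GLP-1": R, "oxm": NE, "ex4": NE}, SummaryClass.selective_single_ligand),
        ({"GLP-1": R, "oxm": NE, "ex4": R}, SummaryClass.shared_two_ligands),
        ({"GLP-1": EN, "oxm": NE, "ex4": EN}, SummaryClass.enhanced),
        ({"GLP-1": EN, "oxm": R, "ex4": EN}, SummaryClass.mixed),
        ({"GLP-1": NE, "oxm": NE, "ex4": NE}, SummaryClass.none),
        ({"GLP-1": ND, "oxm": ND, "ex4": ND}, SummaryClass.none),
    ])
    def test_summary_rules(self, cats, expected):
        assert summarize_across_ligands(cats) is expected

    def test_permutation_invariance(self):
        cats = {"GLP-1": R, "oxm": NE, "ex4": EN}
        perms = [dict(list(cats.items())[i:] + list(cats.items())[:i])
                 for i in range(3)]
        results = {summarize_across_ligands(p) for p in perms}
        assert len(results) == 1

    def test_summary_table_merges_regions(self):
        heat = pd.DataFrame({
            "position": [201, 201, 380, 380],
            "ligand_id": ["GLP-1", "oxm", "GLP-1", "oxm"],
            "category": [R.value, R.value, R.value, NE.value],
        })
        out = summarize_table(heat, wootten={380: "6.58"}).set_index("position")
        assert out.loc[201, "summary_class"] == "global_all_ligands"
        assert out.loc[380, "summary_class"] == "selective_single_ligand"
        assert out.loc[201, "region"] == "ECL1"
        assert out.loc[380, "wootten_number"] == "6.58"


@pytest.fixture()
def panel_positions():
    # 56-residue scan panel within the loop spans
    return (list(range(201, 224)) + list(range(285, 302))
            + list(range(372, 388)))


class TestStructureAnnotation:
    def test_round_trip_recovers_every_category(self, tmp_path, panel_positions):
        pdb_in = tmp_path / "synthetic.pdb"
        make_synthetic_structure(panel_positions, pdb_in)
        cats = {p: list(HeatCategory)[i % len(HeatCategory)]
                for i, p in enumerate(panel_positions)}
        out_pdb, out_tsv = write_structure_annotation(
            cats, pdb_in, tmp_path / "heat.pdb", tmp_path / "heat.tsv")
        recovered = read_structure_annotation(out_pdb)
        assert recovered == cats
        tsv = pd.read_csv(out_tsv, sep="\t")
        assert len(tsv) == len(cats)
        assert set(tsv.columns) == {"position", "region", "category", "code"}

    def test_single_residue_mapping_and_sentinel(self, tmp_path):
        pdb_in = tmp_path / "toy.pdb"
        make_synthetic_structure([201, 202, 203], pdb_in)
        out_pdb, _ = write_structure_annotation(
            {201: HeatCategory.fold_3_5}, pdb_in, tmp_path / "o.pdb")
        from biotite.structure.io.pdb import PDBFile
        atoms = PDBFile.read(str(out_pdb)).get_structure(
            model=1, extra_fields=["b_factor"])
        assert atoms.b_factor[atoms.res_id == 201][0] == pytest.approx(1.0)
        assert atoms.b_factor[atoms.res_id == 202][0] == pytest.approx(-9.99)

    def test_empty_annotation_is_all_sentinel(self, tmp_path):
        pdb_in = tmp_path / "toy.pdb"
        make_synthetic_structure([1, 2, 3], pdb_in)
        out_pdb, out_tsv = write_structure_annotation(
            {}, pdb_in, tmp_path / "o.pdb", tmp_path / "o.tsv")
        assert read_structure_annotation(out_pdb) == {}
        assert pd.read_csv(out_tsv, sep="\t").empty

    def test_missing_positions_warn_or_error(self, tmp_path):
        pdb_in = tmp_path / "toy.pdb"
        make_synthetic_structure(list(range(201, 211)), pdb_in)
        cats10 = {p: HeatCategory.fold_3_5 for p in range(201, 211)}
        with pytest.warns(UserWarning, match="missing"):
            write_structure_annotation({**cats10, 999: HeatCategory.enhanced},
                                       pdb_in, tmp_path / "a.pdb")
        with pytest.raises(ValueError, match="offset"):
            write_structure_annotation(cats10, pdb_in, tmp_path / "b.pdb",
                                       offset=500)

    def test_offset_maps_numbering(self, tmp_path):
        pdb_in = tmp_path / "toy.pdb"
        make_synthetic_structure([101, 102], pdb_in)  # structure numbering -100
        out_pdb, _ = write_structure_annotation(
            {201: HeatCategory.fold_10_30}, pdb_in, tmp_path / "o.pdb", offset=-100)
        assert read_structure_annotation(out_pdb) == {101: HeatCategory.fold_10_30}

    def test_legend_json(self, tmp_path):
        import json
        path = write_legend(tmp_path / "legend.json")
        legend = json.loads(path.read_text())
        assert legend["no_effect"]["color"] == "teal"
        assert legend["fold_gt_30"] == {"code": 4, "color": "red"}
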