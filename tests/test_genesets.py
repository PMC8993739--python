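"""GO mining, ortholog mapping, signature and stage-set derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from musclegrn import genesets
from musclegrn.io import ExpressionMatrix, GeneSet
from musclegrn.synthetic import SynthConfig, gen_consensus_nx, gen_stagewise_profiles

from conftest import STAGES


def _annotations(rows):
    return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_term", "ontology"])


class TestGoMining:
    def test_substring_match(self):
        table = _annotations([("G1", "GO:0000001", "skeletal muscle fiber development", "BP")])
        go_ids, genes = genesets.mine_go_annotations(table, ["skeletal muscle"])
        assert go_ids == ["GO:0000001"] and genes.members == ("G1",)

    def test_variant_spelling_not_matched(self):
        table = _annotations([("G1", "GO:0000002", "Z disc assembly", "CC")])
        go_ids, genes = genesets.mine_go_annotations(table, ["Z disk"])
        assert go_ids == [] and len(genes) == 0

    def test_case_insensitive(self):
        table = _annotations([("G1", "GO:0000003", "Striated Muscle contraction", "BP")])
        go_ids, _ = genesets.mine_go_annotations(table, ["striated muscle"])
        assert go_ids == ["GO:0000003"]

    def test_planted_gene_count_recovered(self):
        # 1289 genes annotated to matching terms, plus decoys on other terms
        rows = [(f"M{i:04d}", "GO:0001111", "myoblast fusion", "BP") for i in range(1289)]
        rows += [(f"X{i:04d}", "GO:0002222", "neuronal migration", "BP") for i in range(300)]
        _, genes = genesets.mine_go_annotations(_annotations(rows), ["myoblast"])
        assert len(genes) == 1289

    def test_union_over_matched_terms_deduplicated(self):
        rows = [("G1", "GO:0000001", "muscle fiber", "BP"),
                ("G1", "GO:0000004", "actin binding", "MF"),
                ("G2", "GO:0000004", "actin binding", "MF")]
        _, genes = genesets.mine_go_annotations(_annotations(rows), ["muscle", "actin"])
        assert sorted(genes.members) == ["G1", "G2"]

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            genesets.mine_go_annotations(_annotations([]), [])

    def test_gaf_reader(self, tmp_path):
        p = tmp_path / "anno.gaf"
        p.write_text("!gaf-version: 2.2\n" +
                     "\t".join(["MGI", "MGI:1", "Myod1", "", "GO:0007517", "ref",
                                "IDA", "", "P", "", "", "", "", "", ""]) + "\n")
        df = genesets.read_gaf(p)
        assert df.iloc[0]["gene_id"] == "Myod1"
        assert df.iloc[0]["ontology"] == "BP"


class TestOrthologMapping:
    def test_planted_coverage(self):
        genes = GeneSet("mouse", "", tuple(f"m{i:04d}" for i in range(1289)))
        table = pd.DataFrame({"source_gene": [f"m{i:04d}" for i in range(1262)],
                              "target_gene": [f"H{i:04d}" for i in range(1262)]})
        mapped, unmapped, log = genesets.map_orthologs(genes, table)
        assert len(mapped) == 1262 and len(unmapped) == 27

    def test_identity_map(self):
        genes = GeneSet("g", "", ("a", "b"))
        table = pd.DataFrame({"source_gene": ["a", "b"], "target_gene": ["a", "b"]})
        mapped, unmapped, _ = genesets.map_orthologs(genes, table)
        assert mapped.members == ("a", "b") and unmapped == []

    def test_many_to_one_collapsed_and_logged(self):
        genes = GeneSet("g", "", ("a", "b"))
        table = pd.DataFrame({"source_gene": ["a", "b"], "target_gene": ["T", "T"]})
        mapped, _, log = genesets.map_orthologs(genes, table)
        assert mapped.members == ("T",)
        assert any("collapse" in line for line in log)


class TestRestrictedSignature:
    def test_boundary_value_excluded(self):
        vals = pd.DataFrame({"skeletal muscle": [1.0, 1.1], "liver": [0.0, 0.5]},
                            index=["at_threshold", "above"])
        m = ExpressionMatrix(vals, "nx")
        sig = genesets.restricted_signature(m, "skeletal muscle")
        assert sig.members == ("above",)  # NX = 1.0 fails the strict > 1 rule

    def test_expressed_elsewhere_excluded(self):
        vals = pd.DataFrame({"skeletal muscle": [5.0], "liver": [2.0]}, index=["g"])
        sig = genesets.restricted_signature(ExpressionMatrix(vals, "nx"), "skeletal muscle")
        assert len(sig) == 0

    def test_single_tissue_exclusion_vacuous(self):
        vals = pd.DataFrame({"skeletal muscle": [5.0, 0.5]}, index=["hi", "lo"])
        sig = genesets.restricted_signature(ExpressionMatrix(vals, "nx"), "skeletal muscle")
        assert sig.members == ("hi",)

    def test_missing_tissue_rejected(self):
        vals = pd.DataFrame({"liver": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="not in matrix"):
            genesets.restricted_signature(ExpressionMatrix(vals, "nx"), "skeletal muscle")

    @given(st.integers(0, 2 ** 12 - 1))
    def test_matches_brute_force_set_algebra(self, bits):
        # 4 genes x 3 tissues with threshold-crossing patterns from the bitmask
        vals = np.array([[(bits >> (3 * g + t)) & 1 for t in range(3)] for g in range(4)],
                        dtype=float) * 2.0
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(4)],
                          columns=["muscle", "liver", "lung"])
        sig = genesets.restricted_signature(ExpressionMatrix(df, "nx"), "muscle")
        brute = {f"g{i}" for i in range(4)
                 if vals[i, 0] > 1.0 and all(vals[i, t] <= 1.0 for t in (1, 2))}
        assert set(sig.members) == brute


class TestStageOnset:
    def test_lapsed_gene_excluded(self):
        prof = pd.DataFrame([[0.0, 2.0, 2.0, 0.0, 2.0]], index=["lapse"], columns=STAGES)
        onset = genesets.stage_onset_sets(prof)
        assert all(len(gs) == 0 for gs in onset.values())

    def test_always_expressed_gene_first_stage(self):
        prof = pd.DataFrame([[2.0] * 5], index=["g"], columns=STAGES)
        onset = genesets.stage_onset_sets(prof)
        assert onset[STAGES[0]].members == ("g",)

    def test_partition_property(self, cfg):
        prof = gen_stagewise_profiles(STAGES, (10, 8, 6, 4, 2), (3, 2, 0, 0, 0), 50, cfg)
        onset = genesets.stage_onset_sets(prof)
        union = set()
        total = 0
        for gs in onset.values():
            assert not (union & gs.as_set())
            union |= gs.as_set()
            total += len(gs)
        assert len(union) == total == 30


class TestMaintenance:
    def test_constant_gene_excluded(self):
        prof = pd.DataFrame([[2.0] * 5], index=["flat"], columns=STAGES)
        maint, _ = genesets.maintenance_genes(prof)
        assert len(maint) == 0

    def test_decreasing_gene_excluded(self):
        prof = pd.DataFrame([[5.0, 4.0, 3.5, 3.0, 2.5]], index=["down"], columns=STAGES)
        maint, _ = genesets.maintenance_genes(prof)
        assert len(maint) == 0

    def test_increasing_gene_included_with_breakdown(self):
        prof = pd.DataFrame([[2.0, 3.0, 4.0, 5.0, 6.0],
                             [0.5, 2.0, 3.0, 4.0, 5.0]],
                            index=["from_start", "from_presomite"], columns=STAGES)
        maint, breakdown = genesets.maintenance_genes(prof)
        assert sorted(maint.members) == ["from_presomite", "from_start"]
        assert breakdown[STAGES[0]] == 1 and breakdown[STAGES[1]] == 1

    def test_subset_of_onset_union(self, cfg):
        prof = gen_stagewise_profiles(STAGES, (10, 8, 6, 4, 2), (3, 2, 1, 1, 0), 50, cfg)
        onset = genesets.stage_onset_sets(prof)
        maint, _ = genesets.maintenance_genes(prof)
        union = set().union(*(gs.as_set() for gs in onset.values()))
        assert maint.as_set() <= union

    def test_min_rel_increase_threshold(self):
        prof = pd.DataFrame([[2.0, 2.02, 2.04, 2.06, 2.08]], index=["slow"], columns=STAGES)
        maint_loose, _ = genesets.maintenance_genes(prof, min_rel_increase=0.0)
        maint_strict, _ = genesets.maintenance_genes(prof, min_rel_increase=0.05)
        assert len(maint_loose) == 1 and len(maint_strict) == 0


class TestUniqueUpregulated:
    def test_planted_unique_genes(self):
        sets = {"hFB": GeneSet("a", "", ("k1", "k2", "shared")),
                "hADMSC": GeneSet("b", "", ("shared",)),
                "hDFSC": GeneSet("c", "", ("k3", "k4", "shared"))}
        candidates = GeneSet("cand", "", ("k3", "k4", "shared", "other"))
        out = genesets.unique_upregulated(sets, candidates)
        assert sorted(out["hDFSC"].members) == ["k3", "k4"]
        assert len(out["hFB"]) == 0 and len(out["hADMSC"]) == 0

    def test_identical_sets_all_empty(self):
        s = GeneSet("s", "", ("a", "b"))
        out = genesets.unique_upregulated({"x": s, "y": s}, GeneSet("c", "", ("a", "b")))
        assert all(len(gs) == 0 for gs in out.values())

    def test_disjoint_sets_full_universe(self):
        sets = {"x": GeneSet("x", "", ("a",)), "y": GeneSet("y", "", ("b",))}
        cand = GeneSet("c", "", ("a", "b"))
        out = genesets.unique_upregulated(sets, cand)
        assert out["x"].members == ("a",) and out["y"].members == ("b",)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            genesets.unique_upregulated({"x": GeneSet("x", "", ("a",))},
                                        GeneSet("c", "", ("a",)))
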