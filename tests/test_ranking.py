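import numpy as np
import pytest

from scprank.commnet import logfdi
from scprank.dataio import InteractionNetwork
from scprank.mapping import MappingResult
from scprank.ranking import (
    build_report,
    merge_ranks,
    rank_collection,
    union_prioritization,
)


def result(entity, rs, j=1.0, collection="KEGG"):
    matched = j > 0
    return MappingResult(
        entity, collection, ("t",), (1,) if matched else (None,),
        L=1, E=rs * j if matched else rs * 1e-6, J=j, RS=rs,
    )


def flat_comm(names):
    n = len(names)
    net_c = InteractionNetwork("control", tuple(names), np.ones((n, n)))
    net_d = InteractionNetwork("disease", tuple(names), np.ones((n, n)))
    return logfdi(net_c, net_d)


class TestRankCollection:
    def test_ascending_rs(self):
        ranks = rank_collection([result("A", 0), result("B", 5), result("C", 9)])
        assert ranks.to_dict() == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_average_rank_ties(self):
        ranks = rank_collection([result("A", 2), result("B", 2)])
        assert ranks.to_dict() == {"A": 1.5, "B": 1.5}

    def test_single_entity(self):
        assert rank_collection([result("A", 3)]).to_dict() == {"A": 1.0}

    def test_duplicate_entity_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_collection([result("A", 1), result("A", 2)])


class TestMergeRanks:
    def test_mean_over_collections(self):
        per = {
            "KEGG": [result("A", 0), result("B", 5)],
            "WIKI": [result("A", 1, collection="WIKI"), result("B", 9, collection="WIKI")],
        }
        table, used, dropped = merge_ranks(per)
        assert table["mean_rank"].to_dict() == {"A": 1.0, "B": 2.0}
        assert set(used) == {"KEGG", "WIKI"} and dropped == ()

    def test_unmapped_collection_excluded_from_mean(self):
        per = {
            "KEGG": [result("A", 1), result("B", 2)],
            "MSIG": [result("A", 3e6, j=0.0, collection="MSIG"),
                     result("B", 1e6, j=0.0, collection="MSIG")],
        }
        table, used, dropped = merge_ranks(per)
        assert used == ("KEGG",) and dropped == ("MSIG",)
        # MSIG ranks exist in the table but do not feed the mean
        assert table["mean_rank"].to_dict() == {"A": 1.0, "B": 2.0}

    def test_all_collections_unmapped_is_an_error(self):
        per = {"KEGG": [result("A", 1e6, j=0.0), result("B", 2e6, j=0.0)]}
        with pytest.raises(ValueError, match="checklist"):
            merge_ranks(per)


class TestUnion:
    def test_overlap_union(self):
        u = union_prioritization(("A", "B", "C", "D"), ("A", "D", "E"), k=3)
        assert u == {"A", "B", "C", "D", "E"}

    def test_identical_top3_gives_size_3(self):
        u = union_prioritization(("A", "B", "C"), ("A", "B", "C"), k=3)
        assert u == {"A", "B", "C"}

    def test_disjoint_top3_gives_size_6(self):
        u = union_prioritization(("A", "B", "C"), ("D", "E", "F"), k=3)
        assert len(u) == 6


class TestBuildReport:
    def per_collection(self, rs_by_entity):
        return {
            "KEGG": [result(e, rs) for e, rs in rs_by_entity.items()],
        }

    def test_final_order_and_union(self):
        per = self.per_collection({"A": 5, "B": 0, "C": 9, "D": 2})
        report = build_report(per, flat_comm(["A", "B", "C", "D"]), k=3)
        assert report.final_order == ("B", "D", "A", "C")
        # flat comm network: all LogFDI zero, alphabetical order
        assert report.comm_order == ("A", "B", "C", "D")
        # top3 by mean rank {B, D, A} union top3 by |LogFDI| {A, B, C}
        assert report.union_top == {"A", "B", "C", "D"}

    def test_mean_tie_breaks_alphabetical(self):
        per = self.per_collection({"B": 1, "A": 1})
        report = build_report(per, flat_comm(["A", "B"]), k=1)
        assert report.final_order == ("A", "B")

    def test_bulk_ranked_but_never_in_union(self):
        per = self.per_collection({"A": 5, "BULK": 0, "B": 2})
        report = build_report(per, flat_comm(["A", "B"]), k=3)
        assert report.final_order[0] == "BULK"
        assert "BULK" not in report.union_top
        assert report.rank_table.loc["BULK", "KEGG"] == 1.0

    def test_single_collection_order_equals_rs_order(self):
        per = self.per_collection({"A": 3, "B": 1, "C": 2})
        report = build_report(per, flat_comm(["A", "B", "C"]), k=3)
        assert report.final_order == ("B", "C", "A")

    def test_adding_globally_worst_entity_preserves_relative_order(self):
        per = self.per_collection({"A": 3, "B": 1, "C": 2})
        base = build_report(per, flat_comm(["A", "B", "C"]), k=3).final_order
        per_aug = self.per_collection({"A": 3, "B": 1, "C": 2, "Z": 99})
        aug = build_report(per_aug, flat_comm(["A", "B", "C", "Z"]), k=3).final_order
        assert tuple(e for e in aug if e != "Z") == base

    def test_processing_order_invariance(self):
        entities = {"A": 4, "B": 1, "C": 3, "D": 2}
        fwd = {
            "KEGG": [result(e, rs) for e, rs in entities.items()],
            "WIKI": [result(e, rs * 2, collection="WIKI") for e, rs in entities.items()],
        }
        rev = {
            "WIKI": list(reversed(fwd["WIKI"])),
            "KEGG": list(reversed(fwd["KEGG"])),
        }
        comm = flat_comm(list(entities))
        assert build_report(fwd, comm).final_order == build_report(rev, comm).final_order
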