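import dataclasses

import pytest

from markerphyler import (
    AlignmentHit,
    ClassifierSet,
    classify_all,
    classify_read,
    classify_reads,
    detect_novel_clades,
    novel_label,
    read_classifications,
    simulate_reads,
    write_classifications,
)
from markerphyler.classify import ClassifyError, Classification
from markerphyler.taxonomy import rank_index
from markerphyler.training import CutoffRegression


def make_classifiers(tree, gene_taxid, cuts_per_aa):
    """ClassifierSet with flat per-aa cutoff rates per rank."""
    regs = {
        ("g1", rank): CutoffRegression("g1", rank, slope, 0.0, 2, 60, 300)
        for rank, slope in cuts_per_aa.items()
    }
    return ClassifierSet(regs, {"gene_taxids": {"g1": gene_taxid}})


@pytest.fixture()
def flat_setting(tiny_db):
    tree = tiny_db.taxonomy
    taxid = tiny_db.records[0].taxid
    cs = make_classifiers(
        tree, taxid,
        {"genus": 0.5, "family": 0.4, "order": 0.3, "class": 0.2, "phylum": 0.1},
    )
    return tree, taxid, cs


class TestClassifyRead:
    def test_passes_genus_when_above_cutoff(self, flat_setting):
        tree, taxid, cs = flat_setting
        hit = AlignmentHit("r", "g1", bit_score=20.0, hsp_length=30)
        c = classify_read(hit, cs, tree)  # genus cutoff = 0.5*30 = 15
        assert c.assigned_rank == "genus"
        assert c.assigned_taxid == tree.lineage_of(taxid).get("genus")
        assert "{" not in c.display_label

    def test_falls_back_to_family(self, flat_setting):
        tree, taxid, cs = flat_setting
        hit = AlignmentHit("r", "g1", bit_score=14.0, hsp_length=30)
        c = classify_read(hit, cs, tree)  # fails 15, passes 0.4*30 = 12
        assert c.assigned_rank == "family"
        assert c.display_label.endswith("{family}")

    def test_exact_tie_passes(self, flat_setting):
        tree, _, cs = flat_setting
        hit = AlignmentHit("r", "g1", bit_score=15.0, hsp_length=30)
        assert classify_read(hit, cs, tree).assigned_rank == "genus"

    def test_below_all_cutoffs_is_unclassified(self, flat_setting):
        tree, _, cs = flat_setting
        hit = AlignmentHit("r", "g1", bit_score=2.0, hsp_length=30)
        c = classify_read(hit, cs, tree)
        assert not c.is_classified
        assert c.display_label == "unclassified"
        assert c.assigned_taxid is None

    def test_unknown_gene_raises(self, flat_setting):
        tree, _, cs = flat_setting
        with pytest.raises(ClassifyError):
            classify_read(AlignmentHit("r", "nope", 99.0, 30), cs, tree)

    def test_out_of_support_length_flagged_extrapolated(self, flat_setting):
        tree, _, cs = flat_setting
        hit = AlignmentHit("r", "g1", bit_score=200.0, hsp_length=150)
        c = classify_read(hit, cs, tree)
        assert c.is_classified and c.extrapolated


class TestNovelLabel:
    def test_family_level_assignment_carries_suffix(self):
        assert novel_label("Enterobacteriaceae", "family") == \
            "Enterobacteriaceae{family}"

    def test_genus_assignment_is_plain(self):
        assert novel_label("Escherichia", "genus") == "Escherichia"

    def test_phylum_assignment_suffix(self):
        assert novel_label("P", "phylum") == "P{phylum}"


class TestClassifyAll:
    def test_hitless_reads_reported_unclassified_in_order(self, flat_setting):
        tree, _, cs = flat_setting
        grouped = [
            ("a", [AlignmentHit("a", "g1", 20.0, 30)]),
            ("b", []),
            ("c", [AlignmentHit("c", "g1", 20.0, 30)]),
        ]
        out = classify_all(grouped, cs, tree)
        assert [c.read_id for c in out] == ["a", "b", "c"]
        assert not out[1].is_classified

    def test_permuting_reads_permutes_output(self, flat_setting):
        tree, _, cs = flat_setting
        grouped = [
            (rid, [AlignmentHit(rid, "g1", 10.0 + i, 30)])
            for i, rid in enumerate("abcd")
        ]
        fwd = classify_all(grouped, cs, tree)
        rev = classify_all(grouped[::-1], cs, tree)
        assert fwd == rev[::-1]


class TestEndToEnd:
    def test_exact_reads_classify_consistently_with_gene_lineage(
        self, tiny_db, tiny_classifiers
    ):
        """Lineage consistency: every assignment lies on the best-hit
        gene's lineage; and with self genes in the reference, exact reads
        are classified correct at their assigned rank."""
        reads = simulate_reads(tiny_db, 60, 60, 0.0, seed=9)
        cls, best = classify_reads(reads, tiny_db, tiny_classifiers, min_bits=20)
        truth = {r.read_id: r.true_taxid for r in reads}
        n_cls = 0
        for c in cls:
            if not c.is_classified:
                continue
            n_cls += 1
            gene_lineage = tiny_db.taxonomy.lineage_of(
                tiny_db.gene(c.gene_id).taxid)
            assert gene_lineage.get(c.assigned_rank) == c.assigned_taxid
            # correctness vs the read's true source at the assigned rank
            true_lineage = tiny_db.taxonomy.lineage_of(truth[c.read_id])
            assert true_lineage.get(c.assigned_rank) == c.assigned_taxid
        assert n_cls / len(cls) > 0.9

    def test_lowering_cutoffs_only_moves_assignments_down(
        self, tiny_db, tiny_classifiers
    ):
        """Stringency monotonicity under a uniform cutoff reduction."""
        reads = simulate_reads(tiny_db, 60, 60, 0.01, seed=10)
        base, _ = classify_reads(reads, tiny_db, tiny_classifiers, min_bits=20)
        lowered = ClassifierSet(
            {
                key: dataclasses.replace(reg, intercept=reg.intercept - 10.0)
                for key, reg in tiny_classifiers.regressions.items()
            },
            tiny_classifiers.metadata,
        )
        after, _ = classify_reads(reads, tiny_db, lowered, min_bits=20)
        order = {None: 99}
        for a, b in zip(base, after):
            ra = order.get(a.assigned_rank, None)
            ra = 99 if a.assigned_rank is None else rank_index(a.assigned_rank)
            rb = 99 if b.assigned_rank is None else rank_index(b.assigned_rank)
            assert rb <= ra

    def test_classification_table_roundtrip(self, tiny_db, tiny_classifiers,
                                            tmp_path):
        reads = simulate_reads(tiny_db, 60, 90, 0.0, seed=11)
        cls, _ = classify_reads(reads, tiny_db, tiny_classifiers, min_bits=20)
        path = tmp_path / "cls.tsv"
        write_classifications(cls, path)
        again = read_classifications(path)
        assert [c.read_id for c in again] == [c.read_id for c in cls]
        assert [c.assigned_rank for c in again] == [c.assigned_rank for c in cls]
        assert [c.display_label for c in again] == [c.display_label for c in cls]


class TestDetectNovelClades:
    def _cls(self, read_id, rank, taxid, tree):
        return Classification(
            read_id=read_id, gene_id="g", bit_score=50.0, hsp_length=20,
            assigned_rank=rank, assigned_taxid=taxid,
            display_label=novel_label(tree.name(taxid), rank),
        )

    def test_reads_stopped_at_order_flag_the_order(self, tiny_db):
        tree = tiny_db.taxonomy
        order = "p1.c1.o1"
        cls = [self._cls(f"r{i}", "order", order, tree) for i in range(9)]
        report = detect_novel_clades(cls, tree, min_reads=5)
        row = report[report.taxid == order].iloc[0]
        assert row.flagged and row.n_at == 9 and row.n_below == 0
        assert len(row.read_ids.split(",")) == 9

    def test_genus_level_assignments_never_flagged(self, tiny_db):
        tree = tiny_db.taxonomy
        genus = "p1.c1.o1.f1.g1"
        cls = [self._cls(f"r{i}", "genus", genus, tree) for i in range(20)]
        report = detect_novel_clades(cls, tree, min_reads=5)
        assert not report.flagged.any()
        # ancestors see the reads as assigned below them
        fam = report[report.taxid == "p1.c1.o1.f1"].iloc[0]
        assert fam.n_below == 20 and fam.n_at == 0

    def test_below_threshold_not_flagged(self, tiny_db):
        tree = tiny_db.taxonomy
        cls = [self._cls(f"r{i}", "class", "p1.c1", tree) for i in range(3)]
        report = detect_novel_clades(cls, tree, min_reads=5)
        assert not report.flagged.any()
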