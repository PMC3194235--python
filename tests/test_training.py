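import random

import numpy as np
import pytest

from markerphyler import (
    AlignmentHit,
    find_cutoff,
    fit_cutoff_regression,
    load_classifiers,
    partition_scores,
    save_classifiers,
    train_all,
)
from markerphyler.training import (
    GeneRankUnresolved,
    LengthCutoff,
    ScorePartition,
    TrainingError,
    default_read_lengths,
)
from tests.conftest import cutoff_oracle


def part(level, else_, gene="g", rank="genus", length=60):
    return ScorePartition(gene, rank, length, list(level), list(else_))


@pytest.fixture(scope="module")
def setting(tiny_db):
    return _partition_setting(tiny_db)


def _partition_setting(tiny_db):
    gene = tiny_db.records[0]  # dnaG of genus p1.c1.o1.f1.g1
    sibling = next(
        r for r in tiny_db.records
        if r.family == gene.family and r.taxid != gene.taxid
        and tiny_db.taxonomy.lineage_of(r.taxid).get("family")
        == tiny_db.taxonomy.lineage_of(gene.taxid).get("family")
    )
    other = next(
        r for r in tiny_db.records
        if tiny_db.taxonomy.lineage_of(r.taxid).get("family")
        != tiny_db.taxonomy.lineage_of(gene.taxid).get("family")
    )
    hits = [
        AlignmentHit("read_sib", gene.gene_id, 50.0, 20),
        AlignmentHit("read_other", gene.gene_id, 30.0, 20),
        AlignmentHit("read_neg", gene.gene_id, 22.0, 20),
        AlignmentHit("read_self", gene.gene_id, 60.0, 20),
    ]
    truth = {
        "read_sib": (sibling.taxid, sibling.gene_id),
        "read_other": (other.taxid, other.gene_id),
        "read_neg": (None, None),
        "read_self": (gene.taxid, gene.gene_id),
    }
    return gene, hits, truth, tiny_db.taxonomy


class TestPartitionScores:
    def test_family_rank_partition(self, setting):
        gene, hits, truth, tax = setting
        p = partition_scores(gene, hits, truth, "family", tax)
        assert p.b_level == [50.0]
        assert sorted(p.b_else) == [22.0, 30.0]

    def test_self_reads_excluded_entirely(self, setting):
        gene, hits, truth, tax = setting
        for rank in ("genus", "family", "phylum"):
            p = partition_scores(gene, hits, truth, rank, tax)
            assert 60.0 not in p.b_level + p.b_else

    def test_no_hits_gives_empty_vectors(self, setting):
        gene, _, truth, tax = setting
        p = partition_scores(gene, [], truth, "family", tax)
        assert p.b_level == [] and p.b_else == []

    def test_unresolvable_rank_signalled(self, tiny_db):
        from markerphyler.refdb import MarkerDB
        from markerphyler.taxonomy import TaxonNode, TaxonomyTree
        # gene attached directly under the root: no genus in its lineage
        tree = TaxonomyTree([
            TaxonNode("root", "root", "root", "root"),
            TaxonNode("x", "root", "no_rank", "x"),
        ])
        from markerphyler.refdb import MarkerGeneRecord
        gene = MarkerGeneRecord("g", "dnaG", "x", "M" * 60, "ATG" * 60)
        with pytest.raises(GeneRankUnresolved):
            partition_scores(gene, [], {}, "genus", tree)


class TestFindCutoff:
    def test_separable_takes_smallest_positive(self):
        lc = find_cutoff(part([50.0], [10.0]))
        assert (lc.b_cut, lc.error_count) == (50.0, 0)

    def test_overlapping_takes_largest_minimiser(self):
        # candidates {30,40,45,50,51} -> err {2,1,2,1,2}; minimisers {40,50}
        lc = find_cutoff(part([50.0, 40.0], [30.0, 45.0]))
        assert (lc.b_cut, lc.error_count) == (50.0, 1)

    def test_empty_positive_side_rejects_everything(self):
        lc = find_cutoff(part([], [20.0, 30.0]))
        assert (lc.b_cut, lc.error_count) == (31.0, 0)

    def test_empty_negative_side_accepts_from_minimum(self):
        lc = find_cutoff(part([40.0, 55.0], []))
        assert (lc.b_cut, lc.error_count) == (40.0, 0)

    def test_both_empty_raises(self):
        with pytest.raises(TrainingError):
            find_cutoff(part([], []))

    def test_monotone_separation_property(self):
        rng = random.Random(0)
        for _ in range(50):
            level = [rng.uniform(50, 80) for _ in range(rng.randint(1, 20))]
            else_ = [rng.uniform(10, 49) for _ in range(rng.randint(1, 20))]
            lc = find_cutoff(part(level, else_))
            assert lc.error_count == 0
            assert lc.b_cut == min(level)

    def test_invariant_to_input_order(self):
        level, else_ = [50.0, 40.0, 45.0], [30.0, 45.0, 20.0]
        a = find_cutoff(part(level, else_))
        b = find_cutoff(part(level[::-1], else_[::-1]))
        assert (a.b_cut, a.error_count) == (b.b_cut, b.error_count)

    def test_matches_bruteforce_oracle_on_random_partitions(self):
        rng = random.Random(7)
        for _ in range(200):
            n1, n2 = rng.randint(0, 50), rng.randint(0, 50)
            if n1 + n2 == 0:
                continue
            level = [round(rng.gauss(60, 15), 2) for _ in range(n1)]
            else_ = [round(rng.expovariate(0.05), 2) for _ in range(n2)]
            lc = find_cutoff(part(level, else_))
            b, err = cutoff_oracle(level, else_)
            assert lc.error_count == err
            assert lc.b_cut == b


class TestFitCutoffRegression:
    def mk(self, pairs):
        return [LengthCutoff("g", "genus", L, b, 0) for L, b in pairs]

    def test_collinear_points_recovered_exactly(self):
        reg = fit_cutoff_regression(self.mk([(60, 30.0), (120, 60.0), (180, 90.0)]))
        # b_cut = 1.5 per aa (0.5 per nt), zero intercept
        assert reg.slope == pytest.approx(1.5)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        assert reg.predict(40) == pytest.approx(60.0)

    def test_ols_matches_normal_equation_oracle(self):
        pairs = [(60, 32.0), (120, 58.0), (180, 92.0)]
        reg = fit_cutoff_regression(self.mk(pairs))
        x = np.array([L / 3 for L, _ in pairs])
        y = np.array([b for _, b in pairs])
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (
            n * (x * x).sum() - x.sum() ** 2
        )
        intercept = (y.sum() - slope * x.sum()) / n
        assert reg.slope == pytest.approx(slope)
        assert reg.intercept == pytest.approx(intercept)

    def test_single_point_proportional_fallback(self):
        reg = fit_cutoff_regression(self.mk([(60, 30.0)]))
        assert reg.n_points == 1
        assert reg.predict(40) == pytest.approx(60.0)  # 120 nt worth

    def test_prediction_clamped_at_zero(self):
        reg = fit_cutoff_regression(self.mk([(60, 10.0), (120, 60.0)]))
        assert reg.predict(1) == 0.0

    def test_no_points_raises(self):
        with pytest.raises(TrainingError):
            fit_cutoff_regression([])


class TestTrainAll:
    def test_default_lengths_are_60bp_grid(self):
        assert default_read_lengths(300) == [60, 120, 180, 240, 300]
        assert default_read_lengths(360) == [60, 120, 180, 240, 300, 360]

    def test_classifier_count_covers_all_gene_ranks(self, tiny_db, tiny_classifiers):
        # balanced taxonomy: every gene has all five ranks resolvable
        assert len(tiny_classifiers) == len(tiny_db) * 5
        assert tiny_classifiers.metadata["skipped_gene_ranks"] == {}

    def test_metadata_carries_gene_taxids(self, tiny_db, tiny_classifiers):
        taxids = tiny_classifiers.metadata["gene_taxids"]
        assert taxids == {r.gene_id: r.taxid for r in tiny_db.records}

    def test_serialisation_roundtrip_and_determinism(self, tiny_db, tmp_path):
        for sub in ("a", "b"):
            cs = train_all(tiny_db, read_lengths=[60, 120], seed=4)
            save_classifiers(cs, tmp_path / f"{sub}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        again = load_classifiers(tmp_path / "a.tsv")
        fresh = train_all(tiny_db, read_lengths=[60, 120], seed=4)
        assert again.regressions == fresh.regressions
        assert again.metadata["gene_taxids"] == fresh.metadata["gene_taxids"]

    def test_empty_db_raises(self, tiny_db):
        from markerphyler.refdb import MarkerDB
        empty = MarkerDB([], tiny_db.taxonomy)
        with pytest.raises(TrainingError, match="empty"):
            train_all(empty)

    def test_genus_cutoffs_more_stringent_than_phylum(self, species_db,
                                                      species_classifiers):
        """Close neighbours score higher, so the learned genus thresholds
        should on average exceed the phylum thresholds (soft tendency)."""
        genus = [r.predict(40) for (g, rank), r in
                 species_classifiers.regressions.items() if rank == "genus"]
        phylum = [r.predict(40) for (g, rank), r in
                  species_classifiers.regressions.items() if rank == "phylum"]
        assert np.mean(genus) >= np.mean(phylum)
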